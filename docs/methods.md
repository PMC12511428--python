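# Methods

## The three-box N–P–O₂ isotope model

### State and circulation

The model resolves phosphate, the two fixed-nitrogen isotopologues (¹⁴N,
¹⁵N) and oxygen in three boxes: a surface box above an upwelling region, the
intermediate box in which the oxygen minimum zone (OMZ) develops, and a box
representing the rest of the ocean. A single overturning loop at transport
*U* advects every tracer rest → OMZ → surface → rest: upwelled deep water
passes through the OMZ into the surface, and surface water returns to the
rest of the ocean. This is the minimal topology in which upwelled deep water
fuels surface production and the OMZ sits beneath the upwelling surface box;
the boxes are named in the underlying conceptual model but their plumbing is
a design choice of this package.

Surface O₂ is relaxed to a fixed solubility value `O2_surf`; subsurface O₂
changes only by transport and aerobic respiration.

### Biological closures

- **Uptake/export.** Production consumes the Liebig-limiting nutrient,
  `export_P = k_uptake · min(P_s, N_s/16) · V_surf`, with `k_uptake` fast
  relative to transport so the limiting nutrient is drawn down nearly
  completely. Export carries N at the production ratio N:P = 16.
- **Assimilation fractionation.** Exported N is depleted by `eps_assim`
  (default 5‰) relative to surface DIN. Fractionation uses the delta-linear
  convention (a flux fractionated by ε carries ratio `r_pool − ε·R_AIR/1000`),
  which makes δ¹⁵N(surface) − δ¹⁵N(export) = ε_assim hold *exactly* rather
  than to first order.
- **N₂ fixation.** `fix = k_fix · max(0, 16·P_s − N_s) · V_surf`, added to
  surface DIN at δ¹⁵N = `eps_fix` (default 0‰, within the −2…+2‰ range of
  nitrogenase). Fixation is the only N source.
- **Remineralization and denitrification.** A fraction `remin_frac_omz`
  (default 0.7) of the export rains into the OMZ. It is remineralized
  aerobically with efficiency a(O₂) — a logistic switch of width
  `o2_ramp_width` centred on `O2_thresh` (defaults 10⁻³ and 5×10⁻³ mol/m³) —
  consuming `rO2P` = 150 mol O₂ per mol P. Of the sub-oxic remainder, a
  share `f_wc_denit` (default 0.1) is remineralized by water-column
  denitrification, consuming `rNO3P` = 104 mol NO₃ per mol P with
  fractionation `eps_wc` = 25‰ and saturating in OMZ nitrate
  (half-saturation `K_NO3`); what neither pathway processes sinks on.
  The rest box treats its organic load the same way (its water-column
  denitrification matters only if the deep ocean itself turns hypoxic).
- **Seafloor and burial.** In the *closed* setup the seafloor returns all P
  (complete remineralization of a deep water column; no P burial). In the
  *open* setup the OMZ-box leftovers reach the margin seafloor beneath the
  upwelling zone, where a fraction `alpha` (default 0.25) of the P is buried
  with N at `rNP_burial`, plus a small O₂-independent floor (`burial_floor`,
  0.2% of the OMZ rain) so that burial is strictly positive whenever there
  is export — without it a zero-input ocean would stop draining once the
  OMZ re-oxygenates. In both setups a fraction `f_sed_N` (default 0.1) of
  the organic N delivered to the rest box is lost to sedimentary
  denitrification without fractionation; benthic N loss operates under oxic
  bottom water in the real ocean and is the unfractionated sink that lets
  steady-state δ¹⁵N sit between 0‰ and ε_wc. All sedimentary N removals are
  reported together as `f_burial_N`, so the bookkeeping identity
  d(total N)/dt = f_fix − f_denit_wc − f_burial_N closes exactly.

### Why the two setups behave differently

At steady state the isotope budget balances fixation (≈0‰) against
water-column denitrification (removes light N, expressed fractionation
shrinking as OMZ nitrate utilization approaches 1) and unfractionated
sedimentary losses. In the closed setup, raising *U* raises export and OMZ
nitrate throughput; the denitrification share and its expression grow, and
deep δ¹⁵N rises. In the open setup burial is pinned to the weathering input
at steady state, so raising *U* mainly adds oxygen: the denitrifying share
falls and δ¹⁵N falls. Export is near-flat across a tenfold span of the P
input because the steady state satisfies
`f_omz·E ≈ U·ΔO₂/rO2P + W/α` — the O₂-supply term dominates the direct
burial term.

### Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| U | 0.1 | Sv | mid-range of a single upwelling region (0–0.25 Sv) |
| P_inventory | 2.42 | Pmol | closed-setup operating point |
| W | 2.0 | mol P/s | open-setup input |
| alpha | 0.25 | – | burial fraction of non-remineralized export P |
| rNP_uptake, rNP_burial | 16 | mol/mol | Redfield |
| rO2P / rNO3P | 150 / 104 | mol/mol | canonical remineralization ratios |
| O2_surf | 0.25 | mol/m³ | cold-surface solubility |
| O2_thresh | 5×10⁻³ | mol/m³ | denitrification onset |
| eps_assim / eps_wc / eps_fix | 5 / 25 / 0 | ‰ | assimilation, water-column denitrification, fixation |
| V_surf / V_omz / V_rest | 10¹⁵ / 10¹⁶ / 1.3×10¹⁸ | m³ | small upwelling boxes under a whole-ocean reservoir |
| k_uptake | 10⁻⁶ | s⁻¹ | days-scale drawdown (fast limit) |
| k_fix | 10⁻¹⁰ | s⁻¹ | slow, substrate-limited fixation |
| K_NO3 | 3×10⁻³ | mol/m³ | denitrification half-saturation |
| f_wc_denit | 0.1 | – | water-column share of sub-oxic remineralization |
| f_sed_N | 0.1 | – | benthic N-loss fraction of the deep organic rain |
| burial_floor | 0.002 | – | O₂-independent margin burial |

Volumes, rate constants and the N-sink partition are not published for the
source box model; the defaults above were chosen once so that the default
configuration reproduces the qualitative steady-state behaviour the model is
meant to exhibit (monotone export in *U* in both setups; δ¹⁵N rising with
*U* under closed P and falling under open P, robust to the burial variants;
open-setup export homeostasis; a denitrifying OMZ at the closed operating
point). They are effective parameters of a three-box caricature, not ocean
inventories; absolute δ¹⁵N levels (≈14‰ deep at the closed operating point)
are accordingly stylized and only trends and closures should be compared
with data.

### Numerics

Steady states are found by root-finding (scipy `hybr`) on the scaled
tendency vector, seeded by stiff time integration (LSODA) with
geometrically growing epochs when the direct solve fails; sweeps use the
previous solution as the next initial state (continuation). In the closed
setup the P equations are rank-deficient (the inventory is conserved), so
one of them is replaced by the inventory constraint. Convergence means the
maximum absolute tendency, in flux units, is below 10⁻¹⁰ of the
characteristic nutrient transport; non-convergence is flagged in the result,
never raised. The *U* = 0 endpoints are degenerate (the rest box decouples
from both other boxes, so its composition is initial-condition-dependent;
the open setup has no reachable steady state there) and are reported as
non-converged or excluded from trend statements, which are evaluated over
converged grid points. The hard O₂ switch (`o2_switch="hard"`) is retained
for sensitivity studies but admits no classical steady state when the O₂
balance would settle on the threshold (the tendency chatters across the
discontinuity), which is why the logistic ramp is the default.

### Known limitations

- With the deficit-proportional fixation closure, steady-state export in the
  closed setup is non-decreasing in the P inventory: fixation always rescues
  N-limited production because the standing surplus P grows with the
  inventory. Deep δ¹⁵N does show an interior maximum along the inventory
  sweep, but export saturates instead of declining. A declining branch would
  require a fixation closure that decouples from the P surplus (for example
  an iron-limited ceiling on the fixer community).
- In the open setup, δ¹⁵N *increases* along the P-input sweep in this
  parameterization (the growing denitrification share outweighs the growing
  unfractionated burial), so the sign of that particular sub-trend should
  not be treated as a robust model property; the upwelling-sweep trends are
  the robust ones and are what the tests pin down.
- No carbon-cycle coupling, no spatial resolution, no transient forcings,
  no sediment diagenesis.

## Carbon-isotope systematics

ε_TOC uses the exact ratio form `1000·((1000+δc)/(1000+δo)−1)`, which
reduces to δc − δo to first order. δ¹³C of dissolved CO₂ is estimated from
a constant pre-industrial atmosphere (−5‰) via the Mook gas↔aqueous
equilibrium ε(T) = −373/T + 0.19; the calcite↔bicarbonate↔gas coefficients
live in the same constant block (`nbox.constants.MOOK_COEFFICIENTS`) so a
different edition can be swapped in one place, and a pure-equilibrium
Δ_CARB(T) variant is provided as a cross-check. Δ_CARB is defined here as
δ¹³C_carb − δ¹³C_CO₂(aq) (positive, ≈ +8…10‰ at modern conditions) so that
ε_P − Δ₂ = ε_TOC − Δ_CARB lands at physically possible photosynthetic
fractionations (≈ 20‰ for modern inputs); defining Δ_CARB with the opposite
sign under the same subtraction would yield ε_P ≈ 38‰, which exceeds the
Rubisco limit. Δ₂ (1.5‰, secondary biological shifts) is carried as
metadata and never subtracted: the reported quantity is ε_P − Δ₂ itself.
Temperatures come from a user-supplied age→temperature table, interpolated
linearly in age; the constant-atmosphere simplification is kept because the
secular change in atmospheric δ¹³C is a small component of the signal.

## Record analytics

Ages are Ma before present, increasing into the past. Splicing concatenates
same-environment sites and reports the mean pairwise δ¹⁵N offset over each
temporal overlap (nearest-age pairing within 2 Myr); offsets beyond the
tolerance are flagged, never corrected. Dry bulk density defaults to
1.0 g/cm³ per site when not reported, and C_org accumulation is
(TOC/100)·ρ·sedimentation rate. Δ¹⁵N = distal − deep after piecewise-linear
interpolation onto a common grid, with grid points masked where either
record has a gap wider than 10 Myr (no values are invented across record
gaps). Binning is anchored at age 0 with empty bins emitted and SD
undefined below n = 2. Windowed correlations default to the {older than
28 Ma, 28–0 Ma} partition and mark windows with fewer than 4 pairs as
insufficient.

## Upwelling diagnostic

Coastal cells are ocean cells with at least one land neighbour
(4-connectivity, zonal wrap); the offshore normal averages the land→ocean
directions and cells whose directions cancel (one-cell straits) are
excluded as having no defined offshore direction. The offshore Ekman mass
transport per unit coastline is τ·t̂/f with t̂ the along-shore unit vector
(normal rotated 90° counter-clockwise), cells within 5° of the equator are
skipped, and only upwelling-favourable (positive) transports enter the
global integral; downwelling is tallied separately. Grid metrics assume a
spherical Earth (R = 6371 km). Each of these conventions is a configuration
choice exposed in the API.

## Synthetic data

The record generator draws site ages from overlapping windows (so splice
diagnostics are always exercised), adds a shared AR(1) anomaly along age
plus independent within-timepoint noise scaled to the ~2‰ spread seen in
bulk-sediment compilations, and modulates TOC so that organic-carbon
accumulation co-varies with the δ¹⁵N anomaly at a configurable sign per age
window. The default baseline curves (stable deep-margin ≈3–4‰; distal
elevated through the Paleogene, converging by ~11 Ma) are illustrative
shapes for testing, never ground truth. What passing tests on synthetic
data demonstrate is that the *pipeline* recovers constructed signals
(offsets, gaps, couplings, binned means) at the noise levels typical of
such records — not that real records have those values. Diagenesis,
bioturbation and foraminiferal binding are not simulated. Wind-field
templates provide a modern-like meridional coast and a Tethys-like zonal
coast under analytic trade/westerly bands; the generators guarantee
non-degeneracy (a coastline exists, fluxes are finite), while comparisons
between templates are made in tests, not inside the generator.
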
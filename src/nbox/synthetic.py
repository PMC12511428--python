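"""Synthetic inputs: sediment records, idealized wind fields, model observations.

Everything the analysis modules consume can be generated here, so the whole
pipeline is exercisable without any external download. Every generator is a
pure function of its scenario and seed: identical inputs give bit-identical
outputs.

The sediment-record generator emulates the statistical structure of
long-timescale bulk-sediment isotope compilations: two environment classes
(deep-margin vs distal), smooth long-term baseline trends described by
piecewise-linear control points, red (AR(1)) noise along the age axis, an
up-to-2 permil within-timepoint spread (sub-millennial variability aliased
by sparse sampling), sparse site-specific age grids with overlapping
coverage, and TOC/sedimentation-rate regimes that let organic-carbon
accumulation co-vary with delta15N with a configurable sign per age window.
The default baselines sketch a stable deep-margin record (~3-4 permil) and a
distal record elevated through the Paleogene that converges by the Miocene;
they are illustrative shapes for testing, not data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .boxmodel import solve_steady_state
from .params import ModelParams
from .records import SedimentRecord
from .upwelling import WindField

__all__ = [
    "RecordScenario",
    "ContinentScenario",
    "make_records",
    "make_windfield",
    "make_boxmodel_observations",
    "DEEP_BASELINE",
    "DISTAL_BASELINE",
]

#: (age Ma, d15N permil) control points: stable deep-margin record ~3-4 permil
DEEP_BASELINE = ((0.0, 4.5), (10.0, 4.0), (28.0, 2.8), (60.0, 4.0), (100.0, 3.0), (140.0, 3.0), (165.0, 2.0))
#: distal record elevated through the Paleogene, converging by ~11 Ma
DISTAL_BASELINE = ((0.0, 4.5), (11.0, 4.5), (30.0, 6.5), (60.0, 8.5), (90.0, 6.5))


@dataclass
class RecordScenario:
    """Statistical description of a synthetic sediment-record ensemble."""

    environment: str = "deep-margin"
    age_min: float = 0.0
    age_max: float = 165.0
    sampling_density: float = 1.5  # points per Myr per site
    baseline: Sequence[tuple[float, float]] = DEEP_BASELINE
    spread: float = 2.0  # permil, within-timepoint spread
    ar_coeff: float = 0.5  # AR(1) coefficient of the age-axis noise
    ar_sd: float = 0.5  # permil, innovation SD of the AR(1) component
    toc_mean: float = 1.0  # wt%
    toc_trend: float = 0.0  # wt% per 100 Myr (toward older ages)
    sed_rate_mean: float = 2.0  # cm/kyr
    #: (age_min, age_max, sign) coupling between d15N anomaly and C_org
    #: accumulation inside each window; +1, -1 or 0
    coupling_windows: Sequence[tuple[float, float, int]] = ((0.0, 28.0, 1), (28.0, 165.0, -1))
    coupling_strength: float = 0.6  # relative TOC modulation per permil anomaly
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ValueError("spread must be non-negative")
        if not abs(self.ar_coeff) < 1:
            raise ValueError("AR(1) coefficient must satisfy |a| < 1")
        if self.age_max <= self.age_min:
            raise ValueError("degenerate age span")
        ages = [a for a, _ in self.baseline]
        if min(ages) < self.age_min - 1e-9 or max(ages) > self.age_max + 1e-9:
            raise ValueError("baseline control points must lie within the age span")

    def baseline_at(self, ages):
        pts = sorted(self.baseline)
        xs = [a for a, _ in pts]
        ys = [v for _, v in pts]
        return np.interp(ages, xs, ys)


def make_records(scenario: RecordScenario, n_sites: int = 3) -> list[SedimentRecord]:
    """Generate per-site records sampled around a shared baseline curve.

    Sites get overlapping age windows covering the scenario span (so splice
    diagnostics are exercised), sparse jittered age grids, a shared AR(1)
    age-axis anomaly plus independent within-timepoint spread, and TOC
    modulated so that organic-carbon accumulation co-varies with the local
    delta15N anomaly at the configured sign per window.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(scenario.seed)
    span = scenario.age_max - scenario.age_min

    # a shared, age-continuous AR(1) anomaly sampled on a fine grid
    fine = np.arange(scenario.age_min, scenario.age_max + 0.5, 0.5)
    ar = np.zeros(fine.size)
    stationary_sd = scenario.ar_sd / np.sqrt(1.0 - scenario.ar_coeff**2)
    ar[0] = rng.normal(0.0, stationary_sd)
    for k in range(1, fine.size):
        ar[k] = scenario.ar_coeff * ar[k - 1] + rng.normal(0.0, scenario.ar_sd)

    records = []
    for s in range(n_sites):
        # overlapping windows: each site covers ~2/n of the span, shifted
        if n_sites == 1:
            lo, hi = scenario.age_min, scenario.age_max
        else:
            w = 2.0 * span / (n_sites + 1)
            lo = scenario.age_min + s * (span - w) / (n_sites - 1)
            hi = lo + w
        n = max(int(round((hi - lo) * scenario.sampling_density)), 4)
        ages = np.sort(rng.uniform(lo, hi, n))
        # enforce strictly increasing ages
        ages += np.arange(n) * 1e-6

        anomaly = np.interp(ages, fine, ar)
        noise = rng.normal(0.0, scenario.spread / 2.0, n)  # 2 sigma ~ spread
        d15N = scenario.baseline_at(ages) + anomaly + noise

        toc_base = scenario.toc_mean + scenario.toc_trend * ages / 100.0
        sign = np.zeros(n)
        for a0, a1, sg in scenario.coupling_windows:
            sel = (ages >= a0) & (ages < a1)
            sign[sel] = sg
        centred = anomaly + noise
        toc = toc_base * np.exp(
            sign * scenario.coupling_strength * centred
        ) * rng.lognormal(0.0, 0.2, n)
        toc = np.maximum(toc, 1e-3)
        sed_rate = scenario.sed_rate_mean * rng.lognormal(0.0, 0.2, n)
        d13C_org = -26.0 + 0.3 * centred + rng.normal(0.0, 0.5, n)

        records.append(
            SedimentRecord(
                site=f"{scenario.environment}-{s + 1:02d}",
                environment=scenario.environment,
                data=pd.DataFrame(
                    {
                        "age": ages,
                        "d15N": d15N,
                        "d13C_org": d13C_org,
                        "TOC": toc,
                        "sed_rate": sed_rate,
                        "dry_bulk_density": np.full(n, 1.0),
                    }
                ),
            )
        )
    return records


@dataclass
class ContinentScenario:
    """Idealized continent/wind template for the upwelling diagnostic.

    Templates: ``meridional-coast`` -- a modern-like N-S continent strip whose
    eastern-boundary ocean sees along-shore trade winds; ``zonal-coast`` -- a
    low-latitude E-W (Tethys-like) landmass with a long zonal southern shore;
    ``custom`` -- caller-supplied mask. Wind patterns: ``trades`` (easterlies
    within +-30 deg, westerlies 30-60 deg), ``zonal-easterly``, or ``custom``
    caller-supplied stress fields.
    """

    template: str = "meridional-coast"
    wind: str = "trades"
    n_lat: int = 36
    n_lon: int = 72
    tau_scale: float = 0.1  # N/m2
    custom_mask: np.ndarray | None = None
    custom_tau: tuple[np.ndarray, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template not in ("meridional-coast", "zonal-coast", "custom"):
            raise ValueError(f"unknown template {self.template!r}")
        if self.wind not in ("trades", "zonal-easterly", "zero", "custom"):
            raise ValueError(f"unknown wind pattern {self.wind!r}")


def make_windfield(scenario: ContinentScenario) -> WindField:
    """Analytic wind-stress field over an idealized continent mask."""
    ni, nj = scenario.n_lat, scenario.n_lon
    lat = np.linspace(-90.0 + 90.0 / ni, 90.0 - 90.0 / ni, ni)
    lon = np.linspace(180.0 / nj, 360.0 - 180.0 / nj, nj)
    LAT = lat[:, None] * np.ones((1, nj))

    if scenario.template == "meridional-coast":
        mask = np.zeros((ni, nj), dtype=bool)
        j0, j1 = int(nj * 0.45), int(nj * 0.55)
        mask[:, j0:j1] = np.abs(LAT[:, j0:j1]) < 65.0
    elif scenario.template == "zonal-coast":
        mask = np.zeros((ni, nj), dtype=bool)
        i0 = np.searchsorted(lat, 5.0)
        i1 = np.searchsorted(lat, 40.0)
        mask[i0:i1, int(nj * 0.2) : int(nj * 0.8)] = True
    else:
        if scenario.custom_mask is None:
            raise ValueError("custom template requires custom_mask")
        mask = np.asarray(scenario.custom_mask, dtype=bool)
        if mask.shape != (ni, nj):
            raise ValueError("custom_mask shape does not match the grid")
    if not mask.any():
        raise ValueError("template produced no coastline (all ocean)")

    if scenario.wind == "zero":
        tau_x = np.zeros((ni, nj))
        tau_y = np.zeros((ni, nj))
    elif scenario.wind == "zonal-easterly":
        tau_x = -scenario.tau_scale * np.cos(np.deg2rad(LAT)) ** 2
        tau_y = np.zeros((ni, nj))
    elif scenario.wind == "trades":
        # easterlies equatorward of 30 deg, westerlies 30-60 deg, with the
        # meridional component of the trades converging on the equator
        band = np.cos(np.deg2rad(3.0 * LAT))
        tau_x = -scenario.tau_scale * np.where(np.abs(LAT) < 30.0, band, band)
        tau_y = -scenario.tau_scale * 0.5 * np.sign(LAT) * (np.abs(LAT) < 30.0)
    else:
        if scenario.custom_tau is None:
            raise ValueError("custom wind requires custom_tau")
        tau_x, tau_y = (np.asarray(t, dtype=float) for t in scenario.custom_tau)

    return WindField(lat=lat, lon=lon, tau_x=tau_x, tau_y=tau_y, land_mask=mask)


def make_boxmodel_observations(
    params: ModelParams,
    noise_sd: dict | None = None,
    seed: int = 0,
    n_obs: int = 20,
) -> pd.DataFrame:
    """Noisy steady-state observations for parameter-recovery experiments.

    Solves the steady state at ``params`` and draws ``n_obs`` Gaussian
    replicates of (export_P, d15N_deep). ``noise_sd`` maps those column
    names to standard deviations (defaults: 5 mol P/s and 0.3 permil).
    Rejects non-converged base states.
    """
    result = solve_steady_state(params)
    if not result.converged:
        raise ValueError("box model did not converge; cannot generate observations")
    if noise_sd is None:
        noise_sd = {"export_P": 5.0, "d15N_deep": 0.3}
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "export_P": result.export_P
            + rng.normal(0.0, noise_sd["export_P"], n_obs),
            "d15N_deep": result.d15N_deep
            + rng.normal(0.0, noise_sd["d15N_deep"], n_obs),
        }
    )
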
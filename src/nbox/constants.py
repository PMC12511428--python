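"""Physical constants and unit conversions shared across the package."""

#: Atmospheric 15N/14N ratio (AIR reference for delta15N).
R_AIR = 0.0036765

#: Sverdrup, volume transport unit (m3/s).
SV = 1.0e6

#: Petamole (mol).
PMOL = 1.0e15

#: Mean Earth radius (m), spherical-Earth grid metrics.
EARTH_RADIUS = 6.371e6

#: Earth rotation rate (rad/s).
OMEGA_EARTH = 7.2921e-5

#: Reference seawater density (kg/m3).
RHO_SEAWATER = 1025.0

# ---------------------------------------------------------------------------
# Carbon-isotope equilibrium fractionations (Mook-style coefficient block).
#
# Each entry gives (a, b) for an expression of the form
#     eps(T) = a / T_kelvin + b      [permil]
# describing the equilibrium 13C separation of the first phase relative to
# the second. Swapping editions of the coefficients only requires editing
# this block; no logic elsewhere depends on the numbers.
# ---------------------------------------------------------------------------
MOOK_COEFFICIENTS = {
    # dissolved CO2 relative to gaseous CO2 (dissolution/hydration leg)
    "co2aq_vs_co2g": (-373.0, 0.19),
    # bicarbonate relative to gaseous CO2
    "hco3_vs_co2g": (9483.0, -23.89),
    # calcite relative to bicarbonate
    "calcite_vs_hco3": (-4232.0, 15.10),
}

#: Secondary-biological 13C offset between primary photosynthate and
#: sedimentary organic carbon (permil). Reported quantities are eps_P - DELTA2;
#: the constant is metadata for anyone deriving eps_P itself.
DELTA2 = 1.5

#: Celsius -> Kelvin offset.
KELVIN = 273.15
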
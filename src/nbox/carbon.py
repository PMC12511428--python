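"""Carbon-isotope systematics: eps_TOC, Delta_CARB and eps_P - Delta_2.

The photosynthetic carbon-isotope fractionation proxy eps_P - Delta_2 is
computed from paired carbonate/organic delta13C following the Hayes
framework::

    eps_P - Delta_2 = eps_TOC - Delta_CARB

where ``eps_TOC`` is the isotopic separation between carbonate and organic
carbon and ``Delta_CARB`` the separation between carbonate minerals and
dissolved CO2. delta13C of dissolved CO2 is estimated from the atmospheric
value (default -5 permil, pre-industrial) via the temperature-dependent
gas <-> aqueous equilibrium fractionation (Mook coefficients, see
:mod:`nbox.constants`). Delta_2 (~1.5 permil) accounts for secondary
biological 13C shifts between primary photosynthate and sedimentary organic
carbon; it is carried as metadata and never subtracted here -- the reported
quantity is eps_P - Delta_2 itself.

All deltas are permil vs VPDB, temperatures degrees Celsius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DELTA2, KELVIN, MOOK_COEFFICIENTS

__all__ = [
    "CarbonSample",
    "epsilon_toc",
    "delta13C_co2_aq",
    "delta_carb",
    "ep_minus_delta2",
    "ep_minus_delta2_table",
    "DELTA2",
]

#: validity range of the equilibrium fractionation expressions (deg C)
TEMPERATURE_RANGE = (-5.0, 60.0)


@dataclass
class CarbonSample:
    """One dated sample of paired organic/carbonate carbon isotopes."""

    age: float  # Ma
    d13C_org: float  # permil vs VPDB
    d13C_carb: float  # permil vs VPDB
    temperature: float | None = None  # deg C, from an external curve
    d13C_atm: float = -5.0  # permil; pre-industrial atmospheric CO2

    def __post_init__(self) -> None:
        for name in ("d13C_org", "d13C_carb", "d13C_atm"):
            v = getattr(self, name)
            if not -1000.0 < v < 1000.0:
                raise ValueError(f"{name}={v} outside (-1000, 1000) permil")


def _mook_eps(key: str, T_kelvin):
    a, b = MOOK_COEFFICIENTS[key]
    return a / T_kelvin + b


def epsilon_toc(d13C_carb, d13C_org):
    """Isotopic separation between carbonate and organic carbon (permil).

    Exact ratio form ``1000*((1000+d13C_carb)/(1000+d13C_org)-1)``, which
    reduces to the simple difference d13C_carb - d13C_org to first order.
    """
    d13C_carb = np.asarray(d13C_carb, dtype=float)
    d13C_org = np.asarray(d13C_org, dtype=float)
    if np.any(d13C_org <= -1000.0):
        raise ValueError("d13C_org <= -1000 permil is unphysical")
    out = 1000.0 * ((1000.0 + d13C_carb) / (1000.0 + d13C_org) - 1.0)
    return float(out) if out.ndim == 0 else out


def delta13C_co2_aq(temperature, d13C_atm=-5.0):
    """delta13C of dissolved CO2 in equilibrium with atmospheric CO2.

    Applies the temperature-dependent dissolution/hydration equilibrium
    fractionation (Mook): eps(CO2aq - CO2g) = -373/T + 0.19 permil.
    Temperatures outside the expressions' validity range are extrapolated
    with a warning.
    """
    temperature = np.asarray(temperature, dtype=float)
    if np.any((temperature < TEMPERATURE_RANGE[0]) | (temperature > TEMPERATURE_RANGE[1])):
        warnings.warn(
            "temperature outside the validity range of the equilibrium "
            f"fractionation expressions {TEMPERATURE_RANGE}; extrapolating",
            stacklevel=2,
        )
    eps = _mook_eps("co2aq_vs_co2g", temperature + KELVIN)
    out = np.asarray(d13C_atm, dtype=float) + eps
    return float(out) if out.ndim == 0 else out


def delta_carb(temperature, d13C_atm, d13C_carb):
    """Delta_CARB: separation between carbonate minerals and dissolved CO2.

    ``Delta_CARB = d13C_carb - delta13C_CO2(aq)``, with the dissolved-CO2
    composition estimated from the atmosphere at the given temperature.
    Positive (~+8..10 permil at modern conditions), so that
    eps_P - Delta_2 = eps_TOC - Delta_CARB lands at realistic eps_P values.
    """
    aq = delta13C_co2_aq(temperature, d13C_atm)
    out = np.asarray(d13C_carb, dtype=float) - aq
    return float(out) if out.ndim == 0 else out


def delta_carb_equilibrium(temperature):
    """Pure-equilibrium Delta_CARB(T): calcite vs dissolved CO2 (permil).

    Composes the Mook equilibria calcite-HCO3, HCO3-CO2(g) and CO2(aq)-CO2(g);
    about +9.9 permil at 25 degC. Provided as a cross-check variant that does
    not use measured carbonate or atmospheric values.
    """
    T = np.asarray(temperature, dtype=float) + KELVIN
    eps = (
        _mook_eps("calcite_vs_hco3", T)
        + _mook_eps("hco3_vs_co2g", T)
        - _mook_eps("co2aq_vs_co2g", T)
    )
    return float(eps) if eps.ndim == 0 else eps


def ep_minus_delta2(sample: CarbonSample) -> float:
    """eps_P - Delta_2 for one sample: eps_TOC - Delta_CARB (permil).

    Delta_2 itself (:data:`DELTA2`, 1.5 permil) is not subtracted; anyone
    deriving eps_P proper adds it back.
    """
    if sample.temperature is None or not np.isfinite(sample.temperature):
        raise ValueError(
            "sample has no temperature: supply an age->temperature curve "
            "(the dissolved-CO2 equilibrium is temperature dependent)"
        )
    return float(
        epsilon_toc(sample.d13C_carb, sample.d13C_org)
        - delta_carb(sample.temperature, sample.d13C_atm, sample.d13C_carb)
    )


def ep_minus_delta2_table(
    records: pd.DataFrame,
    temperatures: pd.DataFrame,
    d13C_atm: float = -5.0,
) -> pd.DataFrame:
    """Vectorized eps_P - Delta_2 over a record table.

    ``records`` needs columns (age, d13C_org, d13C_carb); ``temperatures``
    is an (age, temperature) table interpolated linearly in age. Returns the
    input with eps_toc, delta_carb and ep_minus_delta2 columns appended.
    """
    for col in ("age", "d13C_org", "d13C_carb"):
        if col not in records.columns:
            raise ValueError(f"records table is missing required column {col!r}")
    for col in ("age", "temperature"):
        if col not in temperatures.columns:
            raise ValueError(f"temperature table is missing required column {col!r}")
    temps = temperatures.sort_values("age")
    T = np.interp(records["age"], temps["age"], temps["temperature"])
    out = records.copy()
    out["eps_toc"] = epsilon_toc(out["d13C_carb"], out["d13C_org"])
    out["delta_carb"] = delta_carb(T, d13C_atm, out["d13C_carb"])
    out["ep_minus_delta2"] = out["eps_toc"] - out["delta_carb"]
    return out
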
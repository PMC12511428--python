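"""Parameter and state containers for the three-box N-P-O2 isotope model.

The model resolves a surface box overlying an upwelling region, the
intermediate box in which the oxygen minimum zone (OMZ) develops, and a box
representing the rest of the ocean. A single circulation loop at transport
``U`` advects all tracers rest -> OMZ -> surface -> rest, i.e. deep water is
upwelled through the OMZ into the surface box and returns to the rest of the
ocean.

Two setups are supported:

* ``closed_P=True`` -- the ocean phosphate inventory is fixed (``P_inventory``),
  there is no P burial; this represents deep-water regions where exported P is
  completely remineralized.
* ``closed_P=False`` -- "open" P cycle with a weathering input ``W`` balanced
  at steady state by burial of a fraction ``alpha`` of the organic P rain that
  escapes water-column remineralization, representing shallow regions with
  significant burial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .constants import PMOL, SV

__all__ = ["ModelParams", "ModelState", "BOX_NAMES"]

BOX_NAMES = ("surface", "omz", "rest")


@dataclass
class ModelParams:
    """Constants of the three-box N-P-O2 isotope model.

    Transport/display units follow oceanographic convention: ``U`` in Sv
    (1 Sv = 1e6 m3/s) and ``P_inventory`` in Pmol (1e15 mol); everything else
    is SI (mol, m3, s, mol/m3, permil for isotope epsilons).
    """

    #: upwelling transport (Sv)
    U: float = 0.1
    #: closed (fixed inventory) vs open (weathering + burial) P setup
    closed_P: bool = True
    #: total ocean P for the closed setup (Pmol)
    P_inventory: float = 2.42
    #: P weathering input for the open setup (mol P/s)
    W: float = 2.0
    #: fraction of non-remineralized exported organic P that is buried (open setup)
    alpha: float = 0.25
    #: N:P of primary production (mol/mol)
    rNP_uptake: float = 16.0
    #: N:P of buried material (mol/mol)
    rNP_burial: float = 16.0
    #: O2 consumed per P remineralized aerobically (mol/mol)
    rO2P: float = 150.0
    #: nitrate consumed per P remineralized by denitrification (mol/mol)
    rNO3P: float = 104.0
    #: surface O2 set by solubility (mol/m3)
    O2_surf: float = 0.25
    #: O2 below which denitrification takes over remineralization (mol/m3)
    O2_thresh: float = 5.0e-3
    #: nitrate-assimilation fractionation (permil)
    eps_assim: float = 5.0
    #: water-column denitrification fractionation (permil)
    eps_wc: float = 25.0
    #: delta15N of newly fixed N (permil, within the -2..+2 range)
    eps_fix: float = 0.0
    #: box volumes (m3)
    V_surf: float = 1.0e15
    V_omz: float = 1.0e16
    V_rest: float = 1.3e18
    #: N2-fixation rate constant (1/s); flux = k_fix * max(0, rNP*P - N) * V_surf
    k_fix: float = 1.0e-10
    #: fraction of export remineralized within the OMZ box
    remin_frac_omz: float = 0.7
    #: surface nutrient-uptake rate constant (1/s); "fast" relative to transport
    k_uptake: float = 1.0e-6
    #: relaxation rate of surface O2 toward solubility (1/s)
    k_O2_relax: float = 1.0e-6
    #: half-saturation of denitrification in OMZ nitrate (mol/m3)
    K_NO3: float = 3.0e-3
    #: share of sub-oxic remineralization carried by water-column
    #: denitrification; the remainder sinks on toward the seafloor where N
    #: losses are unfractionated (water-column denitrification is the minor
    #: pathway in the modern ocean)
    f_wc_denit: float = 0.1
    #: aerobic/denitrification switch: smooth logistic ramp or hard threshold
    o2_switch: Literal["ramp", "hard"] = "ramp"
    #: ramp width of the logistic switch (mol/m3); ignored for "hard"
    o2_ramp_width: float = 1.0e-3
    #: fraction of rest-box organic N lost to sedimentary denitrification /
    #: permanent retention (unfractionated) rather than recycled
    f_sed_N: float = 0.1
    #: fraction of the OMZ organic rain that reaches the margin seafloor
    #: regardless of O2 (open setup); keeps burial strictly positive whenever
    #: there is export, so a zero-input ocean drains its P inventory
    burial_floor: float = 0.002
    #: variant: P burial efficiency increasing with bottom-water O2
    o2_dependent_burial: bool = False
    #: half-saturation of the O2-dependent burial-efficiency factor (mol/m3)
    K_O2_burial: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    # -- unit helpers -------------------------------------------------------
    @property
    def U_m3s(self) -> float:
        """Upwelling transport in m3/s."""
        return self.U * SV

    @property
    def P_inventory_mol(self) -> float:
        """Closed-setup P inventory in mol."""
        return self.P_inventory * PMOL

    @property
    def V_total(self) -> float:
        return self.V_surf + self.V_omz + self.V_rest

    def validate(self) -> None:
        numeric = {
            k: v
            for k, v in self.__dict__.items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)
        }
        for name, value in numeric.items():
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} is not finite: {value!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if min(self.V_surf, self.V_omz, self.V_rest) <= 0:
            raise ValueError("box volumes must be positive")
        if self.U < 0:
            raise ValueError("upwelling transport U must be non-negative")
        if not 0.0 <= self.remin_frac_omz <= 1.0:
            raise ValueError("remin_frac_omz must lie in [0, 1]")
        if not 0.0 <= self.f_sed_N <= 1.0:
            raise ValueError("f_sed_N must lie in [0, 1]")
        if not 0.0 <= self.burial_floor <= 1.0:
            raise ValueError("burial_floor must lie in [0, 1]")
        if self.closed_P and self.P_inventory <= 0:
            raise ValueError("closed setup requires a positive P_inventory")
        if not self.closed_P and self.W < 0:
            raise ValueError("open setup requires a non-negative P input W")
        if self.o2_switch not in ("ramp", "hard"):
            raise ValueError("o2_switch must be 'ramp' or 'hard'")

    def updated(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)


@dataclass
class ModelState:
    """Tracer concentrations per box, ordered (surface, OMZ, rest).

    ``P`` phosphate, ``N14``/``N15`` fixed-nitrogen isotopologues and ``O2``
    are all in mol/m3. delta15N is never stored; it is derived from the
    isotopologue pools for reporting only.
    """

    P: np.ndarray = field(default_factory=lambda: np.zeros(3))
    N14: np.ndarray = field(default_factory=lambda: np.zeros(3))
    N15: np.ndarray = field(default_factory=lambda: np.zeros(3))
    O2: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("P", "N14", "N15", "O2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"{name} must have shape (3,), got {arr.shape}")
            setattr(self, name, arr)

    # -- vector packing -----------------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.P, self.N14, self.N15, self.O2])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (12,):
            raise ValueError(f"state vector must have length 12, got {y.shape}")
        return cls(P=y[0:3].copy(), N14=y[3:6].copy(), N15=y[6:9].copy(), O2=y[9:12].copy())

    def validate(self) -> None:
        for name in ("P", "N14", "N15", "O2"):
            arr = getattr(self, name)
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"state field {name} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"state field {name} contains negative concentrations")

    @property
    def N_total(self) -> np.ndarray:
        """Total fixed N per box (mol/m3)."""
        return self.N14 + self.N15

    def total_P_mol(self, params: ModelParams) -> float:
        volumes = np.array([params.V_surf, params.V_omz, params.V_rest])
        return float(np.dot(self.P, volumes))

    def total_N_mol(self, params: ModelParams) -> float:
        volumes = np.array([params.V_surf, params.V_omz, params.V_rest])
        return float(np.dot(self.N_total, volumes))

    @classmethod
    def default_initial(cls, params: ModelParams, d15N: float = 0.0) -> "ModelState":
        """Well-mixed starting state consistent with the setup's P inventory.

        For the open setup an inventory comparable to the modern mean is used
        as a starting guess; the steady state does not depend on it.
        """
        from .constants import R_AIR

        if params.closed_P:
            P0 = params.P_inventory_mol / params.V_total
        else:
            P0 = 2.0e-3
        N0 = params.rNP_uptake * P0
        ratio = R_AIR * (1.0 + d15N / 1000.0)
        N14 = N0 / (1.0 + ratio)
        N15 = N0 - N14
        return cls(
            P=np.full(3, P0),
            N14=np.full(3, N14),
            N15=np.full(3, N15),
            O2=np.array([params.O2_surf, 0.5 * params.O2_surf, params.O2_surf]),
        )
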
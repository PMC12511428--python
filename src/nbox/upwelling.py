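"""Coastal Ekman upwelling diagnostic from gridded wind stress.

Coastal upwelling occurs where the wind blows along-shore with the coast on
the appropriate side (left of the wind in the Northern hemisphere): the
near-surface Ekman transport is then directed offshore and deep water rises
to replace it. Given a wind-stress field and a land mask, this module
detects coastal ocean cells, projects the wind stress onto the local
along-shore direction, converts it to an offshore Ekman mass transport
``tau_parallel / f`` (kg s-1 m-1) and integrates the upwelling-favourable
part along the global coastline.

Conventions (each a configuration choice, see the methods note): coastal
cells are ocean cells with at least one land neighbour (4-connectivity);
cells within ``lat_min`` degrees of the equator are skipped (f -> 0); only
positive (upwelling-favourable) transports enter the global integral, with
downwelling tallied separately; grid metrics assume a spherical Earth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .constants import EARTH_RADIUS, OMEGA_EARTH, RHO_SEAWATER, SV

__all__ = [
    "WindField",
    "CoastalCell",
    "UpwellingResult",
    "coriolis",
    "coastal_cells",
    "coastal_upwelling_flux",
]


def coriolis(lat, omega: float = OMEGA_EARTH):
    """Coriolis parameter f = 2 * Omega * sin(lat), lat in degrees."""
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    out = 2.0 * omega * np.sin(np.deg2rad(lat))
    return float(out) if out.ndim == 0 else out


@dataclass
class WindField:
    """Gridded surface wind stress with a land mask.

    ``lat``/``lon`` are 1-D cell-centre coordinates (degrees) of a regular
    grid; ``tau_x``/``tau_y`` (N/m2) and ``land_mask`` (True = land) are
    (nlat, nlon) arrays.
    """

    lat: np.ndarray
    lon: np.ndarray
    tau_x: np.ndarray
    tau_y: np.ndarray
    land_mask: np.ndarray
    rho: float = RHO_SEAWATER
    omega: float = OMEGA_EARTH

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        shape = (self.lat.size, self.lon.size)
        for name in ("tau_x", "tau_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.land_mask.shape != shape:
            raise ValueError(f"land_mask must have shape {shape}")
        if np.any(np.abs(self.lat) > 90.0):
            raise ValueError("latitudes outside [-90, 90]")

    # -- NetCDF round trip ---------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "tau_x": (("lat", "lon"), self.tau_x),
                "tau_y": (("lat", "lon"), self.tau_y),
                "land_mask": (("lat", "lon"), self.land_mask.astype("i1")),
            },
            coords={"lat": self.lat, "lon": self.lon},
            attrs={"rho": self.rho, "omega": self.omega},
        )

    def to_netcdf(self, path) -> None:
        # NETCDF3 via the scipy engine keeps the file dependency-light
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "WindField":
        return cls(
            lat=ds["lat"].values,
            lon=ds["lon"].values,
            tau_x=ds["tau_x"].values,
            tau_y=ds["tau_y"].values,
            land_mask=ds["land_mask"].values.astype(bool),
            rho=float(ds.attrs.get("rho", RHO_SEAWATER)),
            omega=float(ds.attrs.get("omega", OMEGA_EARTH)),
        )

    @classmethod
    def from_netcdf(cls, path) -> "WindField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


@dataclass
class CoastalCell:
    """One coastal ocean cell with its offshore normal and coastline length."""

    i: int  # lat index
    j: int  # lon index
    lat: float
    lon: float
    normal: tuple[float, float]  # offshore unit vector (east, north)
    segment_length: float  # m


#: (di, dj, unit vector from neighbour toward the centre cell in (east, north))
_NEIGHBOURS = (
    (1, 0, (0.0, -1.0)),  # land to the north -> offshore points south
    (-1, 0, (0.0, 1.0)),  # land to the south -> offshore points north
    (0, 1, (-1.0, 0.0)),  # land to the east -> offshore points west
    (0, -1, (1.0, 0.0)),  # land to the west -> offshore points east
)


def coastal_cells(
    land_mask: np.ndarray,
    lat: np.ndarray | None = None,
    lon: np.ndarray | None = None,
    wrap_lon: bool = True,
) -> list[CoastalCell]:
    """Ocean cells adjacent to land (4-connectivity) with offshore normals.

    The offshore normal is the normalized average of the directions from
    each adjacent land cell into the ocean cell; the coastline segment
    length is the total length of shared land/ocean cell edges, from
    spherical grid metrics at the cell latitude. Returns an empty list for
    all-land or all-ocean masks.
    """
    land_mask = np.asarray(land_mask, dtype=bool)
    ni, nj = land_mask.shape
    if lat is None:
        lat = np.linspace(-90.0 + 90.0 / ni, 90.0 - 90.0 / ni, ni)
    if lon is None:
        lon = np.linspace(0.0 + 180.0 / nj, 360.0 - 180.0 / nj, nj)
    dlat = float(np.abs(np.diff(lat)).mean()) if ni > 1 else 1.0
    dlon = float(np.abs(np.diff(lon)).mean()) if nj > 1 else 1.0
    meridional_edge = np.deg2rad(dlat) * EARTH_RADIUS  # shared E/W edge length
    cells: list[CoastalCell] = []
    for i in range(ni):
        zonal_edge = np.deg2rad(dlon) * EARTH_RADIUS * np.cos(np.deg2rad(lat[i]))
        for j in range(nj):
            if land_mask[i, j]:
                continue
            normal = np.zeros(2)
            length = 0.0
            for di, dj, vec in _NEIGHBOURS:
                ii, jj = i + di, j + dj
                if not 0 <= ii < ni:
                    continue
                if not 0 <= jj < nj:
                    if not wrap_lon:
                        continue
                    jj %= nj
                if land_mask[ii, jj]:
                    normal += np.asarray(vec)
                    # N/S neighbour shares a zonal edge, E/W a meridional one
                    length += zonal_edge if di != 0 else meridional_edge
            norm = np.hypot(*normal)
            if norm == 0.0 or length == 0.0:
                continue
            cells.append(
                CoastalCell(
                    i=i,
                    j=j,
                    lat=float(lat[i]),
                    lon=float(lon[j]),
                    normal=(float(normal[0] / norm), float(normal[1] / norm)),
                    segment_length=float(length),
                )
            )
    return cells


@dataclass
class UpwellingResult:
    """Per-cell Ekman fluxes and their global integrals."""

    table: pd.DataFrame  # one row per coastal cell
    total_upwelling: float  # kg/s, sum of positive (upwelling) fluxes
    total_downwelling: float  # kg/s, sum of negative fluxes (<= 0)
    n_equatorial_skipped: int
    rho: float = RHO_SEAWATER

    @property
    def total_upwelling_Sv(self) -> float:
        """Volume-equivalent total (Sv), dividing the mass flux by rho."""
        return self.total_upwelling / self.rho / SV

    @property
    def total_upwelling_Gkg(self) -> float:
        """Total coastal upwelling in 1e9 kg/s."""
        return self.total_upwelling / 1.0e9

    def summary(self) -> str:
        return (
            f"coastal cells: {len(self.table)} (+{self.n_equatorial_skipped} equatorial skipped)\n"
            f"total coastal upwelling: {self.total_upwelling:.4e} kg/s"
            f" = {self.total_upwelling_Gkg:.4f} x 1e9 kg/s = {self.total_upwelling_Sv:.4f} Sv\n"
            f"total coastal downwelling: {self.total_downwelling:.4e} kg/s"
        )


def coastal_upwelling_flux(field: WindField, lat_min: float = 5.0) -> UpwellingResult:
    """Coastal Ekman upwelling mass flux per cell and its global integral.

    For each coastal cell poleward of ``lat_min``: the offshore Ekman mass
    transport per unit coastline is ``(tau x z_hat) . n_hat / f`` =
    ``tau . t_hat / f`` with ``t_hat`` the along-shore unit vector (offshore
    normal rotated 90 deg counter-clockwise); the cell flux is that times the
    coastline segment length. Positive values (offshore transport, i.e.
    upwelling) are summed into ``total_upwelling``; negative values are
    recorded as downwelling and kept out of the upwelling integral.
    """
    cells = coastal_cells(field.land_mask, field.lat, field.lon)
    rows = []
    skipped = 0
    for c in cells:
        if abs(c.lat) < lat_min:
            skipped += 1
            continue
        f = coriolis(c.lat, field.omega)
        nx, ny = c.normal
        # along-shore unit vector: offshore normal rotated +90 deg (CCW)
        tx, ty = -ny, nx
        tau_along = field.tau_x[c.i, c.j] * tx + field.tau_y[c.i, c.j] * ty
        transport = tau_along / f  # kg s-1 m-1, offshore when positive
        flux = transport * c.segment_length
        rows.append(
            {
                "lat": c.lat,
                "lon": c.lon,
                "normal_east": nx,
                "normal_north": ny,
                "segment_length": c.segment_length,
                "tau_along": tau_along,
                "transport_per_m": transport,
                "flux_kg_s": flux,
                "upwelling": flux > 0,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "lat",
            "lon",
            "normal_east",
            "normal_north",
            "segment_length",
            "tau_along",
            "transport_per_m",
            "flux_kg_s",
            "upwelling",
        ],
    )
    if len(table):
        up = float(table.loc[table["flux_kg_s"] > 0, "flux_kg_s"].sum())
        down = float(table.loc[table["flux_kg_s"] < 0, "flux_kg_s"].sum())
    else:
        up = down = 0.0
    return UpwellingResult(
        table=table,
        total_upwelling=up,
        total_downwelling=down,
        n_equatorial_skipped=skipped,
        rho=field.rho,
    )
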
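"""Composite sediment records and derived statistics.

Builds composite delta15N / delta13C records from per-site series and
computes the derived quantities used to interpret them: splice diagnostics,
organic-carbon accumulation rates, the deep-vs-distal delta15N gap
(Delta15N), the nitrate deficit N*, fixed-width age binning, and windowed
correlations between proxies.

Ages are in Ma before present, increasing into the past; every series is
stored in that orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SedimentRecord",
    "CompositeRecord",
    "SpliceDiagnostic",
    "splice_records",
    "corg_accumulation",
    "delta15N_gap",
    "nstar",
    "bin_series",
    "windowed_correlation",
    "record_statistics",
    "ENVIRONMENTS",
]

ENVIRONMENTS = ("deep-margin", "distal")

#: canonical per-sample columns of a sediment record table
RECORD_COLUMNS = [
    "site",
    "environment",
    "age",
    "d15N",
    "d13C_org",
    "TOC",
    "sed_rate",
    "dry_bulk_density",
]


@dataclass
class SedimentRecord:
    """Per-site dated series of bulk-sediment measurements.

    ``data`` rows carry (age [Ma], d15N [permil vs AIR], d13C_org [permil vs
    VPDB], TOC [wt%], sed_rate [cm/kyr], dry_bulk_density [g/cm3]); missing
    measurements are NaN. Ages must be strictly increasing within the site.
    """

    site: str
    environment: str
    data: pd.DataFrame
    #: True when dry_bulk_density was filled with the 1.0 g/cm3 default
    density_defaulted: bool = False

    def __post_init__(self) -> None:
        if self.environment not in ENVIRONMENTS:
            raise ValueError(
                f"environment must be one of {ENVIRONMENTS}, got {self.environment!r}"
            )
        df = self.data.copy()
        missing = {"age", "d15N"} - set(df.columns)
        if missing:
            raise ValueError(f"record {self.site!r} is missing columns {sorted(missing)}")
        if "dry_bulk_density" not in df.columns:
            df["dry_bulk_density"] = 1.0
            self.density_defaulted = True
        ages = df["age"].to_numpy()
        if np.any(~np.isfinite(ages)):
            raise ValueError(f"record {self.site!r} has non-finite ages")
        if np.any(np.diff(ages) <= 0):
            raise ValueError(f"ages are not strictly increasing within site {self.site!r}")
        if "TOC" in df.columns and np.nanmin(df["TOC"].to_numpy(dtype=float)) < 0:
            raise ValueError(f"record {self.site!r} has negative TOC")
        self.data = df.reset_index(drop=True)

    @property
    def age_span(self) -> tuple[float, float]:
        a = self.data["age"]
        return float(a.iloc[0]), float(a.iloc[-1])

    def corg_accumulation(self) -> pd.Series:
        """Organic-carbon accumulation rate per sample (g C/kyr/cm2)."""
        d = self.data
        return corg_accumulation(d["TOC"], d["sed_rate"], d["dry_bulk_density"])


@dataclass
class SpliceDiagnostic:
    """Mean delta15N offset between two sites over their age overlap."""

    site_a: str
    site_b: str
    overlap: tuple[float, float]
    mean_offset: float
    n_pairs: int
    flagged: bool


@dataclass
class CompositeRecord:
    """Age-sorted multi-site composite for one environment class."""

    environment: str
    data: pd.DataFrame  # columns: age, value, site (+ passthrough)
    diagnostics: list[SpliceDiagnostic] = field(default_factory=list)

    @property
    def age_span(self) -> tuple[float, float]:
        a = self.data["age"]
        return float(a.min()), float(a.max())

    def split_by_site(self) -> dict[str, pd.DataFrame]:
        return {site: g.drop(columns="site") for site, g in self.data.groupby("site", sort=False)}


def _pair_by_age(age_a, val_a, age_b, val_b, tolerance):
    """Nearest-within-tolerance pairing of two age series (brute O(n log n))."""
    order = np.argsort(age_b)
    age_b_sorted = np.asarray(age_b)[order]
    val_b_sorted = np.asarray(val_b)[order]
    idx = np.searchsorted(age_b_sorted, age_a)
    pairs = []
    for i, a in enumerate(np.asarray(age_a)):
        candidates = [j for j in (idx[i] - 1, idx[i]) if 0 <= j < len(age_b_sorted)]
        if not candidates:
            continue
        j = min(candidates, key=lambda j: abs(age_b_sorted[j] - a))
        if abs(age_b_sorted[j] - a) <= tolerance:
            pairs.append((val_a[i], val_b_sorted[j]))
    return np.array(pairs, dtype=float).reshape(-1, 2)


def splice_records(
    records: Sequence[SedimentRecord],
    overlap_tol: float = 0.5,
    value: str = "d15N",
    pair_tolerance: float = 2.0,
) -> CompositeRecord:
    """Concatenate same-environment site records into an age-sorted composite.

    For each temporally overlapping site pair the mean ``value`` offset over
    the overlap is computed (nearest-age pairing within ``pair_tolerance``
    Ma); offsets exceeding ``overlap_tol`` (permil) are flagged in the
    diagnostics but never corrected -- the composite keeps the raw values.
    """
    if not records:
        raise ValueError("need at least one record to splice")
    envs = {r.environment for r in records}
    if len(envs) > 1:
        raise ValueError(f"cannot splice across environment classes: {sorted(envs)}")

    frames = []
    for r in records:
        df = r.data.copy()
        df["site"] = r.site
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True).sort_values(
        ["age", "site"], kind="mergesort"
    )
    merged = merged.rename(columns={value: "value"})
    keep = ["age", "value", "site"] + [
        c for c in merged.columns if c not in ("age", "value", "site")
    ]
    merged = merged[keep].reset_index(drop=True)

    diagnostics: list[SpliceDiagnostic] = []
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            lo = max(a.age_span[0], b.age_span[0])
            hi = min(a.age_span[1], b.age_span[1])
            if lo > hi:
                continue
            sel_a = a.data[(a.data["age"] >= lo) & (a.data["age"] <= hi)]
            sel_b = b.data[(b.data["age"] >= lo) & (b.data["age"] <= hi)]
            pairs = _pair_by_age(
                sel_a["age"].to_numpy(),
                sel_a[value].to_numpy(),
                sel_b["age"].to_numpy(),
                sel_b[value].to_numpy(),
                pair_tolerance,
            )
            pairs = pairs[np.all(np.isfinite(pairs), axis=1)]
            if len(pairs) == 0:
                continue
            offset = float(np.mean(pairs[:, 0] - pairs[:, 1]))
            diagnostics.append(
                SpliceDiagnostic(
                    site_a=a.site,
                    site_b=b.site,
                    overlap=(float(lo), float(hi)),
                    mean_offset=offset,
                    n_pairs=len(pairs),
                    flagged=abs(offset) > overlap_tol,
                )
            )
    return CompositeRecord(
        environment=records[0].environment, data=merged, diagnostics=diagnostics
    )


def corg_accumulation(TOC_wt_pct, sed_rate_cm_per_kyr, dry_bulk_density_g_cm3=1.0):
    """Organic-carbon accumulation rate, (TOC/100) * density * sed rate.

    Units: wt% * g/cm3 * cm/kyr -> g C/kyr/cm2.
    """
    TOC = np.asarray(TOC_wt_pct, dtype=float)
    rate = np.asarray(sed_rate_cm_per_kyr, dtype=float)
    rho = np.asarray(dry_bulk_density_g_cm3, dtype=float)
    if np.nanmin(TOC, initial=0.0) < 0 or np.nanmin(rate, initial=0.0) < 0:
        raise ValueError("TOC and sedimentation rate must be non-negative")
    if np.nanmin(rho, initial=0.0) < 0:
        raise ValueError("dry bulk density must be non-negative")
    out = TOC / 100.0 * rho * rate
    return float(out) if np.ndim(out) == 0 else out


def delta15N_gap(
    deep: CompositeRecord,
    distal: CompositeRecord,
    age_grid,
    max_gap: float = 10.0,
) -> pd.DataFrame:
    """Delta15N(age) = delta15N_DISTAL - delta15N_DEEP on a common age grid.

    Both composites are linearly interpolated in age onto ``age_grid``
    (Ma). Grid points outside either record's span, or bridging a data gap
    wider than ``max_gap`` Myr in either record, are masked (NaN). The sign
    convention makes Delta15N >= 0 when the distal record is heavier.
    """
    age_grid = np.asarray(age_grid, dtype=float)

    def interp(rec: CompositeRecord):
        d = rec.data.dropna(subset=["value"]).sort_values("age")
        ages = d["age"].to_numpy()
        vals = d["value"].to_numpy()
        if len(ages) == 0:
            raise ValueError(f"composite ({rec.environment}) has no finite values")
        y = np.interp(age_grid, ages, vals)
        mask = (age_grid < ages[0]) | (age_grid > ages[-1])
        # mask grid points that would bridge a gap wider than max_gap
        if len(ages) > 1:
            right = np.searchsorted(ages, age_grid, side="left").clip(1, len(ages) - 1)
            gap = ages[right] - ages[right - 1]
            inside = ~mask
            mask |= inside & (gap > max_gap)
        return np.where(mask, np.nan, y)

    deep_i = interp(deep)
    distal_i = interp(distal)
    gap = distal_i - deep_i
    if not np.any(np.isfinite(gap)):
        raise ValueError("age grid has no overlap with both composites")
    return pd.DataFrame({"age": age_grid, "delta15N": gap})


def nstar(NO3, PO4):
    """N* = NO3 - 16*PO4 (mmol N/m3), the nitrate deficit vs Redfield."""
    NO3 = np.asarray(NO3, dtype=float)
    PO4 = np.asarray(PO4, dtype=float)
    if np.nanmin(NO3, initial=0.0) < 0 or np.nanmin(PO4, initial=0.0) < 0:
        raise ValueError("concentrations must be non-negative")
    out = NO3 - 16.0 * PO4
    return float(out) if out.ndim == 0 else out


def bin_series(ages, values, bin_width: float = 5.0) -> pd.DataFrame:
    """Bin a series into fixed-width age bins anchored at age 0.

    Returns one row per bin covering the data span, including empty bins
    (n = 0); SD is NaN ("undefined") for n < 2. Bin centres are at
    ``(k + 1/2) * bin_width``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(ages) & np.isfinite(values)
    ages, values = ages[ok], values[ok]
    if len(ages) == 0:
        return pd.DataFrame(columns=["bin_centre", "mean", "sd", "n"])
    idx = np.floor(ages / bin_width).astype(int)
    rows = []
    for k in range(idx.min(), idx.max() + 1):
        sel = values[idx == k]
        rows.append(
            {
                "bin_centre": (k + 0.5) * bin_width,
                "mean": float(np.mean(sel)) if len(sel) else np.nan,
                "sd": float(np.std(sel, ddof=1)) if len(sel) >= 2 else np.nan,
                "n": int(len(sel)),
            }
        )
    return pd.DataFrame(rows)


def windowed_correlation(
    x_series: pd.DataFrame,
    y_series: pd.DataFrame,
    windows: Iterable[tuple[float, float]] = ((28.0, 165.0), (0.0, 28.0)),
    pair_tolerance: float = 2.0,
    min_n: int = 4,
) -> pd.DataFrame:
    """Pearson correlation between two age series within age windows.

    Series are tables with columns (age, value); points are paired by
    nearest age within ``pair_tolerance`` Ma. Windows are (min_age, max_age)
    intervals in Ma; the default partition separates the last 28 Myr from
    the older record. Windows with fewer than ``min_n`` pairs are marked
    insufficient (r, sign NaN/empty) rather than raising.
    """
    out = []
    xa = x_series["age"].to_numpy(dtype=float)
    xv = x_series["value"].to_numpy(dtype=float)
    ya = y_series["age"].to_numpy(dtype=float)
    yv = y_series["value"].to_numpy(dtype=float)
    for lo, hi in windows:
        sel = (xa >= lo) & (xa <= hi) & np.isfinite(xv)
        pairs = _pair_by_age(xa[sel], xv[sel], ya, yv, pair_tolerance)
        pairs = pairs[np.all(np.isfinite(pairs), axis=1)]
        n = len(pairs)
        if n < min_n or np.std(pairs[:, 0]) == 0 or np.std(pairs[:, 1]) == 0:
            out.append(
                {"age_min": lo, "age_max": hi, "r": np.nan, "n": n,
                 "sign": "", "sufficient": False}
            )
            continue
        r = float(stats.pearsonr(pairs[:, 0], pairs[:, 1]).statistic)
        out.append(
            {
                "age_min": lo,
                "age_max": hi,
                "r": r,
                "n": n,
                "sign": "negative" if r < 0 else ("positive" if r > 0 else "zero"),
                "sufficient": True,
            }
        )
    return pd.DataFrame(out)


def record_statistics(
    deep: CompositeRecord,
    distal: CompositeRecord,
    pleistocene_max_age: float = 2.58,
    interval_halfwidth: float = 2.8,
) -> dict:
    """Summary statistics of the composite delta15N records.

    Returns the deep/distal means and SDs, the deep median, the fraction of
    deep points outside +-``interval_halfwidth`` permil of the median, and
    the mean over the Pleistocene-to-recent interval (both classes pooled).
    """
    dv = deep.data["value"].dropna().to_numpy()
    xv = distal.data["value"].dropna().to_numpy()
    med = float(np.median(dv))
    frac_out = float(np.mean(np.abs(dv - med) > interval_halfwidth))
    recent = np.concatenate(
        [
            deep.data.loc[deep.data["age"] <= pleistocene_max_age, "value"].dropna(),
            distal.data.loc[distal.data["age"] <= pleistocene_max_age, "value"].dropna(),
        ]
    )
    return {
        "deep_mean": float(np.mean(dv)),
        "deep_sd": float(np.std(dv, ddof=1)),
        "deep_median": med,
        "deep_frac_outside": frac_out,
        "distal_mean": float(np.mean(xv)),
        "distal_sd": float(np.std(xv, ddof=1)),
        "pleistocene_recent_mean": float(np.mean(recent)) if len(recent) else np.nan,
        "n_deep": int(len(dv)),
        "n_distal": int(len(xv)),
    }
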
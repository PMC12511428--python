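"""Table/grid readers and writers, configuration, and run manifests.

CSV dialect: comma-separated, UTF-8, ``.`` decimal separator, mandatory
header row, missing values as empty fields. Floats are written at 6
significant digits by default so that repeated runs diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import ModelParams
from .records import RECORD_COLUMNS, SedimentRecord

__all__ = [
    "read_record_table",
    "write_record_table",
    "read_config",
    "params_from_config",
    "write_results",
    "RunManifest",
]

#: required columns of a sediment-record CSV
REQUIRED_COLUMNS = ("site", "environment", "age", "d15N")

#: maps alternative (deposit-style) column names onto the canonical schema;
#: extend here once the published tables' exact headers are known
COLUMN_SYNONYMS = {
    "Site": "site",
    "Environment": "environment",
    "age_Ma": "age",
    "Age (Ma)": "age",
    "d15N_permil": "d15N",
    "δ15N": "d15N",
    "d13Corg": "d13C_org",
    "δ13C_ORG": "d13C_org",
    "TOC_wt_pct": "TOC",
    "TOC (wt%)": "TOC",
    "sed_rate_cm_kyr": "sed_rate",
    "DBD": "dry_bulk_density",
}


def read_record_table(path) -> list[SedimentRecord]:
    """Read a sediment-record CSV into per-site :class:`SedimentRecord` objects.

    Unknown columns are preserved as passthrough metadata. Raises with the
    offending column/site named on missing required columns or non-monotone
    ages.
    """
    df = pd.read_csv(path)
    df = df.rename(columns=COLUMN_SYNONYMS)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table {path} is missing required column(s): {missing}")
    records = []
    for site, g in df.groupby("site", sort=False):
        envs = g["environment"].unique()
        if len(envs) != 1:
            raise ValueError(f"site {site!r} has inconsistent environment labels: {envs}")
        g = g.sort_values("age", kind="mergesort").drop(columns=["site", "environment"])
        ages = g["age"].to_numpy(dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ValueError(f"ages are not strictly increasing within site {site!r}")
        records.append(
            SedimentRecord(site=str(site), environment=str(envs[0]), data=g.reset_index(drop=True))
        )
    return records


def write_record_table(records: list[SedimentRecord], path, float_digits: int = 6) -> None:
    """Write records to CSV in the canonical column order."""
    frames = []
    for r in records:
        df = r.data.copy()
        df.insert(0, "environment", r.environment)
        df.insert(0, "site", r.site)
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    ordered = [c for c in RECORD_COLUMNS if c in merged.columns]
    extra = [c for c in merged.columns if c not in ordered]
    write_results(merged[ordered + extra], path, float_digits=float_digits)


def write_results(
    table: pd.DataFrame,
    path,
    float_digits: int = 6,
    allow_empty: bool = False,
    manifest: "RunManifest | None" = None,
) -> Path:
    """Write a tidy CSV with stable column order and fixed float formatting.

    Missing values become empty fields (undefined markers never appear as
    'nan' text). Empty tables are rejected unless ``allow_empty`` (which
    writes a header-only file).
    """
    path = Path(path)
    if len(table) == 0 and not allow_empty:
        raise ValueError("refusing to write an empty table (pass allow_empty=True)")
    table.to_csv(path, index=False, float_format=f"%.{float_digits}g", na_rep="")
    if manifest is not None:
        manifest.add_output(path)
    return path


def read_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping at the top level")
    return cfg


def params_from_config(cfg: dict) -> ModelParams:
    """Build :class:`ModelParams` from a config mapping (field names 1:1)."""
    unknown = set(cfg) - set(ModelParams.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown model parameter(s) in config: {sorted(unknown)}")
    return ModelParams(**cfg)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI invocation."""

    command: str
    config_hash: str = ""
    seeds: list[int] = field(default_factory=list)
    version: str = __version__
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    @classmethod
    def start(cls, command: str, config: dict | None = None, seeds=(), inputs=()) -> "RunManifest":
        cfg_hash = (
            hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest()
            if config is not None
            else ""
        )
        m = cls(command=command, config_hash=cfg_hash, seeds=list(seeds))
        for p in inputs:
            m.add_input(p)
        return m

    def add_input(self, path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _digest(p)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> Path:
        self.finished = time.time()
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path
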
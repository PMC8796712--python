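"""Readers/writers for the EcoTaxa-dialect object table and CTD CSV,
plus the run configuration.

The object-table dialect is tab-separated UTF-8 with a header row and the
required columns ``object_id, sample_id, taxon, area_mm2, major_mm,
minor_mm, split_fraction, status, multiple_flag``.  Split fractions are
stored as strings ("1", "1/2", …, "1/64") to avoid floating-point round-off
of binary fractions; unknown columns round-trip unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

REQUIRED_OBJECT_COLUMNS = (
    "object_id",
    "sample_id",
    "taxon",
    "area_mm2",
    "major_mm",
    "minor_mm",
    "split_fraction",
    "status",
    "multiple_flag",
)

VALID_STATUS = {"validated", "bad_focus", "junk_category"}

CTD_REQUIRED_COLUMNS = (
    "depth_m",
    "temperature_C",
    "salinity_psu",
    "oxygen_umol_kg",
    "pH",
    "chla_mg_m3",
)

_ALLOWED_SPLITS = {"1"} | {f"1/{2**k}" for k in range(1, 7)}


@dataclass
class ObjectTableReport:
    """Row-level problems found while reading an object table."""

    n_rows: int = 0
    n_rejected: int = 0
    problems: list[str] = field(default_factory=list)


def parse_split_fraction(text: str) -> Fraction:
    """Parse "1/64"-style split fractions; only 2^-k, k = 0..6, are valid."""
    text = str(text).strip()
    if text not in _ALLOWED_SPLITS:
        raise ValueError(
            f"split fraction {text!r} is not a binary fraction 1 .. 1/64"
        )
    return Fraction(text)


def read_object_table(
    path: str | Path,
) -> tuple[pd.DataFrame, ObjectTableReport]:
    """Read an EcoTaxa-dialect TSV.

    Missing required columns raise immediately; malformed rows (unparseable
    split fraction, unknown status, duplicate object id) are collected into
    the returned report and excluded from the table rather than silently
    dropped.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"split_fraction": str},
        float_precision="round_trip",
    )
    missing = set(REQUIRED_OBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"object table {path} missing required column(s): {sorted(missing)}"
        )
    report = ObjectTableReport(n_rows=len(df))
    bad = np.zeros(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            parse_split_fraction(row.split_fraction)
        except ValueError as exc:
            bad[i] = True
            report.problems.append(f"row {i}: {exc}")
            continue
        if row.status not in VALID_STATUS:
            bad[i] = True
            report.problems.append(f"row {i}: unknown status {row.status!r}")
    dup = df["object_id"].duplicated(keep="first").to_numpy()
    for i in np.flatnonzero(dup & ~bad):
        report.problems.append(f"row {i}: duplicate object_id {df['object_id'].iat[i]!r}")
    bad |= dup
    report.n_rejected = int(bad.sum())
    out = df.loc[~bad].copy()
    out["multiple_flag"] = out["multiple_flag"].astype(bool)
    return out, report


def write_object_table(objects: pd.DataFrame, path: str | Path) -> Path:
    """Write the object table in the TSV dialect (UTF-8, header row)."""
    path = Path(path)
    missing = set(REQUIRED_OBJECT_COLUMNS) - set(objects.columns)
    if missing:
        raise ValueError(f"cannot write table missing column(s): {sorted(missing)}")
    out = objects.copy()
    out["multiple_flag"] = out["multiple_flag"].astype(bool)
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def read_ctd_csv(path: str | Path) -> pd.DataFrame:
    """Read a CTD cast CSV; rows are depth-sorted and duplicate depths averaged."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"CTD file {path} is empty")
    missing = set(CTD_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CTD file {path} missing column(s): {sorted(missing)}")
    df = df.groupby("depth_m", as_index=False).mean().sort_values("depth_m")
    return df.reset_index(drop=True)


@dataclass
class RunConfig:
    """Pipeline configuration with documented defaults for every toggle."""

    out_dir: str = "zooscankit_out"
    seed: int = 0
    max_integration_depth: float = 400.0
    pooling_threshold: float = 0.03
    log_base: float = float(np.e)
    n_permutations: int = 10_000
    simper_cutoff: float = 0.70
    detection_measure: str = "ecd"  # or "major"
    include_bad_focus: bool = False  # blurred vignettes excluded by default
    substitution_scope: str = "sample"  # same-sample mean, global fallback
    predictor_scope: str = "cast_mean"  # or "stratum_mean"

    def __post_init__(self) -> None:
        if self.detection_measure not in ("ecd", "major"):
            raise ValueError("detection_measure must be 'ecd' or 'major'")
        if self.predictor_scope not in ("cast_mean", "stratum_mean"):
            raise ValueError("predictor_scope must be 'cast_mean' or 'stratum_mean'")
        if self.substitution_scope not in ("sample", "global"):
            raise ValueError("substitution_scope must be 'sample' or 'global'")
        if not (0 <= self.pooling_threshold < 1):
            raise ValueError("pooling_threshold must be in [0, 1)")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)
        return path
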
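"""Delimited-text and JSON input/output.

Count tables are long-format with columns ``time_days``, ``field_id``,
``count``; biomarker tables have ``subject_id``, ``group``,
``value_pg_ml``.  The delimiter is auto-detected (comma or tab).  Every
generated output can carry a sidecar JSON manifest recording the seed and
parameters that produced it.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any

import pandas as pd

from .fitting import BootstrapInterval, FitResult, NecrosisTimeCourse
from .stats import BiomarkerDataset

__all__ = [
    "SchemaError",
    "read_timecourse",
    "write_timecourse",
    "read_biomarker_table",
    "write_biomarker_table",
    "write_fit_report",
    "read_fit_report",
    "write_manifest",
]


class SchemaError(ValueError):
    """A delimited input violates the expected table schema."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def _read_table(path: str | Path, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}, line 1: missing required column(s) {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    bad = df[list(required)].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise SchemaError(f"{path}, line {line}: missing value in required column")
    return df


def read_timecourse(path: str | Path) -> NecrosisTimeCourse:
    """Read a long-format active-necrosis count table (CSV or TSV)."""
    df = _read_table(path, {"time_days", "field_id", "count"})
    try:
        return NecrosisTimeCourse(records=df)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_timecourse(tc: NecrosisTimeCourse, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tc.records.to_csv(path, index=False)


def read_biomarker_table(path: str | Path) -> BiomarkerDataset:
    """Read a subject-level biomarker table (CSV or TSV)."""
    df = _read_table(path, {"subject_id", "group", "value_pg_ml"})
    try:
        return BiomarkerDataset(records=df)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_biomarker_table(ds: BiomarkerDataset, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ds.records.to_csv(path, index=False)


def write_fit_report(
    fit: FitResult,
    path: str | Path,
    bootstrap: BootstrapInterval | None = None,
    extra: dict[str, Any] | None = None,
) -> None:
    """Write a fit (and optional bootstrap intervals) as a JSON report."""
    report = fit.to_dict()
    if bootstrap is not None:
        report["bootstrap"] = {
            "level": bootstrap.level,
            "replicates": bootstrap.replicates,
            "seed": bootstrap.seed,
            "intervals": {
                k: [lo, hi] for k, (lo, hi) in bootstrap.intervals.items()
            },
        }
    if extra:
        report.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_fit_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def write_manifest(path: str | Path, **entries: Any) -> None:
    """Sidecar JSON manifest (seed, parameters, provenance) for an output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(entries, indent=2, sort_keys=True, default=str) + "\n")
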
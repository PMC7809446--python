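"""Readers and writers for the pipeline's plain-text formats.

Dialects: UTF-8 throughout; TSV for protein tables (abundance matrices,
annotations, correlation reports) with a mandatory header row starting
with ``protein_id``; CSV for assay data; JSON for reports and manifests;
YAML (or JSON) for configuration. Fraction columns are labelled ``F<k>``.
Missing numeric values are written and read as ``NA``. Ragged rows raise a
parse error naming the offending line.
"""

from __future__ import annotations

import csv
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assay import ActivityProfile, AssayCounts
from .curation import ANNOTATION_COLUMNS, CurationResult
from .gradient import ProfileMatrix

__all__ = [
    "ParseError",
    "write_profile_matrix",
    "read_profile_matrix",
    "write_activity",
    "read_activity",
    "write_assay_counts",
    "read_assay_counts",
    "write_annotations",
    "read_annotations",
    "write_correlation_report",
    "read_correlation_report",
    "write_curation_json",
    "read_curation_json",
    "write_json",
    "load_config",
]

NA = "NA"


class ParseError(ValueError):
    """A file does not conform to the documented dialect."""


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    """Strict delimited-text reader: header required, rows must be rectangular."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    rows = [r for r in rows if r]  # ignore blank lines
    if not rows:
        raise ParseError(f"{path}: empty file, header row required")
    width = len(rows[0])
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {lineno}: expected {width} fields, got {len(row)}"
            )
    buf = _io.StringIO()
    csv.writer(buf, delimiter=delimiter, lineterminator="\n").writerows(rows)
    buf.seek(0)
    return pd.read_csv(buf, sep=delimiter, na_values=[NA], keep_default_na=False)


# ---------------------------------------------------------------- profiles

def write_profile_matrix(pm: ProfileMatrix, path: str | Path) -> None:
    """TSV with columns ``protein_id`` then ``F<k>`` per fraction."""
    df = pm.data.copy()
    df.columns = [f"F{int(c)}" for c in df.columns]
    df.to_csv(path, sep="\t", na_rep=NA, float_format="%.10g")


def read_profile_matrix(path: str | Path, replicate_id: str | None = None) -> ProfileMatrix:
    df = _read_table(path, "\t")
    if df.columns[0] != "protein_id":
        raise ParseError(f"{path}: first column must be 'protein_id', got {df.columns[0]!r}")
    fracs = []
    for c in df.columns[1:]:
        if not (isinstance(c, str) and c.startswith("F") and c[1:].isdigit()):
            raise ParseError(f"{path}: fraction column {c!r} does not match 'F<k>'")
        fracs.append(int(c[1:]))
    data = df.set_index("protein_id")
    data.columns = fracs
    rep = replicate_id if replicate_id is not None else Path(path).stem
    return ProfileMatrix(data.astype(float), rep)


# ---------------------------------------------------------------- activity

def write_activity(ap: ActivityProfile, path: str | Path) -> None:
    """CSV with columns fraction, replicate, value, readout_type."""
    df = ap.data.copy()
    df["readout_type"] = ap.readout
    df.to_csv(path, index=False, na_rep=NA, float_format="%.10g")


def read_activity(path: str | Path) -> ActivityProfile:
    df = _read_table(path, ",")
    required = ["fraction", "replicate", "value", "readout_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    readouts = set(df["readout_type"].unique())
    if len(readouts) != 1:
        raise ParseError(f"{path}: mixed readout types {sorted(readouts)}")
    ap = ActivityProfile(
        df[["fraction", "replicate", "value"]].astype(
            {"fraction": int, "replicate": int, "value": float}
        ),
        readout=readouts.pop(),
    )
    return ap


# ------------------------------------------------------------ assay counts

def write_assay_counts(df: pd.DataFrame, path: str | Path) -> None:
    """CSV rows: sample_id, condition, P_cpm, S_cpm."""
    df[["sample_id", "condition", "P_cpm", "S_cpm"]].to_csv(
        path, index=False, na_rep=NA, float_format="%.10g"
    )


def read_assay_counts(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, ",")
    required = ["sample_id", "condition", "P_cpm", "S_cpm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df.astype({"P_cpm": float, "S_cpm": float})


def counts_to_triplets(df: pd.DataFrame) -> dict[str, dict[str, AssayCounts]]:
    """Group an assay-counts table into per-sample condition triplets."""
    out: dict[str, dict[str, AssayCounts]] = {}
    for (sample, cond), sub in df.groupby(["sample_id", "condition"]):
        if len(sub) != 1:
            raise ParseError(
                f"duplicate row for sample {sample!r}, condition {cond!r}"
            )
        row = sub.iloc[0]
        out.setdefault(str(sample), {})[str(cond)] = AssayCounts(
            str(cond), float(row["P_cpm"]), float(row["S_cpm"])
        )
    return out


# ------------------------------------------------------------- annotations

def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    """TSV: protein_id, essential (0/1), tm_spans, localization."""
    out = df[ANNOTATION_COLUMNS].copy()
    out["essential"] = out["essential"].astype(bool).astype(int)
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, "\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df["essential"] = df["essential"].astype(int).astype(bool)
    df["tm_spans"] = df["tm_spans"].astype(int)
    df["localization"] = df["localization"].fillna("unknown").astype(str)
    return df[ANNOTATION_COLUMNS]


# ------------------------------------------------------------ correlations

def write_correlation_report(records: pd.DataFrame, path: str | Path) -> None:
    """TSV: protein_id, per-replicate R columns, r_mean, r_sd, n_defined."""
    records.to_csv(path, sep="\t", na_rep=NA, float_format="%.10g")


def read_correlation_report(path: str | Path) -> pd.DataFrame:
    """Read a correlation report (ours, or any table with protein_id + r_mean).

    Also the import path for externally supplied per-protein correlation
    scores, e.g. a supplementary table exported to TSV.
    """
    df = _read_table(path, "\t")
    if "protein_id" not in df.columns or "r_mean" not in df.columns:
        raise ParseError(f"{path}: need at least columns protein_id and r_mean")
    return df.set_index("protein_id")


# ------------------------------------------------------------------- JSON

def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def write_curation_json(result: CurationResult, path: str | Path) -> None:
    write_json(result.to_dict(), path)


def read_curation_json(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# ------------------------------------------------------------------ config

def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) configuration file into a dict."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParseError(f"{path}: malformed config: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping at top level")
    return cfg
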
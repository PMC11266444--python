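"""CSV schema and validated round-trip I/O for the long visit table and
the baseline table.

Column schemas are documented in ``docs/schema.md``.  Files are RFC-4180
CSV, UTF-8, with a header row; unknown columns are preserved on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .survival import VALID_CDR_GS

VISIT_COLUMNS = ("id", "week", "measure", "value", "test_version")
BASELINE_COLUMNS = (
    "id", "arm", "age", "female", "education", "apoe4_carrier", "urg_member",
    "amyloid_cl", "amyloid_suvr", "ptau217", "tau_neocortical_suvr",
    "baseline_pacc", "baseline_cfi",
)

KNOWN_MEASURES = ("PACC", "CFI_combined", "ADL_partner", "CDR_SB", "CDR_GS")

_RANGES = {"CFI_combined": (0.0, 30.0), "ADL_partner": (0.0, 45.0), "CDR_SB": (0.0, 18.0)}


class SchemaError(ValueError):
    """CSV content violating the documented schema; names row and column."""


def write_visits_csv(visits: pd.DataFrame, path) -> None:
    visits.to_csv(path, index=False)


def write_baseline_csv(baseline: pd.DataFrame, path) -> None:
    baseline.to_csv(path, index=False)


def _validate_visits(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VISIT_COLUMNS if c not in df.columns and c != "test_version"]
    if missing:
        raise SchemaError(f"visit table missing required column(s) {missing}")
    if df.empty:
        return df
    df = df.copy()
    df["week"] = pd.to_numeric(df["week"], errors="coerce")
    bad = df.index[df["week"].isna()]
    if len(bad):
        raise SchemaError(f"row {bad[0] + 2}: column 'week' is not numeric")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    gs = df["measure"] == "CDR_GS"
    bad_gs = df.index[gs & ~df["value"].isin(VALID_CDR_GS)]
    if len(bad_gs):
        r = bad_gs[0]
        raise SchemaError(
            f"row {r + 2}: column 'value': CDR_GS rating {df.loc[r, 'value']!r} "
            f"not in {sorted(VALID_CDR_GS)}"
        )
    for measure, (lo, hi) in _RANGES.items():
        m = df["measure"] == measure
        bad_m = df.index[m & ((df["value"] < lo) | (df["value"] > hi))]
        if len(bad_m):
            r = bad_m[0]
            raise SchemaError(
                f"row {r + 2}: column 'value': {measure} value {df.loc[r, 'value']} "
                f"outside [{lo}, {hi}]"
            )
    dup = df.duplicated(subset=["id", "week", "measure"])
    if dup.any():
        raise SchemaError(f"row {df.index[dup][0] + 2}: duplicate (id, week, measure) record")
    return df


def read_long_csv(path) -> pd.DataFrame:
    """Read and validate a long visit table; empty-but-headered files are
    valid and yield an empty table."""
    df = pd.read_csv(path, dtype={"id": str}, keep_default_na=True)
    return _validate_visits(df)


def read_baseline_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in ("id", "arm") if c not in df.columns]
    if missing:
        raise SchemaError(f"baseline table missing required column(s) {missing}")
    for col in ("female", "apoe4_carrier", "urg_member", "in_tau_substudy"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False}).astype("boolean")
    return df
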
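"""Reading and reshaping longitudinal biomarker tables.

Two on-disk layouts are supported, both UTF-8 CSV with a header row and
empty cells for missing values:

- wide per-visit: one row per subject-visit with one column per measure
  (``subject_id, visit_month, cdr_global, suvr, csf_ab42, csf_ptau, pnfl,
  hippocampus, temporal_composite, cdrsb, pacc, ...``) — the layout every
  analysis stage consumes;
- long: ``subject_id, visit_month, measure, value`` — one row per
  observation, pivoted to wide on read.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["read_visits_csv", "long_to_wide", "wide_to_long"]

ID_COLS = ("subject_id", "visit_month")


def long_to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a (subject_id, visit_month, measure, value) table to per-visit rows."""
    required = {*ID_COLS, "measure", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"long table missing columns {sorted(missing)}")
    dup = table.duplicated(subset=["subject_id", "visit_month", "measure"])
    if dup.any():
        raise ValueError(
            "duplicate (subject, visit, measure) observations; "
            "resolve before pivoting"
        )
    wide = (
        table.pivot_table(
            index=list(ID_COLS), columns="measure", values="value", aggfunc="first"
        )
        .reset_index()
    )
    wide.columns.name = None
    return wide


def wide_to_long(table: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide per-visit table to (subject_id, visit_month, measure, value)."""
    value_cols = [c for c in table.columns if c not in ID_COLS]
    long = table.melt(
        id_vars=list(ID_COLS), value_vars=value_cols,
        var_name="measure", value_name="value",
    ).dropna(subset=["value"])
    return long.sort_values(["subject_id", "visit_month", "measure"]).reset_index(
        drop=True
    )


def read_visits_csv(path) -> pd.DataFrame:
    """Read either layout; long tables are detected by their column set."""
    table = pd.read_csv(path)
    missing = set(ID_COLS) - set(table.columns)
    if missing:
        raise ValueError(f"input CSV missing columns {sorted(missing)}")
    if {"measure", "value"}.issubset(table.columns):
        return long_to_wide(table)
    return table
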
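"""CSV schemas and validated readers/writers.

Trial tables carry one row per task trial with the columns of
:data:`beliefupdate.task.TRIAL_COLUMNS`; cohort tables carry one row per
subject with relapse information and any clinical covariates.  Missing values
are empty cells.  Readers validate ranges up front and name the offending row
and field, so malformed exports fail loudly rather than propagating silently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .task import BASE_RATE_RANGE, ESTIMATE_BOUNDS, LIKERT_VARIABLES, TRIAL_COLUMNS

#: Columns a cohort (subject-level) CSV must provide.
COHORT_REQUIRED = ["subject_id", "relapse_month"]


def _read_csv(path: str | Path, required: list[str], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{label} file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{label} file is empty: {path}") from None
    if df.empty:
        raise SchemaError(f"{label} file has a header but no rows: {path}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} file {path} is missing columns: {missing}")
    return df


def _check_range(df: pd.DataFrame, col: str, lo: float, hi: float, path) -> None:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df[col].notna() & vals.isna()
    oob = vals.notna() & ~vals.between(lo, hi)
    problem = bad | oob
    if problem.any():
        row = int(df.index[problem][0]) + 2  # header + 1-based
        raise SchemaError(
            f"{path}: column {col!r} out of range [{lo}, {hi}] or non-numeric "
            f"(first offending file row {row}, value {df[col][problem].iloc[0]!r})"
        )


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-level CSV."""
    df = _read_csv(path, TRIAL_COLUMNS, "trials")
    _check_range(df, "base_rate", *BASE_RATE_RANGE, path)
    for col in ("first_estimate", "second_estimate", "recalled_rate"):
        _check_range(df, col, *ESTIMATE_BOUNDS, path)
    for col in LIKERT_VARIABLES:
        _check_range(df, col, 1, 6, path)
    for col in ("rt_first", "rt_second"):
        _check_range(df, col, 0, np.inf, path)
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject-level CSV (relapse info + covariates)."""
    df = _read_csv(path, COHORT_REQUIRED, "cohort")
    if df["subject_id"].duplicated().any():
        dup = df["subject_id"][df["subject_id"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate subject_id {dup!r}")
    _check_range(df, "relapse_month", np.nextafter(0, 1), np.inf, path)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as CSV (index kept when it is the subject id)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=df.index.name is not None)
    return path
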
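"""Cohort CSV schemas, validated readers and table writers.

Two cohort schemas are supported:

* ``amh``: ``subject_id,age_years,amh_ng_ml,bmi,smoker`` (smoker ∈ {0,1})
* ``menopause``: ``subject_id,age_menopause_years,bmi_category,smoker``
  (bmi_category ∈ {under,normal,over,obese})

Readers validate every row and report all row-level problems together
rather than failing on the first.  Output tables are written at full
float precision; any display rounding happens elsewhere.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .amh import AMH_COLUMNS, PercentileTable
from .menopause import BMI_CATEGORIES, MENOPAUSE_AGE_BOUNDS, MENOPAUSE_COLUMNS

__all__ = [
    "CohortValidationError",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_percentile_table",
    "write_threshold_table",
]


class CohortValidationError(ValueError):
    """Aggregates row-level schema violations for one file."""

    def __init__(self, path, problems: list[str]):
        self.path = str(path)
        self.problems = problems
        preview = "\n  ".join(problems[:20])
        more = f"\n  ... and {len(problems) - 20} more" if len(problems) > 20 else ""
        super().__init__(f"{path}: {len(problems)} invalid value(s):\n  {preview}{more}")


_SCHEMAS = {"amh": AMH_COLUMNS, "menopause": MENOPAUSE_COLUMNS}


def _numeric(df: pd.DataFrame, col: str, problems: list[str]) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    for row in df.index[vals.isna()]:
        problems.append(f"row {row}, column {col!r}: non-numeric value {df.loc[row, col]!r}")
    return vals.to_numpy(float)


def read_cohort_csv(path, schema: str) -> pd.DataFrame:
    """Read and validate a cohort CSV (``schema`` ∈ {'amh', 'menopause'})."""
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    expected = _SCHEMAS[schema]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise CohortValidationError(path, [f"missing column {c!r}" for c in missing])
    if df.empty:
        warnings.warn(f"{path}: header-only file, no records", UserWarning, stacklevel=2)
        return df

    problems: list[str] = []
    if schema == "amh":
        age = _numeric(df, "age_years", problems)
        amh = _numeric(df, "amh_ng_ml", problems)
        bmi = _numeric(df, "bmi", problems)
        smoker = _numeric(df, "smoker", problems)
        for row in df.index[(age <= 0) | (age > 120)]:
            problems.append(f"row {row}: implausible age_years {df.loc[row, 'age_years']!r}")
        for row in df.index[amh <= 0]:
            problems.append(f"row {row}: amh_ng_ml must be positive, got {df.loc[row, 'amh_ng_ml']!r}")
        for row in df.index[bmi <= 10]:
            problems.append(f"row {row}: implausible bmi {df.loc[row, 'bmi']!r}")
        for row in df.index[~np.isin(smoker, (0.0, 1.0))]:
            problems.append(f"row {row}: smoker must be 0 or 1, got {df.loc[row, 'smoker']!r}")
    else:
        age = _numeric(df, "age_menopause_years", problems)
        smoker = _numeric(df, "smoker", problems)
        lo, hi = MENOPAUSE_AGE_BOUNDS
        for row in df.index[(age <= lo) | (age >= hi)]:
            problems.append(
                f"row {row}: age_menopause_years {df.loc[row, 'age_menopause_years']!r} "
                f"outside the accepted range {MENOPAUSE_AGE_BOUNDS}"
            )
        for row in df.index[~df["bmi_category"].isin(BMI_CATEGORIES)]:
            problems.append(
                f"row {row}: bmi_category {df.loc[row, 'bmi_category']!r} "
                f"not in {BMI_CATEGORIES}"
            )
        for row in df.index[~np.isin(smoker, (0.0, 1.0))]:
            problems.append(f"row {row}: smoker must be 0 or 1, got {df.loc[row, 'smoker']!r}")
    if problems:
        raise CohortValidationError(path, problems)
    df["smoker"] = df["smoker"].astype(int)
    return df[list(expected)]


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def write_percentile_table(table: PercentileTable, path) -> None:
    """AMH percentile curves: rows = ages, columns = probabilities."""
    table.to_frame().to_csv(path, float_format="%.17g")


def write_threshold_table(frame: pd.DataFrame, path) -> None:
    """Profile-by-statistic tables (thresholds, percentiles, intervals)."""
    frame.to_csv(path, float_format="%.17g")
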
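"""Mortality-table schema, validation and CSV round-trip.

The canonical input is a long-format table of daily death counts from caged
fly cohorts, one row per (cohort, day) with the count of flies of that
cohort found dead on that day post-spray.  Columns:

    population_type : cohort's selection regime (e.g. short-lived / long-lived)
    replicate       : biological/technical replicate identifier (free text)
    age_at_spray    : adult age in days at which the cohort was sprayed
    sex             : 'F' or 'M'
    treatment       : 'infected', 'uninfected', 'control' or 'untreated'
    day             : integer day post-spray (>= 1) on which deaths were counted
    deaths          : nonnegative integer death count

Cohorts are followed until every fly has died, so death counts per cohort
sum to the initial cage count and there is no right-censoring.
"""

from __future__ import annotations

import pandas as pd

COLUMNS = [
    "population_type",
    "replicate",
    "age_at_spray",
    "sex",
    "treatment",
    "day",
    "deaths",
]

SEX_LEVELS = frozenset({"F", "M"})
TREATMENT_LEVELS = frozenset({"infected", "uninfected", "control", "untreated"})


class SchemaError(ValueError):
    """A mortality table violates the expected schema."""


def validate_mortality_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and value domains; return a normalised copy.

    Raises :class:`SchemaError` naming the offending column, level and row
    numbers (1-based data rows, as they would appear below a CSV header).
    """
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = table.loc[:, COLUMNS].copy()

    problems: list[str] = []

    def _rows(mask) -> str:
        rows = [str(i + 2) for i in list(df.index[mask])[:5]]
        return "rows " + ", ".join(rows)

    for col in ("age_at_spray", "day", "deaths"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | (coerced != coerced.round())
        if bad.any():
            problems.append(f"column '{col}' must be integer ({_rows(bad)})")
            continue
        df[col] = coerced.astype(int)

    if not problems:
        for col, lo in (("day", 1), ("deaths", 0), ("age_at_spray", 1)):
            bad = df[col] < lo
            if bad.any():
                problems.append(f"column '{col}' must be >= {lo} ({_rows(bad)})")

    bad = ~df["sex"].isin(SEX_LEVELS)
    if bad.any():
        levels = sorted(df.loc[bad, "sex"].astype(str).unique())
        problems.append(f"unknown sex level(s) {levels} ({_rows(bad)})")
    bad = ~df["treatment"].isin(TREATMENT_LEVELS)
    if bad.any():
        levels = sorted(df.loc[bad, "treatment"].astype(str).unique())
        problems.append(f"unknown treatment level(s) {levels} ({_rows(bad)})")

    if problems:
        raise SchemaError("; ".join(problems))
    return df


def read_mortality_table(path) -> pd.DataFrame:
    """Read and validate a mortality table CSV (comment lines start with '#')."""
    df = pd.read_csv(path, comment="#")
    return validate_mortality_table(df)


def write_mortality_table(table: pd.DataFrame, path) -> None:
    """Write a validated mortality table to CSV."""
    validate_mortality_table(table).to_csv(path, index=False)
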
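"""Cohort data model: CSV I/O, missing values, one-hot encoding, descriptives.

A cohort is one row per adolescent participant with sociodemographic
variables (gender, parental education, household income, frequency of
parental quarrels), banded symptom severities (depression, anxiety), a
binary self-concept category and the binary high-suicide-risk flag.
Any field may be missing; missing cells are kept as an explicit mask and
never silently coerced.

The one-hot encoding fixes the 25 network node labels in a frozen order:
FE1-FE3 (father education), ME1-ME3 (mother education), I1-I4 (income
bands), MS1-MS5 (quarrel frequency), D1-D4 (depression severity),
A1-A4 (anxiety severity), SC (self-concept, normal=1) and SS (suicide
risk, high=1).  Multi-category variables expand to one column per
category; dichotomous variables stay a single 0/1 column.  A missing
source value masks the entire column block for that row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Schema


#: Category levels per variable, in domain order.  Gender is coded with
#: female = 1 (the default, overridable through a schema map at read time).
VARIABLE_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "father_edu": ("primary", "secondary", "college_university"),
    "mother_edu": ("primary", "secondary", "college_university"),
    "income": ("lt_100k", "100_250k", "250_500k", "gt_500k"),
    "quarrel": ("divorce", "never", "monthly_1_2", "weekly_1_2", "weekly_3_4_plus"),
    "depression_band": ("no", "mild", "moderate", "severe"),
    "anxiety_band": ("no", "mild", "moderate", "severe"),
    "self_concept": ("low", "normal"),
    "suicide_high": ("non_high", "high"),
}

CATEGORICAL_VARIABLES = tuple(VARIABLE_LEVELS)
ALL_VARIABLES = ("age",) + CATEGORICAL_VARIABLES
CSV_COLUMNS = ("participant_id",) + ALL_VARIABLES

#: Frozen node label order of the 25-node network.
NODE_LABELS: tuple[str, ...] = (
    "FE1", "FE2", "FE3",
    "ME1", "ME2", "ME3",
    "I1", "I2", "I3", "I4",
    "MS1", "MS2", "MS3", "MS4", "MS5",
    "D1", "D2", "D3", "D4",
    "A1", "A2", "A3", "A4",
    "SC", "SS",
)

#: Variable -> its node columns.  Dichotomous variables occupy one column
#: coded by the *second* level of VARIABLE_LEVELS (normal=1, high=1).
NODE_BLOCKS: dict[str, tuple[str, ...]] = {
    "father_edu": ("FE1", "FE2", "FE3"),
    "mother_edu": ("ME1", "ME2", "ME3"),
    "income": ("I1", "I2", "I3", "I4"),
    "quarrel": ("MS1", "MS2", "MS3", "MS4", "MS5"),
    "depression_band": ("D1", "D2", "D3", "D4"),
    "anxiety_band": ("A1", "A2", "A3", "A4"),
    "self_concept": ("SC",),
    "suicide_high": ("SS",),
}

#: Human-readable description of each node (mirrors the network legend).
NODE_DESCRIPTIONS: dict[str, str] = {
    "FE1": "Father primary education", "FE2": "Father secondary education",
    "FE3": "Father college/university education",
    "ME1": "Mother primary education", "ME2": "Mother secondary education",
    "ME3": "Mother college/university education",
    "I1": "Income < 100k RMB", "I2": "Income 100-250k RMB",
    "I3": "Income 250-500k RMB", "I4": "Income > 500k RMB",
    "MS1": "Parents divorced", "MS2": "Never quarrel",
    "MS3": "Quarrel 1-2 times/month", "MS4": "Quarrel 1-2 times/week",
    "MS5": "Quarrel 3-4+ times/week",
    "D1": "No depression", "D2": "Mild depression",
    "D3": "Moderate depression", "D4": "Severe depression",
    "A1": "No anxiety", "A2": "Mild anxiety",
    "A3": "Moderate anxiety", "A4": "Severe anxiety",
    "SC": "Self-concept (normal=1)", "SS": "Suicide risk (high=1)",
}


class CohortValidationError(ValueError):
    """A cohort table or CSV violates the schema."""


# ---------------------------------------------------------------------------
# CohortTable


@dataclass
class CohortTable:
    """Ordered per-participant records backed by a pandas DataFrame.

    ``df`` has the columns of :data:`CSV_COLUMNS`; categorical cells hold
    the string levels of :data:`VARIABLE_LEVELS` or ``NaN`` for missing,
    ``age`` holds floats (integral years) with ``NaN`` for missing.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CohortValidationError(f"missing columns: {missing_cols}")
        self.df = df = df.loc[:, list(CSV_COLUMNS)].reset_index(drop=True)
        ids = df["participant_id"]
        if ids.isna().any():
            raise CohortValidationError("participant_id must not be missing")
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise CohortValidationError(f"duplicate participant_id {dup!r}")
        ages = df["age"].dropna()
        if (ages < 0).any():
            raise CohortValidationError("age must be >= 0")
        for var, levels in VARIABLE_LEVELS.items():
            bad = ~df[var].isna() & ~df[var].isin(levels)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortValidationError(
                    f"row {row}, column {var!r}: unknown category "
                    f"{df[var].iloc[row]!r} (allowed: {levels})"
                )

    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return self.n


def read_cohort_csv(path, schema_config: Mapping[str, Mapping[str, str]] | None = None) -> CohortTable:
    """Read a cohort CSV, mapping labels to schema levels.

    ``schema_config`` optionally maps, per variable, external CSV labels to the
    canonical levels (e.g. ``{"gender": {"F": "female", "M": "male"}}``).
    Blank cells become missing.  Unknown labels raise an error naming the
    row, column and offending token.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CohortValidationError(f"CSV missing columns: {missing_cols}")
    out = pd.DataFrame()
    out["participant_id"] = raw["participant_id"].mask(raw["participant_id"] == "")
    age = raw["age"].mask(raw["age"] == "")
    out["age"] = pd.to_numeric(age, errors="coerce").astype(float)
    schema_config = schema_config or {}
    for var, levels in VARIABLE_LEVELS.items():
        mapping = dict(schema_config.get(var, {}))
        col = raw[var].mask(raw[var] == "")
        mapped = col.map(lambda tok: mapping.get(tok, tok), na_action="ignore")
        bad = ~mapped.isna() & ~mapped.isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortValidationError(
                f"row {row}, column {var!r}: unknown category label "
                f"{col.iloc[row]!r}"
            )
        out[var] = mapped
    return CohortTable(out)


def write_cohort_csv(cohort: CohortTable, path) -> None:
    """Write a cohort to CSV (blank cells for missing values)."""
    df = cohort.df.copy()
    df["age"] = df["age"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# One-hot encoding


@dataclass
class EncodedMatrix:
    """One-hot 0/1 design over the 25 network nodes with a missing mask.

    ``values`` is an ``n x 25`` float array; missing cells are ``NaN``.
    ``group_map`` maps each source variable to its column indices.
    """

    column_labels: tuple[str, ...]
    values: np.ndarray
    group_map: dict[str, tuple[int, ...]]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.column_labels))


def one_hot_encode(cohort: CohortTable) -> EncodedMatrix:
    """Encode a cohort into the frozen 25-column 0/1 design.

    Multi-category blocks get one indicator per category (row block sums
    to 1 when complete); self-concept and suicide risk stay single columns
    coded normal=1 / high=1.  A missing source value masks every column of
    its block for that row.
    """
    n = cohort.n
    values = np.full((n, len(NODE_LABELS)), np.nan)
    group_map: dict[str, tuple[int, ...]] = {}
    col_index = {lab: i for i, lab in enumerate(NODE_LABELS)}
    for var, block in NODE_BLOCKS.items():
        idx = tuple(col_index[lab] for lab in block)
        group_map[var] = idx
        levels = VARIABLE_LEVELS[var]
        col = cohort.df[var]
        observed = ~col.isna()
        if len(block) == 1:
            # dichotomous: second level codes 1
            values[observed.to_numpy(), idx[0]] = (
                col[observed] == levels[1]
            ).to_numpy(dtype=float)
        else:
            codes = col[observed].map({lev: k for k, lev in enumerate(levels)})
            rows = np.flatnonzero(observed.to_numpy())
            for k, j in enumerate(idx):
                values[rows, j] = (codes == k).to_numpy(dtype=float)
    return EncodedMatrix(NODE_LABELS, values, group_map)


def decode(encoded: EncodedMatrix) -> pd.DataFrame:
    """Invert :func:`one_hot_encode` (argmax per block on observed rows)."""
    out = {}
    for var, idx in encoded.group_map.items():
        levels = VARIABLE_LEVELS[var]
        block = encoded.values[:, list(idx)]
        col = np.full(block.shape[0], np.nan, dtype=object)
        observed = ~np.isnan(block).any(axis=1)
        if len(idx) == 1:
            vals = block[observed, 0].astype(int)
            col[observed] = [levels[v] for v in vals]
        else:
            vals = block[observed].argmax(axis=1)
            col[observed] = [levels[v] for v in vals]
        out[var] = col
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Descriptives


@dataclass
class DescriptiveSummary:
    """Per-category counts/rates plus age quartiles."""

    table: pd.DataFrame  # variable, category, count, missing, rate_percent
    age_quartiles: dict[str, float]  # {"25%": ..., "50%": ..., "75%": ...}
    denominator: int


def describe(cohort: CohortTable, denominator: int | None = None) -> DescriptiveSummary:
    """Per-category counts and rates (percent of ``denominator``).

    Rates are ``100 * count / denominator`` rounded to one decimal place;
    the denominator defaults to the cohort size (the published table uses
    the full enrolled count even for variables with missing values).
    Age quartiles use linear interpolation between order statistics.
    """
    if denominator is None:
        denominator = cohort.n
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    rows = []
    for var, levels in VARIABLE_LEVELS.items():
        col = cohort.df[var]
        n_missing = int(col.isna().sum())
        for lev in levels:
            count = int((col == lev).sum())
            rows.append(
                {
                    "variable": var,
                    "category": lev,
                    "count": count,
                    "missing": n_missing,
                    "rate_percent": round(100.0 * count / denominator, 1),
                }
            )
    ages = cohort.df["age"].dropna()
    if len(ages):
        q = ages.quantile([0.25, 0.5, 0.75], interpolation="linear")
        quartiles = {"25%": float(q.iloc[0]), "50%": float(q.iloc[1]), "75%": float(q.iloc[2])}
    else:
        quartiles = {"25%": math.nan, "50%": math.nan, "75%": math.nan}
    return DescriptiveSummary(pd.DataFrame(rows), quartiles, denominator)


def complete_cases(cohort: CohortTable, variables: Sequence[str]) -> CohortTable:
    """Rows with every listed variable non-missing, original order kept."""
    for var in variables:
        if var not in ALL_VARIABLES:
            raise CohortValidationError(f"unknown variable {var!r}")
    if not variables:
        return CohortTable(cohort.df.copy())
    mask = np.ones(cohort.n, dtype=bool)
    for var in variables:
        mask &= ~cohort.df[var].isna().to_numpy()
    return CohortTable(cohort.df.loc[mask].reset_index(drop=True))


def indicator(cohort: CohortTable, variable: str, category: str) -> pd.Series:
    """0/1 indicator for ``variable == category`` (NaN where missing)."""
    if variable not in VARIABLE_LEVELS:
        raise CohortValidationError(f"unknown variable {variable!r}")
    if category not in VARIABLE_LEVELS[variable]:
        raise CohortValidationError(f"unknown category {category!r} for {variable!r}")
    col = cohort.df[variable]
    out = pd.Series(np.nan, index=col.index, name=f"{variable}={category}")
    observed = ~col.isna()
    out[observed] = (col[observed] == category).astype(float)
    return out
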
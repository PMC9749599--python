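"""Reading, validating and writing the household-roster and child tables.

The on-disk format is a flat UTF-8 comma-separated table with a
documented header and ``.`` as the missing-value token — the schema of
the DHS household member recode restricted to the fields this analysis
uses, not any proprietary survey-package container. Household-level
covariates (residence, wealth index, the respondent's earnings type)
are carried as columns repeated on every roster line of the household.

``roster.csv`` columns
    household_id, line_number, relationship_code, age_years, sex,
    education, de_jure, de_facto, is_respondent, survey_round,
    cluster_id, weight, residence, wealth_index, earnings_type

``children.csv`` columns
    household_id, child_line, age_months, given_solids_yesterday,
    caregiver_line, mother_line

Flags are stored as 0/1. Validation is total: every malformed row
produces a diagnostic naming the household and field, and enumerated
values are never silently coerced (the single documented exception: an
unknown relationship code maps to ``other_relative`` with a warning).
"""

from __future__ import annotations

import dataclasses
from typing import Iterator

import numpy as np
import pandas as pd

from hhnet.codes import (
    EARNINGS_LEVELS,
    EDUCATION_LEVELS,
    MAX_ROSTER_LINES,
    RELATIONSHIP_CODES,
    RESIDENCE_LEVELS,
    SEXES,
    WEALTH_LEVELS,
)
from hhnet.errors import OrphanRecordError, RosterValidationError, SchemaError

MISSING_TOKEN = "."

ROSTER_COLUMNS = [
    "household_id",
    "line_number",
    "relationship_code",
    "age_years",
    "sex",
    "education",
    "de_jure",
    "de_facto",
    "is_respondent",
    "survey_round",
    "cluster_id",
    "weight",
    "residence",
    "wealth_index",
    "earnings_type",
]

CHILD_COLUMNS = [
    "household_id",
    "child_line",
    "age_months",
    "given_solids_yesterday",
    "caregiver_line",
    "mother_line",
]


@dataclasses.dataclass(frozen=True)
class Diagnostic:
    """One row-level validation finding."""

    severity: str  # "error" | "warning"
    household_id: str
    field: str
    message: str


@dataclasses.dataclass(frozen=True)
class HouseholdMember:
    """One roster line (object view of a validated roster row)."""

    household_id: str
    line_number: int
    relationship_code: str
    age_years: int | None
    sex: str
    education: str | None
    de_jure: bool
    de_facto: bool
    is_respondent: bool

    @classmethod
    def from_row(cls, row: pd.Series) -> "HouseholdMember":
        return cls(
            household_id=str(row["household_id"]),
            line_number=int(row["line_number"]),
            relationship_code=str(row["relationship_code"]),
            age_years=None if pd.isna(row["age_years"]) else int(row["age_years"]),
            sex=str(row["sex"]),
            education=None if pd.isna(row["education"]) else str(row["education"]),
            de_jure=bool(row["de_jure"]),
            de_facto=bool(row["de_facto"]),
            is_respondent=bool(row["is_respondent"]),
        )


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype=str,
        na_values=[MISSING_TOKEN, ""],
        keep_default_na=False,
        comment=None,
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def read_roster(path, schema_version: str = "1") -> tuple[pd.DataFrame, list[Diagnostic]]:
    """Read and validate a roster file.

    Returns the validated roster as a DataFrame (grouped per household
    via :func:`iter_households`) plus warning diagnostics. Invariant
    violations raise :class:`RosterValidationError` carrying every
    error-level diagnostic found.
    """
    if schema_version != "1":
        raise SchemaError(f"unknown roster schema version {schema_version!r}")
    raw = _read_csv(path, ROSTER_COLUMNS)
    diagnostics: list[Diagnostic] = []
    if raw.empty:
        out = pd.DataFrame({c: pd.Series(dtype=object) for c in ROSTER_COLUMNS})
        return out, []

    df = pd.DataFrame()
    df["household_id"] = raw["household_id"].astype(str)
    df["line_number"] = pd.to_numeric(raw["line_number"], errors="coerce")
    df["relationship_code"] = raw["relationship_code"]
    df["age_years"] = pd.to_numeric(raw["age_years"], errors="coerce")
    df["sex"] = raw["sex"]
    df["education"] = raw["education"]
    for flag in ("de_jure", "de_facto", "is_respondent"):
        df[flag] = pd.to_numeric(raw[flag], errors="coerce")
    df["survey_round"] = raw["survey_round"].astype(str)
    df["cluster_id"] = raw["cluster_id"].astype(str)
    df["weight"] = pd.to_numeric(raw["weight"], errors="coerce")
    df["residence"] = raw["residence"]
    df["wealth_index"] = raw["wealth_index"]
    df["earnings_type"] = raw["earnings_type"]

    def err(hh, field, msg):
        diagnostics.append(Diagnostic("error", str(hh), field, msg))

    def warn(hh, field, msg):
        diagnostics.append(Diagnostic("warning", str(hh), field, msg))

    # field-level checks
    for i, row in df.iterrows():
        hh = row["household_id"]
        if pd.isna(row["line_number"]) or not (1 <= row["line_number"] <= MAX_ROSTER_LINES):
            err(hh, "line_number", f"line_number {raw['line_number'].iloc[i]!r} outside 1..{MAX_ROSTER_LINES}")
        if row["relationship_code"] not in RELATIONSHIP_CODES:
            if pd.isna(row["relationship_code"]):
                err(hh, "relationship_code", "missing relationship code")
            else:
                warn(
                    hh,
                    "relationship_code",
                    f"unknown code {row['relationship_code']!r} mapped to other_relative",
                )
                df.at[i, "relationship_code"] = "other_relative"
        if not pd.isna(row["age_years"]) and row["age_years"] < 0:
            err(hh, "age_years", f"negative age {row['age_years']}")
        if row["sex"] not in SEXES:
            err(hh, "sex", f"sex {row['sex']!r} not in {SEXES}")
        if not pd.isna(row["education"]) and row["education"] not in EDUCATION_LEVELS:
            err(hh, "education", f"education {row['education']!r} not in {EDUCATION_LEVELS}")
        for flag in ("de_jure", "de_facto", "is_respondent"):
            if row[flag] not in (0, 1):
                err(hh, flag, f"{flag} must be 0/1, got {raw[flag].iloc[i]!r}")
        if row["de_jure"] == 0 and row["de_facto"] == 0:
            err(hh, "de_jure", "member neither de jure nor de facto")
        if pd.isna(row["weight"]) or row["weight"] <= 0:
            err(hh, "weight", f"weight must be positive, got {raw['weight'].iloc[i]!r}")
        if not pd.isna(row["residence"]) and row["residence"] not in RESIDENCE_LEVELS:
            err(hh, "residence", f"residence {row['residence']!r} not in {RESIDENCE_LEVELS}")
        if not pd.isna(row["wealth_index"]) and row["wealth_index"] not in WEALTH_LEVELS:
            err(hh, "wealth_index", f"wealth_index {row['wealth_index']!r} not in {WEALTH_LEVELS}")
        if not pd.isna(row["earnings_type"]) and row["earnings_type"] not in EARNINGS_LEVELS:
            err(hh, "earnings_type", f"earnings_type {row['earnings_type']!r} not in {EARNINGS_LEVELS}")

    # household-level invariants
    for hh, grp in df.groupby("household_id", sort=False):
        if len(grp) > MAX_ROSTER_LINES:
            err(hh, "line_number", f"{len(grp)} roster lines exceed the {MAX_ROSTER_LINES}-line maximum")
        if grp["line_number"].notna().all() and grp["line_number"].duplicated().any():
            dupes = sorted(grp.loc[grp["line_number"].duplicated(), "line_number"].astype(int))
            err(hh, "line_number", f"duplicate line_number(s) {dupes}")
        n_resp = int((grp["is_respondent"] == 1).sum())
        if n_resp != 1:
            err(hh, "is_respondent", f"{n_resp} respondents; exactly one required")
        elif grp.loc[grp["is_respondent"] == 1, "sex"].iloc[0] != "female":
            err(hh, "is_respondent", "respondent must be female")
        for col in ("survey_round", "cluster_id", "weight"):
            if grp[col].nunique(dropna=False) > 1:
                err(hh, col, f"{col} not constant within household")

    errors = [d for d in diagnostics if d.severity == "error"]
    if errors:
        hh_ids = sorted({d.household_id for d in errors})
        detail = "; ".join(
            f"{d.household_id}/{d.field}: {d.message}" for d in errors[:10]
        )
        raise RosterValidationError(
            f"{len(errors)} invariant violation(s) in household(s) {hh_ids}: {detail}",
            diagnostics,
        )

    df["line_number"] = df["line_number"].astype(int)
    for flag in ("de_jure", "de_facto", "is_respondent"):
        df[flag] = df[flag].astype(np.int8)
    df["weight"] = df["weight"].astype(float)
    df["age_years"] = df["age_years"].astype(float)
    return df.reset_index(drop=True), diagnostics


def read_children(path, roster: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate a child table.

    Missing feeding responses are preserved as missing (pandas NA),
    never coerced to "no". When a roster is supplied, children must
    reference known households and an existing caregiver line.
    """
    raw = _read_csv(path, CHILD_COLUMNS[:5])  # mother_line optional
    if "mother_line" not in raw.columns:
        raw["mother_line"] = pd.NA
    if raw.empty:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in CHILD_COLUMNS})
    df = pd.DataFrame()
    df["household_id"] = raw["household_id"].astype(str)
    df["child_line"] = pd.to_numeric(raw["child_line"], errors="coerce")
    df["age_months"] = pd.to_numeric(raw["age_months"], errors="coerce")
    df["given_solids_yesterday"] = pd.to_numeric(raw["given_solids_yesterday"], errors="coerce").astype("Int64")
    df["caregiver_line"] = pd.to_numeric(raw["caregiver_line"], errors="coerce")
    df["mother_line"] = pd.to_numeric(raw["mother_line"], errors="coerce").astype("Int64")

    diagnostics = []
    bad_age = df["age_months"].isna() | (df["age_months"] < 0)
    for hh in df.loc[bad_age, "household_id"]:
        diagnostics.append(Diagnostic("error", hh, "age_months", "age_months must be a non-negative integer"))
    bad_resp = ~df["given_solids_yesterday"].isna() & ~df["given_solids_yesterday"].isin([0, 1])
    for hh in df.loc[bad_resp, "household_id"]:
        diagnostics.append(Diagnostic("error", hh, "given_solids_yesterday", "response must be 0/1 or missing"))
    if diagnostics:
        detail = "; ".join(f"{d.household_id}/{d.field}: {d.message}" for d in diagnostics[:10])
        raise RosterValidationError(
            f"{len(diagnostics)} invalid child record(s): {detail}", diagnostics
        )

    if roster is not None and not roster.empty:
        known = set(roster["household_id"].astype(str))
        orphans = sorted(set(df["household_id"]) - known)
        if orphans:
            raise OrphanRecordError(f"child record(s) reference unknown household(s): {orphans}")
        lines = roster.groupby("household_id")["line_number"].agg(set)
        for _, row in df.iterrows():
            if int(row["caregiver_line"]) not in lines[row["household_id"]]:
                raise OrphanRecordError(
                    f"household {row['household_id']!r}: caregiver_line "
                    f"{int(row['caregiver_line'])} not on the roster"
                )
    df["child_line"] = df["child_line"].astype(int)
    df["age_months"] = df["age_months"].astype(int)
    df["caregiver_line"] = df["caregiver_line"].astype(int)
    return df.reset_index(drop=True)


def iter_households(roster: pd.DataFrame) -> Iterator[tuple[str, pd.DataFrame]]:
    """Yield (household_id, roster rows) per household, in file order."""
    yield from roster.groupby("household_id", sort=False)


def write_analysis_table(units: pd.DataFrame, path) -> None:
    """Write an analysis table deterministically (sorted rows, fixed
    column order, ``.`` for missing). Round-trips losslessly through
    :func:`read_analysis_table`."""
    df = units.copy()
    for col in df.columns:
        if df[col].dtype == bool:
            df[col] = df[col].astype(np.int8)
    df.to_csv(path, index=False, na_rep=MISSING_TOKEN)


def read_analysis_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[MISSING_TOKEN, ""], keep_default_na=False)
    for col in ("household_id", "cluster_id", "survey_round"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df
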
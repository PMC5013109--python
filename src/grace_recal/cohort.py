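"""Cohort schema, I/O, eligibility exclusions and the COPD identification rule.

A cohort is a :class:`pandas.DataFrame` with one row per admission and the
canonical columns in :data:`COHORT_COLUMNS`.  Numeric GRACE covariates are
floats (NaN = missing), flags are pandas nullable booleans, ``smoking`` is one
of ``{"never", "ex", "current"}`` (NA = missing) and ``diagnosis`` is one of
``{"STEMI", "NSTEMI", "UA"}``.

COPD is identified from registry fields rather than a diagnosis code: a
patient is flagged as COPD when the obstructive-airway-disease indicator is
set *and* they are an ex- or current smoker.  This mirrors the strategy
validated against linked primary-care records for the UK myocardial-ischaemia
audit, which misclassifies <10% of patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from grace_recal.errors import InputError, PreconditionError, SchemaError

#: Canonical cohort columns, in file order.
COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "heart_rate",
    "systolic_bp",
    "creatinine",
    "diuretic_in_hospital",
    "cardiac_arrest",
    "st_deviation",
    "elevated_markers",
    "oad_indicator",
    "smoking",
    "diagnosis",
    "diabetes",
    "admission_year",
    "died_6m",
)

#: The eight inputs of the mini-GRACE 6-month mortality score (in-hospital
#: diuretic prescription stands in for the heart-failure / Killip term).
GRACE_VARIABLES: tuple[str, ...] = (
    "age",
    "heart_rate",
    "systolic_bp",
    "creatinine",
    "diuretic_in_hospital",
    "cardiac_arrest",
    "st_deviation",
    "elevated_markers",
)

NUMERIC_COLUMNS = ("age", "heart_rate", "systolic_bp", "creatinine")
BOOL_COLUMNS = (
    "diuretic_in_hospital",
    "cardiac_arrest",
    "st_deviation",
    "elevated_markers",
    "oad_indicator",
    "diabetes",
    "died_6m",
)
SMOKING_LEVELS = ("never", "ex", "current")
DIAGNOSIS_LEVELS = ("STEMI", "NSTEMI", "UA")

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}


@dataclass
class ExclusionLog:
    """Counts of records dropped per eligibility rule, in assessment order.

    Each record is counted once, under the first matching reason; this mirrors
    a sequential flow diagram (missing identifier, then missing
    obstructive-airway-disease indicator, then missing smoking history, then
    missing vital status).
    """

    missing_id: int = 0
    missing_oad: int = 0
    missing_smoking: int = 0
    missing_vital_status: int = 0
    n_input: int = 0
    n_retained: int = 0

    def total_excluded(self) -> int:
        return self.missing_id + self.missing_oad + self.missing_smoking + self.missing_vital_status

    def reconciles(self) -> bool:
        return self.n_input == self.n_retained + self.total_excluded()

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "missing_id": self.missing_id,
            "missing_oad": self.missing_oad,
            "missing_smoking": self.missing_smoking,
            "missing_vital_status": self.missing_vital_status,
            "n_retained": self.n_retained,
        }


def _parse_bool(series: pd.Series, column: str) -> pd.Series:
    s = series.astype("string").str.strip().str.lower()
    out = pd.Series(pd.NA, index=series.index, dtype="boolean")
    out[s.isin(_TRUE_TOKENS)] = True
    out[s.isin(_FALSE_TOKENS)] = False
    # anything else (including "") stays missing
    return out


def _parse_enum(series: pd.Series, levels: tuple[str, ...]) -> pd.Series:
    s = series.astype("string").str.strip()
    out = s.where(s.isin(levels))
    return out.astype("string")


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV file with a header row; "" denotes missing; booleans accepted as
        0/1/true/false/yes/no (case-insensitive).
    schema
        Optional mapping from canonical column name to the name used in the
        file, for non-canonical headers.

    Returns
    -------
    A validated cohort DataFrame with canonical columns and dtypes.  Row order
    is preserved; unparseable numeric fields become missing.

    Raises
    ------
    SchemaError
        If a required column is absent (the message names it).
    InputError
        If the file is empty.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cohort file not found: {path}")
    try:
        raw = pd.read_csv(path, dtype="string", keep_default_na=False, na_values=[""])
    except pd.errors.EmptyDataError:
        raise InputError(f"cohort file is empty: {path}") from None
    if schema:
        rename = {src: canon for canon, src in schema.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"cohort file missing required column(s): {', '.join(missing)}")
    if len(raw) == 0:
        raise InputError(f"cohort file has a header but no records: {path}")
    return validate_cohort(raw[list(COHORT_COLUMNS)])


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a raw string-typed table to canonical cohort dtypes."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing required column(s): {', '.join(missing)}")
    out = pd.DataFrame(index=df.index)
    out["patient_id"] = df["patient_id"].astype("string").str.strip().replace("", pd.NA)
    for col in NUMERIC_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce").astype(float)
        # physiological quantities are strictly positive; other values are unusable
        vals[vals <= 0] = np.nan
        out[col] = vals
    for col in BOOL_COLUMNS:
        if pd.api.types.is_bool_dtype(df[col]) or df[col].dtype == "boolean":
            out[col] = df[col].astype("boolean")
        else:
            out[col] = _parse_bool(df[col], col)
    out["smoking"] = _parse_enum(df["smoking"], SMOKING_LEVELS)
    out["diagnosis"] = _parse_enum(df["diagnosis"], DIAGNOSIS_LEVELS)
    out["admission_year"] = pd.to_numeric(df["admission_year"], errors="coerce").astype("Int64")
    return out[list(COHORT_COLUMNS)].reset_index(drop=True)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort to CSV such that ``read_cohort`` round-trips it."""
    out = cohort.copy()
    for col in BOOL_COLUMNS:
        out[col] = out[col].map({True: "true", False: "false"}, na_action="ignore")
    out.to_csv(path, index=False, na_rep="")


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the eligibility exclusions and return the retained cohort + log.

    Records are dropped, in order, for a missing patient identifier, missing
    obstructive-airway-disease indicator, missing smoking history, or missing
    6-month vital status; each record is counted under the first reason that
    applies.  Missing numeric GRACE covariates do *not* exclude a record here
    (downstream steps are complete-case per analysis and report their drops).
    """
    if len(cohort) == 0:
        raise PreconditionError("apply_exclusions requires a non-empty cohort")
    log = ExclusionLog(n_input=len(cohort))
    remaining = cohort

    m = remaining["patient_id"].isna()
    log.missing_id = int(m.sum())
    remaining = remaining[~m]

    m = remaining["oad_indicator"].isna()
    log.missing_oad = int(m.sum())
    remaining = remaining[~m]

    m = remaining["smoking"].isna()
    log.missing_smoking = int(m.sum())
    remaining = remaining[~m]

    m = remaining["died_6m"].isna()
    log.missing_vital_status = int(m.sum())
    remaining = remaining[~m]

    log.n_retained = len(remaining)
    assert log.reconciles()
    if log.n_retained == 0:
        import warnings

        warnings.warn("all records excluded; returning an empty cohort", stacklevel=2)
    return remaining.reset_index(drop=True), log


def identify_copd(record_or_cohort: pd.Series | pd.DataFrame) -> bool | pd.Series:
    """Derive the COPD flag: obstructive-airway-disease indicator AND ever-smoking.

    Accepts a single record (Series) or a whole cohort (DataFrame); for a
    cohort, returns a boolean Series aligned to it.  Requires both
    ``oad_indicator`` and ``smoking`` to be non-missing (run exclusions first).
    """
    if isinstance(record_or_cohort, pd.DataFrame):
        oad = record_or_cohort["oad_indicator"]
        smoking = record_or_cohort["smoking"]
        if oad.isna().any() or smoking.isna().any():
            raise PreconditionError(
                "identify_copd requires non-missing oad_indicator and smoking; apply exclusions first"
            )
        return (oad.astype(bool) & smoking.isin(["ex", "current"])).astype(bool)
    rec = record_or_cohort
    if pd.isna(rec["oad_indicator"]) or pd.isna(rec["smoking"]):
        raise PreconditionError(
            "identify_copd requires non-missing oad_indicator and smoking; apply exclusions first"
        )
    return bool(rec["oad_indicator"]) and rec["smoking"] in ("ex", "current")
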
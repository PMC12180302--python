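"""Derive analysis variables and build the wide binary disease matrix.

Takes a raw per-subject cohort table (demographics, serum uric acid, 20
self-reported disease indicators) and produces:

* the N×21 binary ``DiseaseMatrix`` (hyperuricemia derived from uric acid),
* per-subject derived flags (disease count, multimorbidity, cardiometabolic
  multimorbidity, BMI class, age group),
* an exclusion log with one reason code per dropped subject.

All threshold comparisons read "exceeding"/boundary definitions strictly:
hyperuricemia requires uric acid strictly above the sex threshold; BMI and
age classes use half-open intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diseases import (
    CARDIOMETABOLIC,
    DISEASES,
    REPORTED_DISEASES,
    URIC_ACID_THRESHOLD,
)

BMI_CLASSES = ("underweight", "normal", "overweight", "obese")
AGE_GROUPS = ("60-65", "66-70", "71-75", "76+")

_BMI_EDGES = (18.5, 25.0, 30.0)
_AGE_EDGES = (66.0, 71.0, 76.0)  # group g holds ages in [edge[g-1], edge[g])


@dataclass
class PreprocessResult:
    matrix: pd.DataFrame  # N×21 binary, index = subject_id, canonical order
    flags: pd.DataFrame  # derived per-subject variables, same index
    exclusions: pd.DataFrame  # (subject_id, reason)
    cohort: pd.DataFrame  # the retained raw rows, same index


def derive_hyperuricemia(sex, uric_acid) -> np.ndarray:
    """Sex-specific strict threshold on serum uric acid (μmol/L).

    Males are hyperuricemic above 420, females above 360; values equal to the
    threshold are negative.
    """
    sex = np.asarray(sex)
    uric = np.asarray(uric_acid, dtype=float)
    thr = np.where(sex == "male", URIC_ACID_THRESHOLD["male"], URIC_ACID_THRESHOLD["female"])
    return uric > thr


def classify_bmi(bmi) -> np.ndarray:
    """Half-open BMI classes: <18.5, [18.5,25), [25,30), ≥30 (kg/m²)."""
    bmi = np.atleast_1d(np.asarray(bmi, dtype=float))
    if np.any(bmi[~np.isnan(bmi)] <= 0):
        raise ValueError("BMI must be positive")
    idx = np.digitize(bmi, _BMI_EDGES)
    out = np.array(BMI_CLASSES, dtype=object)[idx]
    out[np.isnan(bmi)] = None
    return out


def classify_age(age) -> np.ndarray:
    """Five-year age groups 60-65, 66-70, 71-75, with ages 76+ pooled."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    if np.any(age < 60):
        raise ValueError("ages below 60 are outside the study population")
    return np.array(AGE_GROUPS, dtype=object)[np.digitize(age, _AGE_EDGES)]


def _exclusion_reasons(cohort: pd.DataFrame) -> pd.Series:
    """First applicable exclusion reason per row, NaN when retained."""
    reason = pd.Series(pd.NA, index=cohort.index, dtype=object)

    def flag(mask: pd.Series, code: str) -> None:
        mask = mask & reason.isna()
        reason[mask] = code

    flag(~cohort["sex"].isin(["male", "female"]), "invalid_sex")
    age = pd.to_numeric(cohort["age"], errors="coerce")
    flag(age.isna(), "missing_age")
    flag(age < 60, "age_below_60")
    uric = pd.to_numeric(cohort["uric_acid"], errors="coerce")
    flag(uric.isna() | (uric <= 0), "missing_uric_acid")
    ind = cohort[list(REPORTED_DISEASES)].apply(pd.to_numeric, errors="coerce")
    flag(ind.isna().any(axis=1), "missing_disease_indicator")
    flag((~ind.isin([0, 1])).any(axis=1), "miscoded_disease_indicator")
    bmi = pd.to_numeric(cohort["bmi"], errors="coerce")
    flag(bmi.notna() & (bmi <= 0), "invalid_bmi")
    return reason


def build_matrix(cohort: pd.DataFrame) -> PreprocessResult:
    """Build the binary disease matrix, derived flags and exclusion log.

    Rows with an unusable sex/age, missing or non-positive uric acid, or any
    missing/miscoded disease indicator are dropped and logged. A missing BMI
    is tolerated (its class is left missing) since it does not enter the
    disease matrix.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    cohort = cohort.copy()
    if "subject_id" not in cohort.columns:
        cohort["subject_id"] = [f"S{i:06d}" for i in range(len(cohort))]

    reason = _exclusion_reasons(cohort)
    exclusions = pd.DataFrame(
        {"subject_id": cohort.loc[reason.notna(), "subject_id"], "reason": reason.dropna()}
    ).reset_index(drop=True)
    kept = cohort.loc[reason.isna()].set_index("subject_id")
    if len(kept) == 0:
        raise ValueError("all rows excluded")

    matrix = pd.DataFrame(index=kept.index)
    matrix["hyperuricemia"] = derive_hyperuricemia(
        kept["sex"].to_numpy(), kept["uric_acid"].to_numpy()
    ).astype(np.int8)
    for d in REPORTED_DISEASES:
        matrix[d] = pd.to_numeric(kept[d]).astype(np.int8)
    matrix = matrix[list(DISEASES)]

    flags = derive_flags(matrix, kept)
    return PreprocessResult(matrix=matrix, flags=flags, exclusions=exclusions, cohort=kept)


def derive_flags(matrix: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject disease count, multimorbidity flags and class variables."""
    count = matrix.sum(axis=1).astype(int)
    cm_cols = [d for d in DISEASES if d in CARDIOMETABOLIC]
    cm_count = matrix[cm_cols].sum(axis=1).astype(int)
    age = pd.to_numeric(cohort["age"])
    bmi = pd.to_numeric(cohort["bmi"], errors="coerce")
    return pd.DataFrame(
        {
            "disease_count": count,
            "multimorbidity": count >= 2,
            "cardiometabolic_mm": cm_count >= 2,
            "age_group": pd.Categorical(
                classify_age(age.to_numpy()), categories=AGE_GROUPS, ordered=True
            ),
            "bmi_class": pd.Categorical(
                classify_bmi(bmi.to_numpy()), categories=BMI_CLASSES, ordered=True
            ),
        },
        index=matrix.index,
    )
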
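"""Descriptive comorbidity statistics on the binary disease matrix.

Definitions (all denominators are counts of included subjects N unless
stated otherwise):

* prevalence of disease d          = patients(d) / N
* overall comorbidity rate of d    = patients with d AND ≥1 other disease / N
* internal comorbidity rate of d   = patients with d AND ≥1 other disease
                                     / patients(d)

so that overall = internal × prevalence exactly as fractions. Combination
prevalence of a disease set S counts subjects carrying ALL diseases in S
regardless of the rest, hence is anti-monotone under set inclusion.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage rounded half-up to ``decimals`` places (report parity)."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    num, den = Decimal(str(numerator)), Decimal(str(denominator))
    return float((num / den * 100).quantize(q, ROUND_HALF_UP))


def comorbidity_rates(patients: int, patients_with_other: int, n: int):
    """(prevalence, overall rate, internal rate) as exact fractions.

    Guards the empty-disease case: all three are 0 when ``patients`` is 0.
    """
    if patients_with_other > patients or patients > n:
        raise ValueError("need patients_with_other <= patients <= n")
    prevalence = patients / n
    overall = patients_with_other / n
    internal = patients_with_other / patients if patients else 0.0
    return prevalence, overall, internal


def comorbidity_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-disease patient counts and the three comorbidity rates.

    Returns one row per disease with exact fractional rates plus the
    2-decimal percent columns used in reports, sorted by prevalence
    descending (ties by name).
    """
    if len(matrix) == 0:
        raise ValueError("empty matrix")
    n = len(matrix)
    values = matrix.to_numpy()
    counts = values.sum(axis=0)
    disease_count = values.sum(axis=1)
    with_other = ((values == 1) & (disease_count >= 2)[:, None]).sum(axis=0)

    rows = []
    for j, disease in enumerate(matrix.columns):
        prev, overall, internal = comorbidity_rates(int(counts[j]), int(with_other[j]), n)
        rows.append(
            {
                "disease": disease,
                "patients": int(counts[j]),
                "patients_with_other": int(with_other[j]),
                "prevalence": prev,
                "overall_comorbidity_rate": overall,
                "internal_comorbidity_rate": internal,
                "prevalence_pct": percent(counts[j], n),
                "overall_pct": percent(with_other[j], n),
                "internal_pct": percent(with_other[j], counts[j]) if counts[j] else 0.0,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["prevalence", "disease"], ascending=[False, True]
    )
    return out.set_index("disease")


def combination_prevalence(
    matrix: pd.DataFrame, set_size: int, top_k: int = 10
) -> pd.DataFrame:
    """Top-k disease combinations of a given size by prevalence.

    Enumerates every size-``set_size`` subset of the columns; a subject
    counts toward a combination when it has all its diseases. Ties are
    broken lexicographically on the (sorted) disease-name tuple so the
    ranking is deterministic.
    """
    if set_size not in (2, 3):
        raise ValueError("set_size must be 2 or 3")
    if top_k < 1:
        raise ValueError("top_k must be at least 1")
    n = len(matrix)
    values = matrix.to_numpy(dtype=bool)
    names = list(matrix.columns)
    rows = []
    for combo in combinations(range(len(names)), set_size):
        count = int(values[:, combo].all(axis=1).sum())
        rows.append(
            {
                "diseases": tuple(sorted(names[j] for j in combo)),
                "count": count,
                "prevalence": count / n,
                "prevalence_pct": percent(count, n),
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["count", "diseases"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out.head(top_k)


def strata_table(flags: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts and row proportions of {no disease, single, multimorbidity}
    per stratum of sex, age group, BMI class, education, smoking, drinking."""
    if len(flags) != len(cohort):
        raise ValueError("flags and cohort are misaligned")
    outcome = pd.cut(
        flags["disease_count"].clip(upper=2),
        bins=[-0.5, 0.5, 1.5, 2.5],
        labels=["no_disease", "single_disease", "multimorbidity"],
    )
    features = {
        "sex": cohort["sex"],
        "age_group": flags["age_group"],
        "bmi_class": flags["bmi_class"],
        "education": cohort["education"],
        "smoke": cohort["smoke"],
        "drink": cohort["drink"],
    }
    blocks = []
    for feature, series in features.items():
        tab = pd.crosstab(series, outcome, dropna=False)
        tab = tab.reindex(columns=["no_disease", "single_disease", "multimorbidity"], fill_value=0)
        tab.insert(0, "n", tab.sum(axis=1))
        for col in ["no_disease", "single_disease", "multimorbidity"]:
            tab[f"{col}_pct"] = [
                percent(c, t) for c, t in zip(tab[col], tab["n"])
            ]
        tab.insert(0, "feature", feature)
        tab.index.name = "stratum"
        blocks.append(tab.reset_index())
    return pd.concat(blocks, ignore_index=True)


def trend_test(disease_count, stratum) -> tuple[float, float]:
    """Linear trend of per-subject disease count across an ordered stratum.

    The stratum (age group or BMI class) is scored 1..G in its category
    order and an ordinary least-squares slope of disease count on the score
    is tested (two-sided) for zero slope. Returns ``(slope, p_value)``.
    """
    disease_count = np.asarray(disease_count, dtype=float)
    stratum = pd.Series(stratum)
    if isinstance(stratum.dtype, pd.CategoricalDtype):
        scores = stratum.cat.codes.to_numpy(dtype=float) + 1.0
    else:
        levels = pd.unique(stratum.dropna())
        mapping = {lvl: i + 1.0 for i, lvl in enumerate(sorted(levels))}
        scores = stratum.map(mapping).to_numpy(dtype=float)
    keep = ~np.isnan(scores) & (scores >= 1)  # categorical NaN codes to -1
    scores, disease_count = scores[keep], disease_count[keep]
    if len(np.unique(scores)) < 2:
        raise ValueError("need at least two distinct strata")
    res = sps.linregress(scores, disease_count)
    p = float(res.pvalue)
    if np.isnan(p):  # constant response: no evidence of trend
        p = 1.0
    return float(res.slope), p
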
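"""Per-cluster profiles and between-cluster statistical comparisons.

Profiles mirror the standard survey layout: per-cluster counts and column
percentages for sex, age group, BMI class, education, smoking and drinking,
the per-cluster disease prevalence matrix (the input to prevalence heatmaps
and radar charts), and per-cluster top comorbidity combinations and
association rules.

Comparisons: chi-square on the sex×cluster table with all pairwise 2×2
follow-ups (no continuity correction by default, switchable), one-way ANOVA
on age and BMI, and Tukey HSD for the pairwise mean contrasts.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .diseases import DISEASES
from .rules import MiningConfig, frequent_itemsets, generate_rules
from .stats import combination_prevalence, percent


def cluster_sizes(assignment) -> pd.Series:
    return pd.Series(assignment).value_counts().sort_index()


def profile_clusters(
    matrix: pd.DataFrame,
    flags: pd.DataFrame,
    cohort: pd.DataFrame,
    assignment,
    top_k: int = 10,
    mine: bool = False,
    mining_config: MiningConfig | None = None,
) -> dict:
    """Per-cluster descriptive profile.

    Returns a dict with:

    * ``sizes`` — subjects per cluster (sums to N),
    * ``features`` — long table of per-cluster counts and column percentages
      for each categorical feature block,
    * ``prevalence`` — clusters × diseases prevalence matrix,
    * ``combinations`` — {cluster: {2: table, 3: table}} top combinations,
    * ``rules`` — {cluster: rule table} when ``mine`` is set.

    Empty clusters are reported with zero rows, not raised.
    """
    assignment = np.asarray(assignment)
    if len(assignment) != len(matrix):
        raise ValueError("assignment must cover all subjects")
    clusters = np.unique(assignment)
    sizes = cluster_sizes(assignment)

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
        tab = pd.crosstab(pd.Series(series).to_numpy(), assignment, dropna=False)
        for c in clusters:
            if c not in tab.columns:
                tab[c] = 0
        tab = tab[sorted(tab.columns)]
        long = tab.stack().rename("count").reset_index()
        long.columns = ["stratum", "cluster", "count"]
        long["feature"] = feature
        long["pct"] = [
            percent(cnt, sizes.get(cl, 0)) for cnt, cl in zip(long["count"], long["cluster"])
        ]
        blocks.append(long[["feature", "stratum", "cluster", "count", "pct"]])
    feature_table = pd.concat(blocks, ignore_index=True)

    prevalence = pd.DataFrame(
        {
            c: matrix.loc[assignment == c].mean(axis=0)
            if (assignment == c).any()
            else pd.Series(0.0, index=matrix.columns)
            for c in clusters
        }
    ).T
    prevalence.index.name = "cluster"

    combos = {}
    rules = {}
    for c in clusters:
        sub = matrix.loc[assignment == c]
        if len(sub) == 0:
            combos[c] = {2: None, 3: None}
            continue
        combos[c] = {
            2: combination_prevalence(sub, 2, top_k),
            3: combination_prevalence(sub, 3, top_k),
        }
        if mine:
            cfg = mining_config or MiningConfig()
            rules[c] = generate_rules(frequent_itemsets(sub, cfg), cfg)

    out = {
        "sizes": sizes,
        "features": feature_table,
        "prevalence": prevalence,
        "combinations": combos,
    }
    if mine:
        out["rules"] = rules
    return out


def compare_clusters(
    cohort: pd.DataFrame,
    assignment,
    continuous: tuple[str, ...] = ("age", "bmi"),
    correction: bool = False,
) -> dict:
    """Between-cluster tests: sex chi-square (overall + pairwise 2×2),
    one-way ANOVA and Tukey HSD on each continuous variable.

    Returns a JSON-serializable dict. Clusters with zero variance in a
    continuous variable are flagged under ``warnings`` rather than raised.
    """
    assignment = np.asarray(assignment)
    clusters = np.unique(assignment)
    if len(clusters) < 2:
        raise ValueError("need at least two non-empty clusters")
    report: dict = {"warnings": []}

    sex_tab = pd.crosstab(cohort["sex"].to_numpy(), assignment)
    chi2, p, dof, _ = sps.chi2_contingency(sex_tab, correction=correction)
    pairwise = {}
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            sub = sex_tab[[a, b]]
            c2, pp, dd, _ = sps.chi2_contingency(sub, correction=correction)
            pairwise[f"{a}-{b}"] = {"chi2": float(c2), "df": int(dd), "p": float(pp)}
    report["sex"] = {
        "chi2": float(chi2),
        "df": int(dof),
        "p": float(p),
        "pairwise": pairwise,
    }

    for var in continuous:
        x = pd.to_numeric(cohort[var], errors="coerce").to_numpy()
        keep = ~np.isnan(x)
        xv, g = x[keep], assignment[keep]
        groups = [xv[g == c] for c in clusters]
        for c, arr in zip(clusters, groups):
            if len(arr) > 1 and np.ptp(arr) == 0:
                report["warnings"].append(f"cluster {c}: zero variance in {var}")
        F, p = sps.f_oneway(*groups)
        dfb, dfw = len(clusters) - 1, len(xv) - len(clusters)
        tukey = pairwise_tukeyhsd(xv, g)
        # exact adjusted p-values (the printed summary rounds to 4 decimals)
        pair_labels = list(combinations(tukey.groupsunique, 2))
        report[var] = {
            "anova_F": float(F),
            "df_between": dfb,
            "df_within": dfw,
            "p": float(p),
            "tukey": [
                {
                    "group1": str(g1),
                    "group2": str(g2),
                    "meandiff": float(md),
                    "p_adj": float(pa),
                }
                for (g1, g2), md, pa in zip(
                    pair_labels, tukey.meandiffs, tukey.pvalues
                )
            ],
        }
    return report


def prevalence_heatmap_matrix(matrix: pd.DataFrame, assignment) -> pd.DataFrame:
    """Clusters × 21-disease prevalence matrix (heatmap/radar input)."""
    assignment = np.asarray(assignment)
    out = {
        c: matrix.loc[assignment == c, list(DISEASES)].mean(axis=0)
        for c in np.unique(assignment)
    }
    df = pd.DataFrame(out).T
    df.index.name = "cluster"
    return df
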
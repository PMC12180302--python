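"""Apriori frequent-itemset mining and association rules on disease data.

Level-wise Apriori: size-ℓ candidates are joined from frequent (ℓ−1)-sets
sharing a prefix, pruned by downward closure (every (ℓ−1)-subset must be
frequent), then counted in one vectorized pass over the binary matrix.
Rule metrics over subjects N:

* support(A→B)    = count(A ∪ B) / N
* confidence(A→B) = support(A ∪ B) / support(A)
* lift(A→B)       = confidence(A→B) / support(B)

Defaults mirror common practice in multimorbidity surveys: minimum support
3.0%, minimum confidence 30%, antecedents of at most three diseases (so
itemsets are explored up to size four), singleton consequents.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


@dataclass
class MiningConfig:
    min_support: float = 0.03
    min_confidence: float = 0.30
    max_antecedent: int = 3
    singleton_consequents: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_support <= 1):
            raise ValueError("min_support must be in (0, 1]")
        if not (0 < self.min_confidence <= 1):
            raise ValueError("min_confidence must be in (0, 1]")
        if self.max_antecedent < 1:
            raise ValueError("max_antecedent must be at least 1")


def frequent_itemsets(matrix, config: MiningConfig | None = None) -> dict:
    """All itemsets with support ≥ min_support, up to size max_antecedent+1.

    ``matrix`` is an N×m binary array or DataFrame; items are column names
    (or indices for plain arrays). Returns ``{frozenset: support}``.
    """
    config = config or MiningConfig()
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        values = matrix.to_numpy(dtype=bool)
    else:
        values = np.asarray(matrix, dtype=bool)
        names = list(range(values.shape[1]))
    n = len(values)
    if n == 0:
        raise ValueError("empty matrix")
    max_size = config.max_antecedent + 1

    supports: dict[frozenset, float] = {}
    # level 1
    level = {}  # sorted item tuple -> presence column
    for j, name in enumerate(names):
        s = values[:, j].mean()
        if s >= config.min_support:
            supports[frozenset([name])] = float(s)
            level[(name,)] = values[:, j]

    size = 1
    while level and size < max_size:
        keys = sorted(level)
        candidates = {}
        for a, b in combinations(keys, 2):
            if a[:-1] != b[:-1]:  # prefix join
                continue
            cand = a + (b[-1],)
            # downward closure: every size-`size` subset must be frequent
            if any(
                frozenset(cand[:i] + cand[i + 1 :]) not in supports
                for i in range(len(cand))
            ):
                continue
            candidates[cand] = level[a] & level[b]
        level = {}
        for cand, col in candidates.items():
            s = col.mean()
            if s >= config.min_support:
                supports[frozenset(cand)] = float(s)
                level[cand] = col
        size += 1
    return supports


def generate_rules(
    itemsets: dict, config: MiningConfig | None = None
) -> pd.DataFrame:
    """Association rules from frequent itemsets.

    For every frequent set S and non-empty antecedent A ⊂ S with
    |A| ≤ max_antecedent, the rule A → S∖A is emitted when its confidence
    meets the threshold. By default consequents are restricted to single
    diseases. Rules are sorted by lift, then support, descending, then
    lexicographically.
    """
    config = config or MiningConfig()
    rows = []
    for s, support_s in itemsets.items():
        if len(s) < 2:
            continue
        items = sorted(s)
        for r in range(1, len(items)):
            if r > config.max_antecedent:
                continue
            if config.singleton_consequents and len(items) - r != 1:
                continue
            for antecedent in combinations(items, r):
                a = frozenset(antecedent)
                b = s - a
                if a not in itemsets or b not in itemsets:
                    continue  # sub-itemset below support (cannot happen by closure)
                confidence = support_s / itemsets[a]
                if confidence < config.min_confidence:
                    continue
                rows.append(
                    {
                        "antecedent": tuple(sorted(a)),
                        "consequent": tuple(sorted(b)),
                        "support": support_s,
                        "confidence": confidence,
                        "lift": confidence / itemsets[b],
                    }
                )
    out = pd.DataFrame(
        rows, columns=["antecedent", "consequent", "support", "confidence", "lift"]
    )
    if len(out):
        out = out.sort_values(
            ["lift", "support", "antecedent", "consequent"],
            ascending=[False, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return out


class Apriori(BaseEstimator):
    """Estimator wrapper around the miner.

    ``fit(X)`` computes ``itemsets_`` ({frozenset: support}) and ``rules_``
    (a DataFrame with antecedent, consequent, support, confidence, lift).
    """

    def __init__(
        self,
        min_support: float = 0.03,
        min_confidence: float = 0.30,
        max_antecedent: int = 3,
        singleton_consequents: bool = True,
    ):
        self.min_support = min_support
        self.min_confidence = min_confidence
        self.max_antecedent = max_antecedent
        self.singleton_consequents = singleton_consequents

    def _config(self) -> MiningConfig:
        return MiningConfig(
            min_support=self.min_support,
            min_confidence=self.min_confidence,
            max_antecedent=self.max_antecedent,
            singleton_consequents=self.singleton_consequents,
        )

    def fit(self, X, y=None) -> "Apriori":
        config = self._config()
        self.itemsets_ = frequent_itemsets(X, config)
        self.rules_ = generate_rules(self.itemsets_, config)
        return self

    def rules_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "rules_")
        return self.rules_.copy()


def mine_rules(matrix, **kwargs) -> pd.DataFrame:
    """One-call mining: frequent itemsets then rules, returns the rule table."""
    return Apriori(**kwargs).fit(matrix).rules_
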
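"""BR+IG feature ranking.

The multilabel problem is decomposed by binary relevance into one
single-label dataset per condition; information gain (in bits) is computed
for every (feature, label) pair and aggregated across labels into a single
score per feature.  Numeric features are discretized into equal-frequency
bins first; missing values form their own category so selection never
depends on an imputation step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ConfigError, MultiLabelDataset

__all__ = ["FeatureRanking", "information_gain", "br_ig_rank", "select_top_k"]

_MISSING = "__missing__"


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector (0 log 0 := 0)."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _discretize(feature: pd.Series, bins: int) -> pd.Series:
    """Equal-frequency binning of numeric features; missing is its own bin."""
    if pd.api.types.is_numeric_dtype(feature):
        nonmiss = feature.dropna()
        if nonmiss.nunique() > 1:
            binned = pd.qcut(feature, q=min(bins, nonmiss.nunique()),
                             duplicates="drop", labels=False)
        else:
            binned = pd.Series(np.zeros(len(feature)), index=feature.index)
        cat = binned.astype(object)
    else:
        cat = feature.astype(object)
    return cat.where(feature.notna(), _MISSING)


def information_gain(feature: pd.Series, label, bins: int = 10) -> float:
    """IG = H(label) - H(label | feature), base-2 logarithm.

    A constant label has zero entropy, hence IG = 0 by definition.
    """
    label = np.asarray(label)
    if not np.isin(label, [0, 1]).all():
        raise ConfigError("label must be binary")
    cat = _discretize(pd.Series(feature).reset_index(drop=True), bins)
    n = len(label)
    h_label = _entropy(np.bincount(label.astype(int), minlength=2))
    h_cond = 0.0
    for _, idx in cat.groupby(cat, sort=False).groups.items():
        sub = label[np.asarray(idx)]
        h_cond += (len(sub) / n) * _entropy(np.bincount(sub.astype(int), minlength=2))
    return max(0.0, h_label - h_cond)


@dataclass
class FeatureRanking:
    """Per-(feature, label) IG matrix with an aggregate ordering.

    ``table`` has one row per feature: the per-label IG columns, the
    aggregate score and the 1-based rank.  ``order`` lists feature names
    by descending aggregate score (ties broken lexicographically).
    """

    table: pd.DataFrame
    order: list[str]
    aggregate: str = "mean"

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def br_ig_rank(dataset: MultiLabelDataset, bins: int = 10,
               aggregate: str = "mean") -> FeatureRanking:
    """Rank features by information gain aggregated over the BR decomposition."""
    if aggregate not in ("mean", "max"):
        raise ConfigError(f"unknown aggregate {aggregate!r}")
    Y = dataset.label_matrix()
    rows = {}
    for feat in dataset.features:
        rows[feat] = [information_gain(dataset.X[feat], Y[:, j], bins)
                      for j in range(dataset.n_labels)]
    table = pd.DataFrame(rows, index=dataset.labels).T
    agg = table.mean(axis=1) if aggregate == "mean" else table.max(axis=1)
    table["aggregate"] = agg
    # descending score, lexicographic tie-break, stable and deterministic
    order = sorted(table.index, key=lambda f: (-table.loc[f, "aggregate"], f))
    table = table.loc[order]
    table["rank"] = np.arange(1, len(order) + 1)
    return FeatureRanking(table=table, order=order, aggregate=aggregate)


def select_top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """First ``k`` features of the ranking (a prefix, so nested in k)."""
    if not 1 <= k <= len(ranking.order):
        raise ConfigError(f"k={k} out of range 1..{len(ranking.order)}")
    return ranking.order[:k]
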
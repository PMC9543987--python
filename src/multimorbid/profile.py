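"""Cohort characterization and imbalance handling.

Imbalance descriptors for a multilabel cohort D with label space L:

* label cardinality  LC(D) = (1/|D|) sum_i |Y_i|        (mean conditions)
* label density      LD(D) = LC(D) / |L|
* IRLbl(y)           = max_{y'} count(y') / count(y)    (>= 1, =1 at the
  most frequent label)
* MeanIR             = mean over labels of IRLbl

plus the multimorbidity descriptives: counts of participants by number of
conditions (optionally cross-tabulated against a stratifier such as sex),
multimorbidity prevalence (share with >= 2 conditions), and the pairwise
co-occurrence matrix of conditional prevalences.

``ml_ros_oversample`` implements multilabel random oversampling: labels
whose IRLbl exceeds the current MeanIR are minority labels; instances
carrying them are cloned at random until a clone budget is exhausted or no
minority label remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ConfigError, DataError, MultiLabelDataset

__all__ = [
    "ImbalanceProfile",
    "ConditionCountTable",
    "CooccurrenceResult",
    "OversampleResult",
    "imbalance_profile",
    "condition_count_table",
    "multimorbidity_prevalence",
    "cooccurrence_matrix",
    "ml_ros_oversample",
]


@dataclass
class ImbalanceProfile:
    cardinality: float
    density: float
    irlbl: pd.Series
    mean_ir: float

    def to_frame(self) -> pd.DataFrame:
        rows = {"cardinality": self.cardinality, "density": self.density,
                "mean_ir": self.mean_ir}
        rows.update({f"irlbl[{k}]": v for k, v in self.irlbl.items()})
        return pd.DataFrame({"value": rows})


def _label_counts(Y: np.ndarray, labels: list[str]) -> pd.Series:
    counts = pd.Series(Y.sum(axis=0), index=labels)
    zero = counts.index[counts == 0].tolist()
    if zero:
        raise DataError(f"label(s) with zero occurrences: {zero}; IRLbl undefined")
    return counts


def imbalance_profile(dataset: MultiLabelDataset) -> ImbalanceProfile:
    """Compute LC, LD, per-label IRLbl and MeanIR for a cohort."""
    Y = dataset.label_matrix()
    counts = _label_counts(Y, dataset.labels)
    cardinality = float(Y.sum(axis=1).mean())
    density = cardinality / dataset.n_labels
    irlbl = counts.max() / counts
    return ImbalanceProfile(cardinality, density, irlbl.astype(float), float(irlbl.mean()))


# ----------------------------------------------------------------------

_BUCKETS = ["0", "1", "2", "3", "4", "5+"]


def _bucket(n_cond: np.ndarray) -> pd.Categorical:
    lab = np.where(n_cond >= 5, "5+", n_cond.astype(str))
    return pd.Categorical(lab, categories=_BUCKETS, ordered=True)


@dataclass
class ConditionCountTable:
    """Participants bucketed by number of chronic conditions (0..4, 5+).

    With a stratifier, ``by_stratum`` holds the cross-tabulation (stratum
    levels as rows, buckets as columns) and ``percentages`` the
    within-bucket column percentages rounded to one decimal.
    """

    counts: pd.Series
    n: int
    by_stratum: pd.DataFrame | None = None
    percentages: pd.DataFrame | None = None
    raw_counts: pd.Series = field(default=None, repr=False)


def condition_count_table(dataset: MultiLabelDataset,
                          stratifier: str | None = None) -> ConditionCountTable:
    """Bucket instances by condition count, optionally stratified."""
    n_cond = dataset.label_matrix().sum(axis=1)
    buckets = _bucket(n_cond)
    counts = pd.Series(buckets).value_counts().reindex(_BUCKETS, fill_value=0)
    raw = pd.Series(n_cond).value_counts().sort_index()
    by_stratum = percentages = None
    if stratifier is not None:
        if stratifier not in dataset.X.columns:
            raise ConfigError(f"stratifier {stratifier!r} is not a feature")
        strat = dataset.X[stratifier]
        if strat.isna().any():
            raise DataError(f"stratifier {stratifier!r} has missing values")
        by_stratum = pd.crosstab(strat, buckets, dropna=False)
        by_stratum = by_stratum.reindex(columns=_BUCKETS, fill_value=0)
        percentages = (100 * by_stratum / by_stratum.sum(axis=0)).round(1)
    return ConditionCountTable(counts=counts, n=dataset.n, by_stratum=by_stratum,
                               percentages=percentages, raw_counts=raw)


def multimorbidity_prevalence(dataset: MultiLabelDataset) -> float:
    """Fraction of instances carrying at least two of the conditions."""
    if dataset.n_labels < 2:
        raise ConfigError("multimorbidity requires at least two label columns")
    return float((dataset.label_matrix().sum(axis=1) >= 2).mean())


# ----------------------------------------------------------------------


@dataclass
class CooccurrenceResult:
    """Pairwise conditional prevalences among condition carriers.

    ``matrix[y, x]`` is the prevalence of condition ``y`` among instances
    that have condition ``x`` (diagonal 1).  ``marginal`` is each label's
    overall prevalence; ``with_cooccurrence`` the prevalence of carrying
    the label together with at least one other, and ``isolated`` the
    prevalence of carrying it alone.
    """

    matrix: pd.DataFrame
    marginal: pd.Series
    with_cooccurrence: pd.Series
    isolated: pd.Series


def cooccurrence_matrix(dataset: MultiLabelDataset) -> CooccurrenceResult:
    Y = dataset.label_matrix().astype(float)
    labels = dataset.labels
    counts = _label_counts(dataset.label_matrix(), labels)
    joint = Y.T @ Y  # joint[y, x] = count(y and x)
    cond = joint / counts.to_numpy()[None, :]
    matrix = pd.DataFrame(cond, index=labels, columns=labels)
    marginal = counts / dataset.n
    n_cond = Y.sum(axis=1)
    with_co = pd.Series(
        [(Y[:, j].astype(bool) & (n_cond >= 2)).mean() for j in range(len(labels))],
        index=labels)
    isolated = marginal - with_co
    return CooccurrenceResult(matrix, marginal.astype(float), with_co, isolated)


# ----------------------------------------------------------------------


@dataclass
class OversampleResult:
    dataset: MultiLabelDataset
    clone_sources: list[int]
    notice: str | None = None

    @property
    def n_clones(self) -> int:
        return len(self.clone_sources)


def ml_ros_oversample(dataset: MultiLabelDataset, budget_fraction: float = 0.25,
                      seed: int | None = None) -> OversampleResult:
    """IRLbl-driven random oversampling of minority-label instances.

    Repeatedly sweeps the labels whose imbalance ratio exceeds the current
    MeanIR, cloning (uniformly, with replacement) one instance carrying
    each such label per visit.  Label counts are updated after every clone
    so the stopping condition is exact.  Stops when the clone budget
    ``ceil(budget_fraction * n)`` is exhausted or no minority label
    remains.  All original instances are retained; ``clone_sources`` lists
    the source row (original index) of each appended clone.
    """
    if budget_fraction <= 0:
        raise ConfigError("budget_fraction must be positive")
    Y = dataset.label_matrix()
    counts = _label_counts(Y, dataset.labels).to_numpy().astype(float)
    rng = np.random.default_rng(seed)
    budget = int(np.ceil(budget_fraction * dataset.n))
    # carriers[l]: original-row indices currently carrying label l (clones
    # re-add their source row index, which is equivalent for sampling)
    carriers = [list(np.flatnonzero(Y[:, l])) for l in range(dataset.n_labels)]
    clones: list[int] = []
    while len(clones) < budget:
        mean_ir = (counts.max() / counts).mean()
        minority = [l for l in range(dataset.n_labels)
                    if counts.max() / counts[l] > mean_ir]
        if not minority:
            break
        for l in minority:
            if len(clones) >= budget:
                break
            if counts.max() / counts[l] <= (counts.max() / counts).mean():
                continue  # label left the minority set mid-sweep
            src = int(rng.choice(carriers[l]))
            clones.append(src)
            for m in np.flatnonzero(Y[src]):
                counts[m] += 1
                carriers[m].append(src)
    if not clones:
        return OversampleResult(dataset, [], notice="no minority labels; dataset unchanged")
    X_new = pd.concat([dataset.X, dataset.X.iloc[clones]], ignore_index=True)
    Y_new = pd.concat([dataset.Y, dataset.Y.iloc[clones]], ignore_index=True)
    out = MultiLabelDataset(X_new, Y_new, allow_single_label=dataset.n_labels == 1)
    return OversampleResult(out, clones)
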
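"""Repeated stratified cross-validation harness with nested tuning.

Outer evaluation is multilabel-stratified k-fold CV (default 10-fold,
repeated 5 times); hyperparameters are tuned per outer fold by an inner
(default 3-fold) CV on the training partition, selected by inner Hamming
loss.  Imputation is fitted inside each fold, oversampling (when enabled)
is applied to the training partition only, and feature selection inside
the feature-curve experiment is recomputed on each training partition by
default.  Test partitions are never touched by any fitting step; an
optional audit trail records the row indices each stage consumed so this
can be asserted by instrumentation tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ConfigError, FeatureEncoder, Imputer, MultiLabelDataset
from .forest import MtvRandomForest, MtvRfConfig
from .metrics import MetricReport, compute_metrics
from .profile import ml_ros_oversample
from .selection import br_ig_rank, select_top_k
from .transform import (BaseLearnerSpec, BinaryRelevance, ClassifierChain,
                        DependentBinaryRelevance)

__all__ = [
    "CVPlan",
    "ExperimentReport",
    "METHODS",
    "iterative_stratification",
    "run_cv_experiment",
    "run_feature_curve",
]

METHODS = ("MTV-RF", "RF-BR", "RF-CC", "RF-DBR", "SVM-BR", "SVM-CC", "SVM-DBR")

_METRIC_NAMES = ["hamming_loss", "subset_accuracy", "accuracy",
                 "precision", "recall", "f_measure"]


# ----------------------------------------------------------------------
# Fold assignment


def iterative_stratification(Y, k: int, seed: int | None = None) -> np.ndarray:
    """Multilabel-stratified fold assignment (iterative stratification).

    Labels are processed from rarest to most frequent; each unassigned
    instance carrying the current label goes to the fold with the largest
    remaining demand for that label, ties broken by smallest fold then by
    a seeded random draw.  Instances with no labels fill the smallest
    folds.  Returns an array of fold indices in ``0..k-1``.
    """
    Y = np.asarray(Y)
    n, L = Y.shape
    if k > n:
        raise ConfigError(f"cannot make {k} folds from {n} instances")
    rng = np.random.default_rng(seed)
    assignment = np.full(n, -1)
    # desired per-fold share of instances and of each label
    fold_size_left = np.full(k, n / k)
    label_left = np.tile(Y.sum(axis=0)[:, None] / k, (1, k)).astype(float)  # L x k
    remaining = Y.sum(axis=0).astype(float)
    order = np.argsort(remaining, kind="stable")  # rarest label first
    for l in order:
        carriers = np.flatnonzero((Y[:, l] == 1) & (assignment == -1))
        for i in carriers[rng.permutation(len(carriers))]:
            # folds at size capacity are ineligible, keeping sizes balanced
            eligible = np.flatnonzero(fold_size_left > 1e-9)
            if eligible.size == 0:
                eligible = np.arange(k)
            demand = label_left[l][eligible]
            best = eligible[np.flatnonzero(demand == demand.max())]
            if len(best) > 1:
                sizes = fold_size_left[best]
                best = best[np.flatnonzero(sizes == sizes.max())]
                f = int(rng.choice(best))
            else:
                f = int(best[0])
            assignment[i] = f
            fold_size_left[f] -= 1
            label_left[Y[i] == 1, f] -= 1
    free = np.flatnonzero(assignment == -1)
    for i in free[rng.permutation(len(free))]:
        best = np.flatnonzero(fold_size_left == fold_size_left.max())
        f = int(rng.choice(best)) if len(best) > 1 else int(best[0])
        assignment[i] = f
        fold_size_left[f] -= 1
    return assignment


# ----------------------------------------------------------------------
# Plans and reports


@dataclass
class CVPlan:
    """Cross-validation layout and fold-internal processing options.

    ``grid``: ``None`` uses the method's default hyperparameter grid,
    ``{}`` disables tuning, otherwise a mapping of hyperparameter name to
    candidate values.  ``imputation`` is ``"train"`` (fit on the training
    partition, apply to both — the default) or ``"separate"`` (fit on each
    partition independently).
    """

    k: int = 10
    repeats: int = 5
    inner: int = 3
    seed: int | None = None
    oversample: bool = False
    oversample_budget: float = 0.25
    imputation: str = "train"
    feature_subset: list | None = None
    grid: dict | None = None

    def __post_init__(self):
        if self.k < 2 or self.inner < 2:
            raise ConfigError("k and inner fold counts must be >= 2")
        if self.repeats < 1:
            raise ConfigError("repeats must be >= 1")
        if self.imputation not in ("train", "separate"):
            raise ConfigError(f"unknown imputation mode {self.imputation!r}")


@dataclass
class ExperimentReport:
    method: str
    fold_reports: list = field(default_factory=list)
    fold_params: list = field(default_factory=list)
    failures: int = 0

    @property
    def n_folds(self) -> int:
        return len(self.fold_reports)

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.fold_reports])

    @property
    def means(self) -> dict:
        return {m: float(self._values(m).mean()) for m in _METRIC_NAMES}

    @property
    def sds(self) -> dict:
        return {m: float(self._values(m).std(ddof=1)) if self.n_folds > 1 else 0.0
                for m in _METRIC_NAMES}

    def summary(self) -> pd.DataFrame:
        row = {"method": self.method, "n_folds": self.n_folds}
        row.update(self.means)
        row.update({f"{m}_sd": v for m, v in self.sds.items()})
        return pd.DataFrame([row])


# ----------------------------------------------------------------------
# Method construction


def _is_forest_method(method: str) -> bool:
    return method == "MTV-RF" or method.startswith("RF-")


def default_grid(method: str, p: int) -> dict:
    """Small standard tuning grid per learner family."""
    if _is_forest_method(method):
        return {"mtry": sorted({int(np.ceil(np.sqrt(p))), max(1, round(p / 3))}),
                "min_node_size": [5, 20]}
    return {"C": [0.1, 1.0, 10.0], "gamma": [1.0 / p, 4.0 / p]}


class _FittedMethod:
    """A fitted model plus the fold-local preprocessing needed to score."""

    def __init__(self, method, model, encoder=None):
        self.method = method
        self.model = model
        self.encoder = encoder

    def predict(self, dataset: MultiLabelDataset):
        if self.method == "MTV-RF":
            return self.model.predict(dataset.X)
        return self.model.predict(self.encoder.transform(dataset.X).to_numpy(float))


def _fit_method(method: str, train: MultiLabelDataset, hyper: dict,
                method_params: dict, seed: int | None) -> _FittedMethod:
    if method == "MTV-RF":
        cfg = MtvRfConfig(
            n_trees=method_params.get("n_trees", 100),
            mtry=hyper.get("mtry", method_params.get("mtry")),
            min_node_size=hyper.get("min_node_size", method_params.get("min_node_size", 5)),
            weight_structure=method_params.get("weight_structure", "uniform"),
            seed=seed,
        )
        return _FittedMethod(method, MtvRandomForest(cfg).fit(train))
    kind, scheme = method.split("-")
    encoder = FeatureEncoder("onehot").fit(train.X)
    X = encoder.transform(train.X).to_numpy(float)
    Y = train.label_matrix()
    if kind == "RF":
        params = {"n_estimators": method_params.get("n_estimators", 100)}
        if "mtry" in hyper:
            params["max_features"] = min(hyper["mtry"], X.shape[1])
        if "min_node_size" in hyper:
            params["min_samples_split"] = max(2, hyper["min_node_size"])
        base = BaseLearnerSpec("rf", params)
    else:
        params = {"C": hyper.get("C", 1.0), "gamma": hyper.get("gamma", "scale")}
        base = BaseLearnerSpec("svm", params)
    cls = {"BR": BinaryRelevance, "CC": ClassifierChain,
           "DBR": DependentBinaryRelevance}[scheme]
    model = cls(base, seed=seed)
    model.fit(X, Y, train.labels)
    return _FittedMethod(method, model, encoder)


def _tune(method: str, train: MultiLabelDataset, plan: CVPlan,
          method_params: dict, seed: int | None) -> dict:
    """Pick hyperparameters by inner stratified CV, minimizing Hamming loss."""
    grid = plan.grid
    if grid is None:
        p = len(train.features)
        grid = default_grid(method, p)
    if not grid:
        return {}
    keys = list(grid)
    points = [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]
    if len(points) == 1:
        return points[0]
    folds = iterative_stratification(train.label_matrix(), plan.inner, seed)
    best_loss, best_point = np.inf, points[0]
    for point in points:
        losses = []
        for f in range(plan.inner):
            tr = np.flatnonzero(folds != f)
            te = np.flatnonzero(folds == f)
            fitted = _fit_method(method, train.subset(tr), point, method_params, seed)
            pred = fitted.predict(train.subset(te))
            losses.append(compute_metrics(train.Y.iloc[te], pred).hamming_loss)
        mean_loss = float(np.mean(losses))
        if mean_loss < best_loss - 1e-12:
            best_loss, best_point = mean_loss, point
    return best_point


# ----------------------------------------------------------------------
# The outer loop


def _run_cv(dataset: MultiLabelDataset, method: str, plan: CVPlan,
            method_params: dict | None = None, select_k: int | None = None,
            global_ranking=None, ig_bins: int = 10,
            audit: list | None = None) -> ExperimentReport:
    if method not in METHODS:
        raise ConfigError(f"unknown method {method!r}; choose from {METHODS}")
    method_params = method_params or {}
    if plan.feature_subset is not None:
        dataset = dataset.select_features(plan.feature_subset)
    report = ExperimentReport(method=method)
    ss = np.random.SeedSequence(plan.seed)
    repeat_seeds = ss.spawn(plan.repeats)
    for r, rseed in enumerate(repeat_seeds):
        fold_seed, *fold_children = (int(s.generate_state(1)[0] % 2**31)
                                     for s in rseed.spawn(plan.k + 1))
        folds = iterative_stratification(dataset.label_matrix(), plan.k, fold_seed)
        for f in range(plan.k):
            child_seed = fold_children[f]
            test_rows = np.flatnonzero(folds == f)
            train_rows = np.flatnonzero(folds != f)
            entry = {"repeat": r, "fold": f,
                     "test_rows": set(test_rows.tolist()),
                     "imputer_rows": set(), "oversample_rows": set(),
                     "selection_rows": set(), "tuning_rows": set()}
            train = dataset.subset(train_rows)
            test = dataset.subset(test_rows)
            # fold-internal feature selection (leakage-safe default)
            if select_k is not None:
                if global_ranking is not None:
                    subset = select_top_k(global_ranking, select_k)
                else:
                    ranking = br_ig_rank(train, bins=ig_bins)
                    subset = select_top_k(ranking, select_k)
                    entry["selection_rows"] |= set(train_rows.tolist())
                # keep the dataset's original column order for stability
                subset = [c for c in dataset.features if c in set(subset)]
                train = train.select_features(subset)
                test = test.select_features(subset)
            # fold-internal imputation
            imputer = Imputer().fit(train)
            entry["imputer_rows"] |= set(train_rows.tolist())
            train = imputer.transform(train)
            if plan.imputation == "train":
                test = imputer.transform(test)
            else:
                test = Imputer().fit_transform(test)
            # oversample the training partition only
            if plan.oversample:
                res = ml_ros_oversample(train, plan.oversample_budget, seed=child_seed)
                train = res.dataset
                entry["oversample_rows"] |= {int(train_rows[s]) for s in res.clone_sources}
            # nested tuning on the training partition
            hyper = _tune(method, train, plan, method_params, child_seed)
            entry["tuning_rows"] |= set(train_rows.tolist())
            fitted = _fit_method(method, train, hyper, method_params, child_seed)
            pred = fitted.predict(test)
            report.fold_reports.append(compute_metrics(test.Y, pred))
            report.fold_params.append(hyper)
            if audit is not None:
                audit.append(entry)
    return report


def run_cv_experiment(dataset: MultiLabelDataset, method: str, plan: CVPlan,
                      method_params: dict | None = None,
                      audit: list | None = None) -> ExperimentReport:
    """Repeated stratified nested-CV evaluation of one method."""
    return _run_cv(dataset, method, plan, method_params, audit=audit)


def run_feature_curve(dataset: MultiLabelDataset, methods, ks, plan: CVPlan,
                      method_params: dict | None = None, mode: str = "per_fold",
                      ig_bins: int = 10) -> pd.DataFrame:
    """CV performance of each method on top-k BR+IG feature subsets.

    ``mode="per_fold"`` recomputes the ranking on each training partition
    (no selection leakage); ``mode="global"`` ranks once on the full
    dataset, reproducing a single-ranking workflow.  Returns a tidy table
    with one row per (method, k).
    """
    if mode not in ("per_fold", "global"):
        raise ConfigError(f"unknown ranking mode {mode!r}")
    p = len(dataset.features if plan.feature_subset is None else plan.feature_subset)
    ks = sorted(ks)
    if max(ks) > p:
        raise ConfigError(f"k={max(ks)} exceeds the {p} available features")
    ranking = br_ig_rank(dataset, bins=ig_bins) if mode == "global" else None
    rows = []
    for method in methods:
        for k in ks:
            rep = _run_cv(dataset, method, plan, method_params,
                          select_k=k, global_ranking=ranking, ig_bins=ig_bins)
            row = {"method": method, "k": k}
            row.update(rep.means)
            rows.append(row)
    return pd.DataFrame(rows)
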
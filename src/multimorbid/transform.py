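"""Problem-transformation multilabel classifiers.

Three reductions of the multilabel task to binary tasks over a pluggable
binary base learner:

* **Binary relevance (BR)** — one independent binary classifier per label;
  label dependence is ignored.
* **Classifier chain (CC)** — classifiers ordered along a chain; the k-th
  is trained on the features augmented with the *true* values of the k-1
  preceding labels, and at prediction time consumes its predecessors'
  *predicted* (thresholded) values sequentially.
* **Dependent binary relevance (DBR)** — each label's classifier is
  trained on the features augmented with the true values of *all other*
  labels; at prediction time an internal BR stage estimates the other
  labels first and feeds those estimates to the second stage.

Base learners follow a minimal contract: ``fit(X, y)`` on a numeric design
matrix and binary target, and ``score(X)`` returning a probability in
[0, 1] per instance.  A label that is constant in the training data is
handled by a constant-rate predictor rather than failing the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data import ConfigError, PredictionMatrix

__all__ = [
    "BaseLearnerSpec",
    "BinaryRelevance",
    "ClassifierChain",
    "DependentBinaryRelevance",
]


class _ConstantLearner:
    """Predicts a fixed probability; used when a training label is constant."""

    def __init__(self, rate: float):
        self.rate = float(rate)

    def fit(self, X, y):  # pragma: no cover - trivial
        return self

    def score(self, X) -> np.ndarray:
        return np.full(len(X), self.rate)


class _SklearnLearner:
    """Adapter giving scikit-learn classifiers the fit/score contract."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def score(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        pos = list(self.estimator.classes_).index(1)
        return proba[:, pos]


@dataclass
class BaseLearnerSpec:
    """Factory for seeded binary base learners.

    ``kind`` is ``"rf"`` (random forest) or ``"svm"`` (RBF support vector
    machine with Platt-scaled probabilities, standardized inputs);
    ``params`` are forwarded to the underlying scikit-learn estimator.
    """

    kind: str = "rf"
    params: dict = field(default_factory=dict)

    def make(self, seed: int | None = None):
        if self.kind == "rf":
            defaults = dict(n_estimators=100)
            defaults.update(self.params)
            return _SklearnLearner(RandomForestClassifier(random_state=seed, **defaults))
        if self.kind == "svm":
            defaults = dict(C=1.0, kernel="rbf", gamma="scale", probability=True)
            defaults.update(self.params)
            est = Pipeline([
                ("scale", StandardScaler()),
                ("svc", SVC(random_state=seed, **defaults)),
            ])
            return _SklearnLearner(est)
        raise ConfigError(f"unknown base learner kind {self.kind!r}")


def _fit_binary(spec: BaseLearnerSpec, X: np.ndarray, y: np.ndarray, seed: int):
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        import warnings
        warnings.warn("constant training label; using a constant-rate predictor")
        return _ConstantLearner(y.mean())
    return spec.make(seed).fit(X, y)


def _child_seeds(seed: int | None, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]


class BinaryRelevance:
    """Independent per-label binary classifiers."""

    method = "BR"

    def __init__(self, base: BaseLearnerSpec, threshold: float = 0.5,
                 seed: int | None = None):
        self.base = base
        self.threshold = threshold
        self.seed = seed
        self.learners_: list | None = None
        self.labels_: list[str] | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray, labels: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        self.labels_ = list(labels) if labels is not None else [f"y{j}" for j in range(Y.shape[1])]
        seeds = _child_seeds(self.seed, Y.shape[1])
        self.learners_ = [_fit_binary(self.base, X, Y[:, j], seeds[j])
                          for j in range(Y.shape[1])]
        self.n_features_ = X.shape[1]
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted(X)
        return np.column_stack([lrn.score(np.asarray(X, dtype=float))
                                for lrn in self.learners_])

    def predict(self, X: np.ndarray) -> PredictionMatrix:
        return PredictionMatrix.from_scores(self.predict_scores(X), self.labels_,
                                            self.threshold)

    def _check_fitted(self, X):
        if self.learners_ is None:
            raise ConfigError("model is not fitted")
        if np.asarray(X).shape[1] != self.n_features_:
            raise ConfigError(
                f"expected {self.n_features_} feature columns, got {np.asarray(X).shape[1]}")


class ClassifierChain:
    """Chained per-label classifiers consuming predecessor labels.

    The chain order defaults to the label-column order of the training
    matrix; results depend on it, so it is stored on the fitted model.
    """

    method = "CC"

    def __init__(self, base: BaseLearnerSpec, order: Sequence[int] | None = None,
                 threshold: float = 0.5, seed: int | None = None):
        self.base = base
        self.order = order
        self.threshold = threshold
        self.seed = seed
        self.learners_: list | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray, labels: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        L = Y.shape[1]
        self.labels_ = list(labels) if labels is not None else [f"y{j}" for j in range(L)]
        order = list(self.order) if self.order is not None else list(range(L))
        if sorted(order) != list(range(L)):
            raise ConfigError("chain order must be a permutation of the labels")
        self.order_ = order
        seeds = _child_seeds(self.seed, L)
        self.learners_ = []
        for k, j in enumerate(order):
            # true values of the k preceding chain labels augment the features
            aug = np.hstack([X, Y[:, order[:k]].astype(float)])
            self.learners_.append(_fit_binary(self.base, aug, Y[:, j], seeds[k]))
        self.n_features_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> PredictionMatrix:
        if self.learners_ is None:
            raise ConfigError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_:
            raise ConfigError(
                f"expected {self.n_features_} feature columns, got {X.shape[1]}")
        n, L = X.shape[0], len(self.order_)
        scores = np.zeros((n, L))
        hard = np.zeros((n, L))
        prev = np.zeros((n, 0))
        for k, j in enumerate(self.order_):
            s = self.learners_[k].score(np.hstack([X, prev]))
            scores[:, j] = s
            hard[:, j] = (s >= self.threshold).astype(float)
            prev = np.hstack([prev, hard[:, [j]]])
        return PredictionMatrix.from_scores(scores, self.labels_, self.threshold)


class DependentBinaryRelevance:
    """Two-stage dependent binary relevance.

    Stage 1 is an internal BR model used only at prediction time to
    estimate the other labels; stage 2 classifiers are trained with the
    true values of all other labels appended to the features.
    """

    method = "DBR"

    def __init__(self, base: BaseLearnerSpec, threshold: float = 0.5,
                 seed: int | None = None):
        self.base = base
        self.threshold = threshold
        self.seed = seed
        self.stage1_: BinaryRelevance | None = None
        self.stage2_: list | None = None

    def fit(self, X: np.ndarray, Y: np.ndarray, labels: Sequence[str] | None = None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        L = Y.shape[1]
        if L < 2:
            raise ConfigError("DBR requires at least two labels")
        self.labels_ = list(labels) if labels is not None else [f"y{j}" for j in range(L)]
        s1_seed, s2_seed = _child_seeds(self.seed, 2)
        self.stage1_ = BinaryRelevance(self.base, self.threshold, seed=s1_seed)
        self.stage1_.fit(X, Y, self.labels_)
        seeds = _child_seeds(s2_seed, L)
        self.stage2_ = []
        for j in range(L):
            others = [m for m in range(L) if m != j]
            aug = np.hstack([X, Y[:, others].astype(float)])
            self.stage2_.append(_fit_binary(self.base, aug, Y[:, j], seeds[j]))
        self.n_features_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> PredictionMatrix:
        if self.stage2_ is None:
            raise ConfigError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_:
            raise ConfigError(
                f"expected {self.n_features_} feature columns, got {X.shape[1]}")
        stage1_hard = self.stage1_.predict(X).predicted.astype(float)
        L = len(self.labels_)
        scores = np.zeros((X.shape[0], L))
        for j in range(L):
            others = [m for m in range(L) if m != j]
            aug = np.hstack([X, stage1_hard[:, others]])
            scores[:, j] = self.stage2_[j].score(aug)
        return PredictionMatrix.from_scores(scores, self.labels_, self.threshold)
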
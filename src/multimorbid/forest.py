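"""Multivariate random forest for joint prediction of binary conditions.

An algorithm-adaptation multilabel classifier: each tree is grown on a
bootstrap sample and every node split is chosen by a *composite normalized
Gini* criterion that pools all labels,

    score(split) = sum_l  w_l * DeltaGini_l / Gini_l(parent),

where ``Gini_l = 2 p_l (1 - p_l)`` is the binary Gini impurity of label
``l`` at the node, ``DeltaGini_l`` the usual impurity decrease of the
split for that label, and ``w_l`` nonnegative label weights summing to 1.
Labels already pure at the parent contribute 0.  Normalizing each label's
decrease by its parent impurity puts rare and common conditions on a
comparable scale before pooling, which is how the joint splitting rule
couples the labels.

Two weight structures are provided: ``uniform`` (identity covariance
structure, the default) and ``compound_symmetry`` (weights proportional to
each label's mean absolute correlation with the other labels, so strongly
co-occurring conditions steer the splits).

Terminal nodes store per-label positive fractions; the forest prediction
for a label is the mean terminal fraction over trees, thresholded at 0.5.
Out-of-bag row indices are retained per tree for permutation variable
importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ConfigError, DataError, MultiLabelDataset, PredictionMatrix
from .metrics import hamming_loss, subset_accuracy

__all__ = [
    "MtvRfConfig",
    "MtvRandomForest",
    "ImportanceReport",
    "composite_gini_score",
]


@dataclass
class MtvRfConfig:
    """Forest hyperparameters.

    ``mtry`` defaults to ``ceil(sqrt(p))``; ``min_node_size`` is the
    smallest node that may still be split.  ``label_weights`` overrides
    the weight structure with explicit weights (normalized internally).
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int = 5
    label_weights: np.ndarray | None = None
    weight_structure: str = "uniform"
    seed: int | None = None

    def __post_init__(self):
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.weight_structure not in ("uniform", "compound_symmetry"):
            raise ConfigError(f"unknown weight structure {self.weight_structure!r}")


@dataclass
class ImportanceReport:
    """Permutation importances (mean loss increase), descending."""

    table: pd.DataFrame
    runs: int
    loss: str

    @property
    def order(self) -> list[str]:
        return list(self.table.index)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _gini(p: np.ndarray) -> np.ndarray:
    return 2.0 * p * (1.0 - p)


def composite_gini_score(Y_node: np.ndarray, left_mask: np.ndarray,
                         weights: np.ndarray | None = None) -> float:
    """Composite normalized Gini decrease of one candidate split.

    ``Y_node`` is the (m, L) label matrix at the node and ``left_mask`` a
    boolean vector sending each instance to the left child.  Both children
    must be nonempty.
    """
    Y_node = np.asarray(Y_node, dtype=float)
    left_mask = np.asarray(left_mask, dtype=bool)
    m, L = Y_node.shape
    n_left = int(left_mask.sum())
    if n_left == 0 or n_left == m:
        raise ConfigError("split must produce two nonempty children")
    w = np.full(L, 1.0 / L) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    p_parent = Y_node.mean(axis=0)
    p_left = Y_node[left_mask].mean(axis=0)
    p_right = Y_node[~left_mask].mean(axis=0)
    g_parent = _gini(p_parent)
    delta = g_parent - (n_left / m) * _gini(p_left) - ((m - n_left) / m) * _gini(p_right)
    active = g_parent > 0
    if not active.any():
        return 0.0
    return float((w[active] * delta[active] / g_parent[active]).sum())


# ----------------------------------------------------------------------
# Tree representation: parallel arrays, -1 marking leaves.


@dataclass
class _Tree:
    feature: list = field(default_factory=list)
    threshold: list = field(default_factory=list)
    left: list = field(default_factory=list)
    right: list = field(default_factory=list)
    value: list = field(default_factory=list)  # per-label positive fraction
    oob: np.ndarray | None = None

    def add_node(self) -> int:
        for arr in (self.feature, self.threshold, self.left, self.right, self.value):
            arr.append(None)
        return len(self.feature) - 1

    def predict(self, X: np.ndarray, L: int) -> np.ndarray:
        out = np.zeros((X.shape[0], L))
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, rows = stack.pop()
            if rows.size == 0:
                continue
            if self.feature[node] is None:
                out[rows] = self.value[node]
            else:
                go_left = X[rows, self.feature[node]] <= self.threshold[node]
                stack.append((self.left[node], rows[go_left]))
                stack.append((self.right[node], rows[~go_left]))
        return out


class MtvRandomForest:
    """Forest of multivariate trees over mixed-type predictor tables.

    Categorical features are handled by ordering their levels by the
    pooled positive-label rate (computed once per forest on the training
    data) and splitting on the resulting rank codes — the classical
    ordered-level reduction of subset splits.  Predictors must be fully
    imputed before fitting.
    """

    def __init__(self, config: MtvRfConfig | None = None, **kwargs):
        self.config = config if config is not None else MtvRfConfig(**kwargs)
        self.trees_: list[_Tree] | None = None

    # -------------------------------------------------- encoding
    def _fit_encoding(self, X: pd.DataFrame, Y: np.ndarray) -> None:
        self._cat_codes: dict[str, dict] = {}
        self._cat_default: dict[str, float] = {}
        pooled = Y.mean(axis=1)  # per-instance mean label rate
        for col in X.columns:
            if not pd.api.types.is_numeric_dtype(X[col]):
                rate = pd.Series(pooled).groupby(X[col].reset_index(drop=True)).mean()
                order = rate.sort_values(kind="stable").index
                self._cat_codes[col] = {lev: float(i) for i, lev in enumerate(order)}
                self._cat_default[col] = float(len(order) - 1) / 2.0

    def _encode(self, X: pd.DataFrame) -> np.ndarray:
        cols = []
        for col in self.features_:
            s = X[col]
            if col in self._cat_codes:
                codes = s.map(self._cat_codes[col]).astype(float)
                codes = codes.fillna(self._cat_default[col])
                cols.append(codes.to_numpy())
            else:
                v = pd.to_numeric(s).to_numpy(dtype=float)
                cols.append(v)
        M = np.column_stack(cols)
        if np.isnan(M).any():
            raise DataError("predictors contain missing values; impute before the forest")
        return M

    # -------------------------------------------------- fitting
    def fit(self, dataset: MultiLabelDataset) -> "MtvRandomForest":
        if dataset.n < 2:
            raise ConfigError("need at least two instances to grow a forest")
        cfg = self.config
        self.features_ = dataset.features
        self.labels_ = dataset.labels
        Y = dataset.label_matrix().astype(float)
        self._fit_encoding(dataset.X, Y)
        X = self._encode(dataset.X)
        n, p = X.shape
        L = Y.shape[1]
        self.weights_ = self._label_weights(Y)
        mtry = cfg.mtry if cfg.mtry is not None else int(np.ceil(np.sqrt(p)))
        mtry = max(1, min(mtry, p))
        ss = np.random.SeedSequence(cfg.seed)
        self.trees_ = []
        for child in ss.spawn(cfg.n_trees):
            rng = np.random.default_rng(child)
            boot = rng.integers(0, n, size=n)
            tree = self._grow_tree(X[boot], Y[boot], mtry, rng)
            tree.oob = np.setdiff1d(np.arange(n), np.unique(boot))
            self.trees_.append(tree)
        return self

    def _label_weights(self, Y: np.ndarray) -> np.ndarray:
        L = Y.shape[1]
        cfg = self.config
        if cfg.label_weights is not None:
            w = np.asarray(cfg.label_weights, dtype=float)
            if w.shape != (L,) or (w < 0).any() or w.sum() <= 0:
                raise ConfigError("label_weights must be nonnegative with positive sum")
            return w / w.sum()
        if cfg.weight_structure == "uniform":
            return np.full(L, 1.0 / L)
        # compound symmetry: weight by mean |corr| with the other labels
        C = np.corrcoef(Y.T)
        C = np.nan_to_num(C, nan=0.0)
        np.fill_diagonal(C, 0.0)
        w = np.abs(C).sum(axis=1) / max(L - 1, 1) + 1e-9
        return w / w.sum()

    def _grow_tree(self, X: np.ndarray, Y: np.ndarray, mtry: int,
                   rng: np.random.Generator) -> _Tree:
        cfg = self.config
        p = X.shape[1]
        w = self.weights_
        tree = _Tree()
        root = tree.add_node()
        stack = [(root, np.arange(X.shape[0]))]
        while stack:
            node, rows = stack.pop()
            Yn = Y[rows]
            p_node = Yn.mean(axis=0)
            g_parent = _gini(p_node)
            split = None
            if rows.size >= cfg.min_node_size and (g_parent > 0).any():
                split = self._best_split(X, Yn, rows, g_parent, w, mtry, rng)
            if split is None:
                tree.feature[node] = None
                tree.value[node] = p_node
                continue
            feat, thr = split
            tree.feature[node] = feat
            tree.threshold[node] = thr
            tree.value[node] = p_node
            left = tree.add_node()
            right = tree.add_node()
            tree.left[node], tree.right[node] = left, right
            mask = X[rows, feat] <= thr
            stack.append((left, rows[mask]))
            stack.append((right, rows[~mask]))
        return tree

    def _best_split(self, X, Yn, rows, g_parent, w, mtry, rng):
        m, L = Yn.shape
        active = g_parent > 0
        wa = w[active]
        ga = g_parent[active]
        Ya = Yn[:, active]
        feats = rng.choice(X.shape[1], size=min(mtry, X.shape[1]), replace=False)
        best = (0.0, None, None)
        for f in feats:
            x = X[rows, f]
            order = np.argsort(x, kind="stable")
            xs = x[order]
            cut = np.flatnonzero(xs[:-1] < xs[1:])
            if cut.size == 0:
                continue
            csum = np.cumsum(Ya[order], axis=0)
            n_left = (cut + 1).astype(float)
            n_right = m - n_left
            p_left = csum[cut] / n_left[:, None]
            p_right = (csum[-1] - csum[cut]) / n_right[:, None]
            delta = (ga[None, :]
                     - (n_left / m)[:, None] * _gini(p_left)
                     - (n_right / m)[:, None] * _gini(p_right))
            scores = (wa[None, :] * delta / ga[None, :]).sum(axis=1)
            k = int(np.argmax(scores))
            if scores[k] > best[0] + 1e-12:
                thr = 0.5 * (xs[cut[k]] + xs[cut[k] + 1])
                best = (float(scores[k]), int(f), thr)
        return None if best[1] is None else (best[1], best[2])

    # -------------------------------------------------- prediction
    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        if self.trees_ is None:
            raise ConfigError("forest is not fitted")
        missing = [c for c in self.features_ if c not in X.columns]
        if missing:
            raise ConfigError(f"missing feature column(s): {missing}")
        M = self._encode(X)
        L = len(self.labels_)
        acc = np.zeros((len(X), L))
        for tree in self.trees_:
            acc += tree.predict(M, L)
        return acc / len(self.trees_)

    def predict(self, X: pd.DataFrame | MultiLabelDataset) -> PredictionMatrix:
        if isinstance(X, MultiLabelDataset):
            X = X.X
        return PredictionMatrix.from_scores(self.predict_scores(X), self.labels_, 0.5)

    # -------------------------------------------------- importance
    def _oob_scores(self, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Sum of per-tree scores over trees where each row is out-of-bag."""
        L = len(self.labels_)
        sums = np.zeros((M.shape[0], L))
        counts = np.zeros(M.shape[0])
        for tree in self.trees_:
            if tree.oob.size == 0:
                continue
            sums[tree.oob] += tree.predict(M[tree.oob], L)
            counts[tree.oob] += 1
        return sums, counts

    def permutation_importance(self, dataset: MultiLabelDataset, runs: int = 100,
                               loss: str = "hamming",
                               seed: int | None = None) -> ImportanceReport:
        """Generalized permutation variable importance on out-of-bag rows.

        For each run and feature, the feature's values are permuted across
        the out-of-bag-covered instances, out-of-bag predictions are
        recomputed, and the importance contribution is the increase of the
        selected multilabel loss over the intact out-of-bag loss.
        Contributions are averaged over ``runs``.
        """
        if runs < 1:
            raise ConfigError("runs must be >= 1")
        if self.trees_ is None:
            raise ConfigError("forest is not fitted")
        loss_fn = {"hamming": hamming_loss,
                   "subset_error": lambda t, p: 1.0 - subset_accuracy(t, p)}.get(loss)
        if loss_fn is None:
            raise ConfigError(f"unknown loss {loss!r}")
        M = self._encode(dataset.X)
        Y = dataset.label_matrix()
        sums, counts = self._oob_scores(M)
        covered = counts > 0
        if not covered.any():
            raise ConfigError("no out-of-bag coverage; grow more trees")
        truth = Y[covered]
        base_pred = (sums[covered] / counts[covered, None] >= 0.5).astype(np.int8)
        base_loss = loss_fn(truth, base_pred)
        rng = np.random.default_rng(seed)
        p = len(self.features_)
        imp = np.zeros(p)
        cov_idx = np.flatnonzero(covered)
        for _ in range(runs):
            for j in range(p):
                Mp = M.copy()
                Mp[cov_idx, j] = M[rng.permutation(cov_idx), j]
                s, c = self._oob_scores(Mp)
                pred = (s[covered] / np.maximum(c[covered, None], 1) >= 0.5).astype(np.int8)
                imp[j] += loss_fn(truth, pred) - base_loss
        imp /= runs
        table = pd.DataFrame({"importance": imp}, index=self.features_)
        table = table.sort_values("importance", ascending=False, kind="stable")
        return ImportanceReport(table=table, runs=runs, loss=loss)
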
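"""Multivariate random forest: split criterion, growth, importance."""

import numpy as np
import pandas as pd
import pytest

import multimorbid as mm
from multimorbid.data import ConfigError
from conftest import make_dataset


def grid_dataset(n=60, seed=0, noise_free=True):
    """Two labels driven by two binary features (separable when noise-free)."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    X = pd.DataFrame({"a": a.astype(float), "b": b.astype(float)})
    Y = pd.DataFrame({"y1": a, "y2": b})
    return mm.MultiLabelDataset(X, Y)


class TestCompositeGini:
    def test_perfect_single_label_split_scores_half_with_two_labels(self):
        # split separates label 1 exactly; label 2 unaffected (stays pure-mixed)
        Y = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        score = mm.composite_gini_score(Y, np.array([True, True, False, False]))
        assert score == pytest.approx(0.5)

    def test_uninformative_split_scores_zero(self):
        # both children inherit the parent's per-label distributions
        Y = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        score = mm.composite_gini_score(Y, np.array([True, True, False, False]))
        assert score == pytest.approx(0.0)

    def test_empty_child_rejected(self):
        Y = np.array([[1, 0], [0, 1]])
        with pytest.raises(ConfigError):
            mm.composite_gini_score(Y, np.array([True, True]))

    def test_single_label_reduces_to_classical_normalized_gini(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            y = rng.integers(0, 2, 12)
            if y.min() == y.max():
                continue
            mask = np.zeros(12, bool)
            mask[rng.choice(12, rng.integers(1, 11), replace=False)] = True
            if mask.all() or not mask.any():
                continue
            # scalar-impurity oracle
            def gini(v):
                p = v.mean()
                return 2 * p * (1 - p)
            nl = mask.sum()
            delta = gini(y) - nl / 12 * gini(y[mask]) - (12 - nl) / 12 * gini(y[~mask])
            expected = delta / gini(y)
            got = mm.composite_gini_score(y.reshape(-1, 1), mask)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_candidate_search_on_small_node(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 3))
        Y = rng.integers(0, 2, (10, 2))
        Y[:, 0] = (X[:, 1] > 0).astype(int)  # make one label splittable
        best_oracle = 0.0
        for f in range(3):
            for thr in np.unique(X[:, f])[:-1]:
                mask = X[:, f] <= thr
                if 0 < mask.sum() < 10:
                    best_oracle = max(best_oracle,
                                      mm.composite_gini_score(Y, mask))
        ds = mm.MultiLabelDataset(pd.DataFrame(X, columns=list("abc")),
                                  pd.DataFrame(Y, columns=["y1", "y2"]))
        rf = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=1, mtry=3,
                                               min_node_size=10, seed=0))
        rf.fit(ds)
        tree = rf.trees_[0]
        # root split of a single tree with mtry=all must attain the oracle best
        boot = None  # root is grown on a bootstrap; evaluate directly instead
        Xenc = rf._encode(ds.X)
        mask = Xenc[:, tree.feature[0]] <= tree.threshold[0]
        root_score = mm.composite_gini_score(Y, mask) if 0 < mask.sum() < 10 else 0.0
        assert root_score <= best_oracle + 1e-9


class TestForestFit:
    def test_single_tree_memorizes_separable_toy(self):
        ds = grid_dataset()
        rf = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=1, mtry=2,
                                               min_node_size=2, seed=0)).fit(ds)
        # bootstrap may omit rows; check on many trees for exact memorization
        rf_many = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=25, mtry=2,
                                                    min_node_size=2, seed=0)).fit(ds)
        assert mm.hamming_loss(ds.Y, rf_many.predict(ds.X)) == 0.0

    def test_fixed_seed_reproduces_forest(self):
        ds = grid_dataset(seed=3)
        a = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=10, seed=5)).fit(ds)
        b = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=10, seed=5)).fit(ds)
        np.testing.assert_array_equal(a.predict_scores(ds.X), b.predict_scores(ds.X))

    def test_shared_driver_chosen_at_root(self):
        # two correlated labels driven by one feature among noise
        rng = np.random.default_rng(12)
        n = 300
        driver = rng.standard_normal(n)
        X = pd.DataFrame({"driver": driver,
                          "noise1": rng.standard_normal(n),
                          "noise2": rng.standard_normal(n)})
        p = 1 / (1 + np.exp(-3 * driver))
        Y = pd.DataFrame({"y1": (rng.random(n) < p).astype(int),
                          "y2": (rng.random(n) < p).astype(int)})
        ds = mm.MultiLabelDataset(X, Y)
        rf = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=30, mtry=3,
                                               min_node_size=50, seed=0)).fit(ds)
        roots = [t.feature[0] for t in rf.trees_]
        assert np.mean([f == 0 for f in roots]) >= 0.9

    def test_scores_are_probabilities_and_tree_averaging_is_idempotent(self):
        ds = grid_dataset(seed=7)
        rf1 = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=1, seed=9)).fit(ds)
        s1 = rf1.predict_scores(ds.X)
        assert ((s1 >= 0) & (s1 <= 1)).all()
        # duplicating the same tree leaves the averaged scores unchanged
        rf1.trees_ = rf1.trees_ * 2
        np.testing.assert_allclose(rf1.predict_scores(ds.X), s1)

    def test_categorical_features_supported(self):
        ds = make_dataset(
            {"cat": ["a", "a", "b", "b", "c", "c"] * 5,
             "num": list(np.linspace(0, 1, 30))},
            {"y1": [1, 1, 0, 0, 0, 0] * 5, "y2": [0, 0, 0, 0, 1, 1] * 5})
        rf = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=20, mtry=2,
                                               min_node_size=2, seed=0)).fit(ds)
        assert mm.hamming_loss(ds.Y, rf.predict(ds.X)) == 0.0

    def test_schema_mismatch_raises(self):
        ds = grid_dataset()
        rf = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=2, seed=0)).fit(ds)
        with pytest.raises(ConfigError, match="missing feature"):
            rf.predict(ds.X.rename(columns={"a": "zzz"}))

    def test_more_trees_stabilize_scores_across_seeds(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(150)
        p = 1 / (1 + np.exp(-1.5 * x))
        ds = mm.MultiLabelDataset(
            pd.DataFrame({"x": x, "noise": rng.standard_normal(150)}),
            pd.DataFrame({"y1": (rng.random(150) < p).astype(int),
                          "y2": (rng.random(150) < p).astype(int)}))
        def spread(n_trees):
            scores = [mm.MtvRandomForest(
                mm.MtvRfConfig(n_trees=n_trees, min_node_size=20, seed=s)
            ).fit(ds).predict_scores(ds.X) for s in range(6)]
            return np.var(np.stack(scores), axis=0).mean()
        assert spread(200) < spread(10)


class TestPermutationImportance:
    def _planted(self, n=250, seed=0):
        rng = np.random.default_rng(seed)
        driver = rng.standard_normal(n)
        X = pd.DataFrame({"driver": driver,
                          "idle": rng.standard_normal(n)})
        p = 1 / (1 + np.exp(-2.5 * driver))
        Y = pd.DataFrame({"y1": (rng.random(n) < p).astype(int),
                          "y2": (rng.random(n) < p).astype(int)})
        return mm.MultiLabelDataset(X, Y)

    def test_sole_driver_has_largest_positive_importance(self):
        ds = self._planted()
        rf = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=30, mtry=2,
                                               min_node_size=25, seed=1)).fit(ds)
        rep = rf.permutation_importance(ds, runs=5, seed=1)
        assert rep.order[0] == "driver"
        assert rep.table.loc["driver", "importance"] > 0

    def test_unused_feature_has_near_zero_importance(self):
        ds = self._planted()
        rf = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=30, mtry=2,
                                               min_node_size=25, seed=1)).fit(ds)
        rep = rf.permutation_importance(ds, runs=5, seed=1)
        assert abs(rep.table.loc["idle", "importance"]) < 0.05

    def test_reproducible_under_fixed_seed(self):
        ds = self._planted(seed=4)
        rf = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=15, seed=2)).fit(ds)
        a = rf.permutation_importance(ds, runs=3, seed=9).table
        b = rf.permutation_importance(ds, runs=3, seed=9).table
        pd.testing.assert_frame_equal(a, b)

    def test_run_count_validated(self):
        ds = self._planted()
        rf = mm.MtvRandomForest(mm.MtvRfConfig(n_trees=5, seed=0)).fit(ds)
        with pytest.raises(ConfigError):
            rf.permutation_importance(ds, runs=0)
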
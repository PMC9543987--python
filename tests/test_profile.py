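"""Imbalance descriptors, multimorbidity descriptives, and ML-ROS."""

import numpy as np
import pandas as pd
import pytest

import multimorbid as mm
from multimorbid.data import DataError
from conftest import make_dataset, random_dataset


def counts_dataset(counts, L=None):
    """Dataset whose label occurrence counts equal ``counts`` (disjoint carriers)."""
    L = L or len(counts)
    n = sum(counts)
    Y = np.zeros((n, L), dtype=int)
    start = 0
    for j, c in enumerate(counts):
        Y[start:start + c, j] = 1
        start += c
    X = pd.DataFrame({"x": np.arange(n, dtype=float)})
    return mm.MultiLabelDataset(X, pd.DataFrame(Y, columns=[f"y{j}" for j in range(L)]))


class TestImbalanceProfile:
    def test_direct_ratio_arithmetic(self):
        prof = mm.imbalance_profile(counts_dataset([6, 3, 2]))
        assert prof.irlbl.tolist() == [1.0, 2.0, 3.0]
        assert prof.mean_ir == pytest.approx(2.0)

    def test_balanced_labels_give_unit_ratios(self):
        prof = mm.imbalance_profile(counts_dataset([4, 4, 4]))
        assert (prof.irlbl == 1.0).all() and prof.mean_ir == 1.0

    def test_saturated_labels(self):
        ds = make_dataset({"x": [0.0, 1.0]}, {"a": [1, 1], "b": [1, 1], "c": [1, 1]})
        prof = mm.imbalance_profile(ds)
        assert prof.cardinality == 3.0 and prof.density == 1.0

    def test_zero_occurrence_label_is_explicit_error(self):
        ds = make_dataset({"x": [0.0, 1.0]}, {"a": [1, 1], "b": [0, 0]})
        with pytest.raises(DataError, match="'b'"):
            mm.imbalance_profile(ds)

    def test_agrees_with_recount_oracle_on_random_datasets(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ds = random_dataset(rng)
            Y = ds.label_matrix()
            prof = mm.imbalance_profile(ds)
            # brute-force recount
            card = sum(int(Y[i].sum()) for i in range(ds.n)) / ds.n
            counts = [int(Y[:, j].sum()) for j in range(ds.n_labels)]
            irlbl = [max(counts) / c for c in counts]
            assert prof.cardinality == pytest.approx(card)
            assert prof.density == pytest.approx(card / ds.n_labels)
            assert np.allclose(prof.irlbl, irlbl)
            assert prof.mean_ir == pytest.approx(np.mean(irlbl))
            assert prof.irlbl.min() == 1.0 and prof.mean_ir >= 1.0


class TestConditionCounts:
    def test_all_instances_with_two_conditions(self):
        ds = make_dataset({"x": [0.0] * 3},
                          {"a": [1, 1, 1], "b": [1, 1, 1], "c": [0, 0, 0]})
        table = mm.condition_count_table(ds)
        assert table.counts["2"] == 3 and table.counts.sum() == 3

    def test_bucket_counts_sum_to_n(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            ds = random_dataset(rng)
            assert mm.condition_count_table(ds).counts.sum() == ds.n

    def test_consistency_with_multimorbidity_prevalence(self):
        rng = np.random.default_rng(13)
        ds = random_dataset(rng, n=200, L=6)
        table = mm.condition_count_table(ds)
        at_least_two = table.counts[["2", "3", "4", "5+"]].sum()
        assert mm.multimorbidity_prevalence(ds) == pytest.approx(at_least_two / ds.n)

    def test_prevalence_extremes(self):
        all_multi = make_dataset({"x": [0.0, 1.0]}, {"a": [1, 1], "b": [1, 1]})
        assert mm.multimorbidity_prevalence(all_multi) == 1.0
        none = make_dataset({"x": [0.0, 1.0]}, {"a": [1, 0], "b": [0, 1]})
        assert mm.multimorbidity_prevalence(none) == 0.0


class TestCooccurrence:
    def test_identical_columns_have_unit_conditional_prevalence(self):
        ds = make_dataset({"x": [0.0] * 4},
                          {"a": [1, 1, 0, 0], "b": [1, 1, 0, 0], "c": [1, 0, 1, 0]})
        co = mm.cooccurrence_matrix(ds)
        assert co.matrix.loc["a", "b"] == 1.0 and co.matrix.loc["b", "a"] == 1.0
        assert np.allclose(np.diag(co.matrix), 1.0)

    def test_matches_exhaustive_pair_counting_on_hand_built_dataset(self):
        Y = pd.DataFrame({"a": [1, 1, 0, 1, 0], "b": [1, 0, 1, 1, 0],
                          "c": [0, 1, 1, 0, 1]})
        ds = mm.MultiLabelDataset(pd.DataFrame({"x": [0.0] * 5}), Y)
        co = mm.cooccurrence_matrix(ds)
        arr = Y.to_numpy()
        for yi, y in enumerate(Y.columns):
            for xi, x in enumerate(Y.columns):
                both = sum(int(arr[i, yi] and arr[i, xi]) for i in range(5))
                assert co.matrix.loc[y, x] == pytest.approx(both / arr[:, xi].sum())

    def test_independent_labels_approach_marginal_prevalence(self):
        rng = np.random.default_rng(21)
        Y = pd.DataFrame({"a": (rng.random(20000) < 0.5).astype(int),
                          "b": (rng.random(20000) < 0.3).astype(int)})
        ds = mm.MultiLabelDataset(pd.DataFrame({"x": np.zeros(20000)}), Y)
        co = mm.cooccurrence_matrix(ds)
        assert co.matrix.loc["a", "b"] == pytest.approx(0.5, abs=0.02)

    def test_marginal_splits_into_isolated_plus_cooccurring(self, small_cohort):
        co = mm.cooccurrence_matrix(small_cohort)
        assert np.allclose(co.marginal, co.with_cooccurrence + co.isolated)


class TestMlRos:
    def test_balanced_dataset_returned_unchanged(self):
        res = mm.ml_ros_oversample(counts_dataset([4, 4, 4]), 0.5, seed=0)
        assert res.n_clones == 0 and res.notice is not None
        assert res.dataset.n == 12

    def test_clones_come_from_rare_label_carriers(self):
        ds = counts_dataset([8, 2])
        res = mm.ml_ros_oversample(ds, 0.5, seed=3)
        assert res.n_clones > 0
        rare_carriers = set(np.flatnonzero(ds.label_matrix()[:, 1]).tolist())
        assert set(res.clone_sources) <= rare_carriers
        after = mm.imbalance_profile(res.dataset)
        assert res.dataset.label_matrix()[:, 1].sum() > 2

    def test_mean_ir_never_increases_and_originals_retained(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            ds = random_dataset(rng)
            before = mm.imbalance_profile(ds).mean_ir
            res = mm.ml_ros_oversample(ds, 0.3, seed=int(rng.integers(2**31)))
            after = mm.imbalance_profile(res.dataset).mean_ir
            assert after <= before + 1e-9
            assert res.dataset.n <= ds.n + int(np.ceil(0.3 * ds.n))
            # original rows preserved verbatim at the front
            assert np.array_equal(res.dataset.label_matrix()[:ds.n], ds.label_matrix())

    def test_reproducible_given_seed(self):
        ds = counts_dataset([10, 4, 2])
        a = mm.ml_ros_oversample(ds, 0.4, seed=5)
        b = mm.ml_ros_oversample(ds, 0.4, seed=5)
        assert a.clone_sources == b.clone_sources
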
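"""Undersampling strategies against direct arithmetic and exhaustive oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tispred import (
    BalancerSpec,
    balance,
    mclus_undersample,
    random_undersample,
    sbc_quotas,
    sbc_undersample,
)
from tispred.balancing import largest_remainder


class TestLargestRemainder:
    def test_spec_quota_example(self):
        # raw quotas 2.4 and 1.6 with total 4 -> 2 and 2
        assert largest_remainder([2.4, 1.6], 4, caps=[6, 4]).tolist() == [2, 2]

    def test_caps_respected_and_shortfall_redistributed(self):
        alloc = largest_remainder([3.5, 0.5], 4, caps=[2, 4])
        assert alloc.tolist() == [2, 2]

    def test_insufficient_caps_fill_everything(self):
        assert largest_remainder([5.0, 5.0], 20, caps=[3, 4]).tolist() == [3, 4]

    @given(
        weights=st.lists(st.floats(0.01, 50, allow_nan=False),
                         min_size=1, max_size=8),
        total=st.integers(0, 40),
    )
    @settings(max_examples=100, deadline=None)
    def test_sums_to_total_when_feasible(self, weights, total):
        raw = total * np.array(weights) / np.sum(weights)
        caps = np.full(len(raw), 100)
        alloc = largest_remainder(raw, total, caps)
        assert alloc.sum() == total
        assert (alloc >= 0).all()


class TestRandom:
    def test_matches_minority_count(self):
        idx = random_undersample(100, 10, BalancerSpec(method="random", seed=1))
        assert len(idx) == 10 and len(set(idx.tolist())) == 10
        assert idx.max() < 100

    def test_saturates_when_majority_small(self):
        idx = random_undersample(5, 10, BalancerSpec(method="random", seed=1))
        assert sorted(idx.tolist()) == [0, 1, 2, 3, 4]

    def test_deterministic_for_fixed_seed(self):
        spec = BalancerSpec(method="random", seed=42)
        a = random_undersample(1000, 50, spec)
        b = random_undersample(1000, 50, spec)
        assert (a == b).all()

    def test_ratio_m(self):
        idx = random_undersample(100, 10, BalancerSpec(method="random", m=2, seed=0))
        assert len(idx) == 20


class TestSbc:
    def test_quota_arithmetic_example(self):
        # clusters (MA,MI) = (6,2) and (4,2): ratios 3 and 2, raw 2.4/1.6 -> 2/2
        assert sbc_quotas([6, 4], [2, 2], m=1).tolist() == [2, 2]

    def test_single_cluster_ratio_cancels(self):
        assert sbc_quotas([50], [7], m=1).tolist() == [7]

    def test_zero_minority_cluster_uses_one(self):
        # Size_MI = 2 so the target is 2; ratios 8/1 and 4/2 give raw
        # quotas 1.6 and 0.4 -> integers 2 and 0
        assert sbc_quotas([8, 4], [0, 2], m=1).tolist() == [2, 0]

    @given(
        size_ma=st.lists(st.integers(0, 30), min_size=2, max_size=6),
        size_mi=st.lists(st.integers(0, 10), min_size=2, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_quotas_sum_to_target(self, size_ma, size_mi):
        k = min(len(size_ma), len(size_mi))
        size_ma, size_mi = size_ma[:k], size_mi[:k]
        if sum(size_ma) == 0 or sum(size_mi) == 0:
            return
        quotas = sbc_quotas(size_ma, size_mi, m=1)
        assert quotas.sum() == min(sum(size_ma), sum(size_mi))
        assert (quotas <= np.array(size_ma)).all()

    def test_selection_is_subset_at_target_size(self, rng):
        X_ma = rng.normal(size=(60, 5))
        X_mi = rng.normal(size=(12, 5))
        idx = sbc_undersample(X_ma, X_mi, BalancerSpec(method="sbc", seed=2))
        assert len(idx) == 12
        assert len(set(idx.tolist())) == 12 and idx.max() < 60

    def test_centroid_selection_variant(self, rng):
        X_ma = rng.normal(size=(40, 3))
        X_mi = rng.normal(size=(8, 3))
        spec = BalancerSpec(method="sbc", seed=2, sbc_selection="centroid")
        idx = sbc_undersample(X_ma, X_mi, spec)
        assert len(idx) == 8
        assert (idx == sbc_undersample(X_ma, X_mi, spec)).all()


def kmeans_global_optimum(X: np.ndarray, k: int):
    """Exhaustive minimum within-cluster sum of squares over all partitions."""
    n = len(X)
    best, best_assign = np.inf, None
    for assign in itertools.product(range(k), repeat=n):
        if len(set(assign)) != k:
            continue
        a = np.array(assign)
        wcss = sum(
            ((X[a == c] - X[a == c].mean(axis=0)) ** 2).sum()
            for c in range(k)
        )
        if wcss < best - 1e-12:
            best, best_assign = wcss, a
    return best_assign


class TestMclus:
    def test_nearest_to_centroid_on_separated_groups(self):
        # three well-separated triples with distinct within-group distances,
        # so the nearest-to-centroid member of each group is unambiguous
        X = np.array([
            [0.0, 0.0], [1.0, 0.0], [0.0, 2.0],
            [20.0, 0.0], [21.0, 0.0], [20.0, 2.0],
            [0.0, 20.0], [1.0, 20.0], [0.0, 22.0],
        ])
        assign = kmeans_global_optimum(X, 3)
        expected = set()
        for c in range(3):
            members = np.nonzero(assign == c)[0]
            centroid = X[members].mean(axis=0)
            d = np.linalg.norm(X[members] - centroid, axis=1)
            expected.add(members[np.argmin(d)])
        idx = mclus_undersample(X, 3, BalancerSpec(method="mclus", seed=0))
        assert set(idx.tolist()) == expected

    def test_identical_points_degenerate_geometry(self):
        X = np.ones((8, 4))
        idx = mclus_undersample(X, 5, BalancerSpec(method="mclus", seed=0))
        assert len(idx) == 5

    def test_size_contract(self, rng):
        X = rng.normal(size=(50, 6))
        for mc in (5, 17, 50):
            idx = mclus_undersample(X, mc, BalancerSpec(method="mclus", seed=3))
            assert len(idx) == mc
            assert len(set(idx.tolist())) == mc

    def test_take_s_reduces_cluster_count(self, rng):
        X = rng.normal(size=(60, 4))
        for s in (1, 2, 3):
            spec = BalancerSpec(method="mclus", mclus_take=s, seed=1)
            idx = mclus_undersample(X, 12, spec)
            assert len(idx) == 12  # k = ceil(12/s) clusters, still 12 selected

    def test_majority_smaller_than_minority_takes_all(self, rng):
        X = rng.normal(size=(4, 3))
        idx = mclus_undersample(X, 10, BalancerSpec(method="mclus", seed=0))
        assert idx.tolist() == [0, 1, 2, 3]


class TestDispatch:
    @pytest.mark.parametrize("method", ["none", "random", "sbc", "mclus"])
    def test_all_methods_return_exact_subsets(self, method, rng):
        X_ma = rng.normal(size=(40, 8))
        X_mi = rng.normal(size=(10, 8))
        spec = BalancerSpec(method=method, seed=7)
        idx = balance(X_ma, X_mi, spec)
        assert len(set(idx.tolist())) == len(idx)
        assert idx.min() >= 0 and idx.max() < 40
        if method != "none":
            assert len(idx) == 10  # m:1 ratio
        # identity membership: selected rows are rows of the input
        assert (X_ma[idx] == np.asarray(X_ma)[idx]).all()

    @pytest.mark.parametrize("method", ["random", "sbc", "mclus"])
    def test_determinism(self, method, rng):
        X_ma = rng.normal(size=(30, 5))
        X_mi = rng.normal(size=(9, 5))
        spec = BalancerSpec(method=method, seed=11)
        assert (balance(X_ma, X_mi, spec) == balance(X_ma, X_mi, spec)).all()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            BalancerSpec(method="smote")
        with pytest.raises(ValueError):
            BalancerSpec(mclus_take=4)
        with pytest.raises(ValueError):
            BalancerSpec(m=0)
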
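import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster

from xenofrag.cna import DegenerateInputError
from xenofrag.genome import InvalidSpecError
from xenofrag.stats import (
    bh_adjust,
    cluster_and_project,
    count_informative,
    marker_auc,
    marker_auc_series,
    permutation_test,
    two_group_test,
)


def brute_force_auc(a, b):
    """Pairwise win/tie enumeration, folded for orientation."""
    wins = ties = 0
    for x in a:
        for y in b:
            if x > y:
                wins += 1
            elif x == y:
                ties += 1
    auc = (wins + 0.5 * ties) / (len(a) * len(b))
    return max(auc, 1 - auc)


def exhaustive_balanced_splits(n):
    """All distinct balanced 2-group splits of range(n), up to relabeling."""
    idx = set(range(n))
    seen = set()
    for comb in itertools.combinations(range(n), n // 2):
        key = min(frozenset(comb), frozenset(idx - set(comb)), key=sorted)
        seen.add((key, frozenset(idx - set(key))))
    return [np.array(sorted(g1)) for g1, _ in seen]


class TestMarkerAUC:
    def test_perfect_separation(self):
        assert marker_auc([5, 6, 7, 1, 2, 3], ["a"] * 3 + ["b"] * 3) == 1.0

    def test_constant_values_give_half(self):
        assert marker_auc([4, 4, 4, 4], ["a", "a", "b", "b"]) == 0.5

    def test_ties_get_half_credit(self):
        # case {5,6,7} vs control {1,2,6}: 7 wins + 1 tie over 9 pairs
        assert marker_auc([5, 6, 7, 1, 2, 6], ["a"] * 3 + ["b"] * 3) == pytest.approx(
            7.5 / 9
        )

    def test_matches_pair_enumeration_with_ties(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            vals = rng.integers(0, 8, size=12).astype(float)  # forces ties
            got = marker_auc(vals, ["a"] * 6 + ["b"] * 6)
            assert got == pytest.approx(brute_force_auc(vals[:6], vals[6:]))

    @given(st.lists(st.integers(0, 100), min_size=12, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_folding_makes_auc_label_invariant(self, vals):
        labels = ["a"] * 6 + ["b"] * 6
        flipped = ["b"] * 6 + ["a"] * 6
        assert marker_auc(vals, labels) == pytest.approx(marker_auc(vals, flipped))

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidSpecError):
            marker_auc([1, 2, 3], ["a", "a", "a"])


class TestCountInformative:
    def test_constant_markers_are_uninformative(self):
        m = pd.DataFrame(np.ones((12, 5)))
        n, markers = count_informative(m, ["a"] * 6 + ["b"] * 6, 0.9)
        assert n == 0 and markers == []

    def test_single_separating_marker(self):
        m = pd.DataFrame({"m1": [1, 2, 3, 7, 8, 9], "m2": [5, 5, 5, 5, 5, 5]})
        n, markers = count_informative(m, ["a"] * 3 + ["b"] * 3, 0.9)
        assert n == 1 and markers == ["m1"]

    def test_threshold_is_strict(self):
        m = pd.DataFrame({"m1": [1.0, 2, 3, 7, 8, 9]})
        n, _ = count_informative(m, ["a"] * 3 + ["b"] * 3, threshold=1.0)
        assert n == 0  # AUC == 1.0 is not > 1.0

    def test_null_false_positive_rate_matches_exhaustive_enumeration(self):
        # For tie-free data the AUC distribution over labelings is
        # data-independent, so P(AUC > 0.9 | exchangeable 6v6) follows from
        # enumerating all balanced splits once.
        splits = exhaustive_balanced_splits(12)
        vals = np.arange(12, dtype=float)
        labels = np.zeros(12, dtype=int)
        exceed = 0
        for g1 in splits:
            labels[:] = 0
            labels[g1] = 1
            if marker_auc(vals, labels) > 0.9:
                exceed += 1
        p_null = exceed / len(splits)
        rng = np.random.default_rng(3)
        n_eff, n_null = 50, 950
        effect = np.concatenate(
            [rng.normal(0, 1, (6, n_eff)), rng.normal(8, 1, (6, n_eff))]
        )
        noise = rng.normal(0, 1, (12, n_null))
        m = pd.DataFrame(np.hstack([effect, noise]))
        n, _ = count_informative(m, ["a"] * 6 + ["b"] * 6, 0.9)
        expected = n_eff + n_null * p_null
        sd = np.sqrt(n_null * p_null * (1 - p_null))
        assert abs(n - expected) <= 4 * sd


class TestPermutation:
    def test_constant_matrix_gives_p_one(self):
        m = pd.DataFrame(np.ones((12, 10)))
        res = permutation_test(m, ["a"] * 6 + ["b"] * 6, n_perm=100, seed=1)
        assert res.observed_informative == 0
        assert (res.null_counts == 0).all()
        assert res.p_value == 1.0

    def test_2v2_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(4, 30)))
        labels = np.array(["a", "a", "b", "b"])
        observed, _ = count_informative(m, labels, 0.8)
        null = []
        for g1 in exhaustive_balanced_splits(4):
            lab = np.where(np.isin(np.arange(4), g1), "x", "y")
            null.append(count_informative(m, lab, 0.8)[0])
        p_exact = np.mean([c >= observed for c in null])
        res = permutation_test(m, labels, n_perm=3000, threshold=0.8, seed=2)
        se = np.sqrt(p_exact * (1 - p_exact) / 3000)
        assert abs(res.p_value - p_exact) <= max(3 * se, 0.02)

    def test_null_p_values_are_roughly_uniform(self):
        # exchangeable cohorts: P(p <= 0.05) must sit near (at or below) 5%
        rng = np.random.default_rng(13)
        labels = ["a"] * 6 + ["b"] * 6
        hits = 0
        reps = 200
        for i in range(reps):
            m = pd.DataFrame(rng.normal(size=(12, 50)))
            res = permutation_test(m, labels, n_perm=200, threshold=0.8, seed=1000 + i)
            hits += res.p_value <= 0.05
        assert 0.01 <= hits / reps <= 0.12

    def test_seeded_runs_are_bit_reproducible(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(12, 20)))
        labels = ["a"] * 6 + ["b"] * 6
        r1 = permutation_test(m, labels, n_perm=300, seed=9)
        r2 = permutation_test(m, labels, n_perm=300, seed=9)
        assert np.array_equal(r1.null_counts, r2.null_counts)
        assert r1.p_value == r2.p_value

    def test_unbalanced_labels_rejected(self):
        m = pd.DataFrame(np.zeros((5, 3)))
        with pytest.raises(InvalidSpecError):
            permutation_test(m, ["a", "a", "a", "b", "b"])

    def test_q95_is_null_quantile(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(12, 40)))
        res = permutation_test(m, ["a"] * 6 + ["b"] * 6, n_perm=500, seed=3)
        assert res.null_q95 == pytest.approx(np.quantile(res.null_counts, 0.95))


class TestTwoGroupTest:
    def test_fully_separated_3v3_exact_p(self):
        r = two_group_test([1, 2, 3], [5, 6, 7])
        assert r.method == "U-test (exact)"
        assert r.p_value == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        r = two_group_test([1, 2, 3], [1, 2, 3])
        assert r.p_value == pytest.approx(1.0)

    def test_paired_t_zero_variance_flagged(self):
        r = two_group_test([1, 2, 3], [1, 2, 3], paired=True, test="ttest")
        assert r.degenerate and r.p_value == 1.0

    def test_hodges_lehmann_shift_sign_and_ci(self):
        rng = np.random.default_rng(5)
        a = rng.normal(3.0, 1, 30)
        b = rng.normal(0.0, 1, 30)
        r = two_group_test(a, b)
        assert 2.0 < r.shift_estimate < 4.0
        assert r.ci_low < r.shift_estimate < r.ci_high
        assert r.ci_low > 0  # clearly separated groups

    def test_insufficient_n_rejected(self):
        with pytest.raises(InvalidSpecError):
            two_group_test([1], [2, 3])
        with pytest.raises(InvalidSpecError):
            two_group_test([1, 2, 3], [1, 2], paired=True)


class TestBH:
    def test_hand_computed_step_up(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidSpecError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_never_below_raw_max_one(self, ps):
        adj = bh_adjust(ps)
        assert (adj <= 1.0 + 1e-12).all()
        assert (adj >= np.asarray(ps) - 1e-12).all()


class TestClusterAndProject:
    def test_two_clusters_recovered_at_top_split(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1, (4, 20)), rng.normal(6, 1, (4, 20))])
        m = pd.DataFrame(X, index=[f"s{i}" for i in range(8)])
        order, link, scores, var = cluster_and_project(m)
        groups = fcluster(link, t=2, criterion="maxclust")
        assert len(set(groups[:4])) == 1 and len(set(groups[4:])) == 1
        assert groups[0] != groups[-1]
        assert var.sum() == pytest.approx(100.0)

    def test_duplicated_sample_merges_first_at_height_zero(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(4, 10))
        X[1] = X[0]
        m = pd.DataFrame(X)
        _, link, _, _ = cluster_and_project(m)
        assert link[0, 2] == pytest.approx(0.0)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            cluster_and_project(pd.DataFrame(np.ones((4, 6))))


def test_marker_auc_series_matches_scalar_auc():
    rng = np.random.default_rng(10)
    m = pd.DataFrame(rng.normal(size=(12, 8)))
    labels = ["a"] * 6 + ["b"] * 6
    series = marker_auc_series(m, labels)
    for col in m.columns:
        assert series[col] == pytest.approx(marker_auc(m[col], labels))
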
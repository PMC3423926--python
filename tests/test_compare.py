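"""Pearson similarity, UPGMA, bootstrap supports, d statistic, permutation test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from soilshift import (
    SimilarityMatrix,
    bootstrap_support,
    dissimilarity_d,
    n_distinct_partitions,
    pearson_similarity,
    permutation_test_d,
    upgma,
)
from soilshift.compare import DegenerateProfileError


def frame(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols)


def brute_r(x, y) -> float:
    # textbook formula from raw sums
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, syy, sxy = sum(v * v for v in x), sum(v * v for v in y), sum(
        a * b for a, b in zip(x, y)
    )
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


class TestPearsonSimilarity:
    def test_perfect_correlation(self):
        sim = pearson_similarity(frame({"a": [1, 2, 3], "b": [2, 4, 6]}))
        assert sim.loc("a", "b") == pytest.approx(100.0)

    def test_perfect_anticorrelation(self):
        sim = pearson_similarity(frame({"a": [1, 2, 3], "b": [3, 2, 1]}))
        assert sim.loc("a", "b") == pytest.approx(-100.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(42)
        prof = frame({k: rng.random(20) for k in "abc"})
        sim = pearson_similarity(prof)
        for a, b in itertools.combinations("abc", 2):
            expected = 100 * brute_r(prof[a].tolist(), prof[b].tolist())
            assert abs(sim.loc(a, b) - expected) < 1e-9

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(0)
        prof = frame({k: rng.random(30) for k in "abcd"})
        scaled = prof.copy()
        scaled["b"] = scaled["b"] * 37.5
        diff = pearson_similarity(prof).values - pearson_similarity(scaled).values
        assert np.abs(diff).max() < 1e-9

    def test_constant_profile_error_names_sample(self):
        with pytest.raises(DegenerateProfileError, match="'flat'"):
            pearson_similarity(frame({"ok": [1, 2, 3], "flat": [5, 5, 5]}))


def sim_from_dissimilarity(ids, dis: dict) -> SimilarityMatrix:
    n = len(ids)
    m = np.full((n, n), 100.0)
    for (a, b), d in dis.items():
        i, j = ids.index(a), ids.index(b)
        m[i, j] = m[j, i] = 100.0 - d
    return SimilarityMatrix(list(ids), m)


class TestUpgma:
    def test_three_sample_hand_example(self):
        # dissimilarities AB=2, AC=8, BC=8: merge {A,B} at height 1,
        # then C joins at height 4 (average of 8 and 8, halved)
        sim = sim_from_dissimilarity(
            ["A", "B", "C"], {("A", "B"): 2, ("A", "C"): 8, ("B", "C"): 8}
        )
        dend = upgma(sim)
        assert dend.height_of({"A", "B"}) == pytest.approx(1.0)
        assert dend.height_of({"A", "B", "C"}) == pytest.approx(4.0)

    def test_all_pairs_equal_flat_merges(self):
        sim = sim_from_dissimilarity(
            list("ABC"), {p: 6 for p in itertools.combinations("ABC", 2)}
        )
        dend = upgma(sim)
        assert set(dend.clusters.values()) == {3.0}

    def test_ultrametric_and_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            prof = pd.DataFrame(rng.random((25, 6)), columns=list("ABCDEF"))
            sim = pearson_similarity(prof)
            dend = upgma(sim)
            # heights non-decreasing from leaves to root
            hs = sorted(dend.clusters.items(), key=lambda kv: len(kv[0]))
            for key, h in hs:
                for other, oh in hs:
                    if other < key:
                        assert oh <= h + 1e-9
            # merge heights equal scipy's average-linkage distances / 2
            z = linkage(squareform(100.0 - sim.values, checks=False), "average")
            ours = sorted(dend.clusters.values())
            scipys = sorted(z[:, 2] / 2.0)
            assert np.allclose(ours, scipys, atol=1e-9)


class TestBootstrapSupport:
    def test_identical_pair_gets_full_support(self):
        rng = np.random.default_rng(1)
        base = rng.random(40)
        prof = frame(
            {
                "a1": base + rng.normal(0, 0.01, 40),
                "a2": base + rng.normal(0, 0.01, 40),
                "b1": rng.random(40),
                "b2": rng.random(40),
            }
        )
        dend = bootstrap_support(prof, n_boot=50, seed=0)
        assert dend.supports[frozenset({"a1", "a2"})] == pytest.approx(100.0)
        assert all(0 <= v <= 100 for v in dend.supports.values())


class TestDissimilarityD:
    def test_identical_profiles_zero(self):
        sim = SimilarityMatrix(list("abcd"), np.full((4, 4), 100.0))
        res = dissimilarity_d(sim, ["a", "b"], ["c", "d"])
        assert res.d == 0.0

    def test_hand_arithmetic(self):
        # within pairs 90 and 80, four between pairs all 60: d = 85 - 60 = 25
        sim = sim_from_dissimilarity(
            list("ABCD"),
            {
                ("A", "B"): 10,
                ("C", "D"): 20,
                ("A", "C"): 40,
                ("A", "D"): 40,
                ("B", "C"): 40,
                ("B", "D"): 40,
            },
        )
        res = dissimilarity_d(sim, ["A", "B"], ["C", "D"])
        assert res.d == pytest.approx(25.0)
        assert res.mean_within == pytest.approx(85.0)
        assert res.mean_between == pytest.approx(60.0)

    def test_sample_order_irrelevant(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(-100, 100, (6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 100.0)
        sim = SimilarityMatrix(list("abcdef"), m)
        r1 = dissimilarity_d(sim, ["a", "b", "c"], ["d", "e", "f"])
        r2 = dissimilarity_d(sim, ["c", "a", "b"], ["f", "d", "e"])
        assert r1.d == pytest.approx(r2.d)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_brute_force_pair_loop(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(7)]
        m = rng.uniform(-100, 100, (7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 100.0)
        sim = SimilarityMatrix(ids, m)
        a, b = ids[:3], ids[3:]
        res = dissimilarity_d(sim, a, b)
        within = [sim.loc(x, y) for g in (a, b) for x, y in itertools.combinations(g, 2)]
        between = [sim.loc(x, y) for x in a for y in b]
        expected = sum(within) / len(within) - sum(between) / len(between)
        assert res.d == pytest.approx(expected, abs=1e-12)


def two_group_profiles(rng, n_a, n_b, separation=1.0, n_feat=30):
    base_a, base_b = rng.random(n_feat), rng.random(n_feat)
    cols = {}
    for i in range(n_a):
        cols[f"a{i}"] = base_a + rng.normal(0, 0.3 / max(separation, 1e-9), n_feat)
    for i in range(n_b):
        cols[f"b{i}"] = base_b + rng.normal(0, 0.3 / max(separation, 1e-9), n_feat)
    return pd.DataFrame(cols)


class TestPermutationTest:
    def test_4v4_exhaustive_count_and_min_p(self):
        # independent enumeration: C(8,4)/2 = 35 unordered partitions
        combos = {
            min(frozenset(c), frozenset(range(8)) - frozenset(c),
                key=lambda s: tuple(sorted(s)))
            for c in itertools.combinations(range(8), 4)
        }
        assert len(combos) == 35
        assert n_distinct_partitions(4, 4) == 35
        rng = np.random.default_rng(8)
        prof = two_group_profiles(rng, 4, 4, separation=50)
        res = permutation_test_d(prof, [f"a{i}" for i in range(4)],
                                 [f"b{i}" for i in range(4)])
        assert res.mode == "exhaustive"
        assert res.n_partitions == 35
        assert len(res.null_d) == 35
        assert res.p_value == pytest.approx(1 / 35)

    def test_2v2_three_partitions_never_significant(self):
        assert n_distinct_partitions(2, 2) == 3
        rng = np.random.default_rng(9)
        prof = two_group_profiles(rng, 2, 2, separation=50)
        res = permutation_test_d(prof, ["a0", "a1"], ["b0", "b1"])
        assert res.n_partitions == 3
        assert res.p_value == pytest.approx(1 / 3)
        assert res.min_attainable_p > 0.05

    def test_unequal_groups_use_all_combinations(self):
        assert n_distinct_partitions(3, 5) == math.comb(8, 3)

    def test_stratified_partition_count(self):
        # 3v3 within each of two strata: (C(6,3))^2 / 2 = 200
        assert n_distinct_partitions(6, 6, strata_sizes=[(3, 3), (3, 3)]) == 200

    def test_null_p_uniform_on_attainable_set(self):
        # with exchangeable samples every rank of the observed d is equally
        # likely, so p <= alpha with probability floor(alpha*K)/K
        rng = np.random.default_rng(10)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            prof = pd.DataFrame(
                rng.random((25, 8)), columns=[f"a{i}" for i in range(4)]
                + [f"b{i}" for i in range(4)]
            )
            res = permutation_test_d(prof, [f"a{i}" for i in range(4)],
                                     [f"b{i}" for i in range(4)])
            rejections += res.p_value <= 0.05
        # expected rate 1/35 = 0.0286; 99% binomial envelope for n=200
        rate = rejections / n_sim
        assert rate <= 0.0286 + 2.58 * math.sqrt(0.0286 * 0.9714 / n_sim)

    def test_monte_carlo_mode_on_large_designs(self):
        rng = np.random.default_rng(11)
        prof = two_group_profiles(rng, 9, 9, separation=50)
        res = permutation_test_d(
            prof,
            [f"a{i}" for i in range(9)],
            [f"b{i}" for i in range(9)],
            n_perm=200,
            seed=3,
        )
        assert res.mode == "monte_carlo"
        assert res.p_value == pytest.approx(1 / 201)
        again = permutation_test_d(
            prof,
            [f"a{i}" for i in range(9)],
            [f"b{i}" for i in range(9)],
            n_perm=200,
            seed=3,
        )
        assert res.p_value == again.p_value

    def test_groups_too_small_rejected(self):
        rng = np.random.default_rng(12)
        prof = two_group_profiles(rng, 1, 3)
        with pytest.raises(ValueError, match="at least two"):
            permutation_test_d(prof, ["a0"], ["b0", "b1", "b2"])
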
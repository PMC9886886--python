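"""Unit tests of the statistical primitives against brute-force oracles and
the reference implementations in scipy/statsmodels."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from immunet.stats import (
    ConstantInputError,
    bh_adjust,
    empirical_cdf,
    fold_change_ddct,
    hypergeom_tail,
    pearson_with_p,
    wilcoxon_rank_sum,
)


class TestPearson:
    def test_perfect_linearity(self):
        r, p = pearson_with_p([1, 2, 3], [2, 4, 6])
        assert r == 1.0 and p == 0.0
        r, p = pearson_with_p([1, 2, 3], [-2, -4, -6])
        assert r == -1.0 and p == 0.0

    def test_hand_computed_example(self):
        # cov-sum 4 over sqrt(5·5); t = 0.8·sqrt(2)/0.6 on 2 df gives p = 0.2
        r, p = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert p == pytest.approx(0.2, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantInputError):
            pearson_with_p([1.0, 1.0, 1.0], [1, 2, 3])

    def test_matches_scipy(self, rng):
        for n in (3, 5, 20, 51):
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, p = pearson_with_p(x, y)
            ref = sps.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestBH:
    def test_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_dominates_p_and_preserves_order(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        # step-up is monotone: sorted p gives sorted q
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=200)
        q_ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), q_ref)


class TestWilcoxon:
    def test_exact_extreme_split(self):
        # rank sum 6 is one of the two extreme outcomes among C(6,3)=20
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.p_value == pytest.approx(0.1)

    def test_exact_median_split(self):
        # rank sum 5 sits at the enumeration median: two-sided p caps at 1
        res = wilcoxon_rank_sum([1, 4], [2, 3], mode="exact")
        assert res.p_value == 1.0

    def test_exact_requires_tie_free(self):
        with pytest.raises(ValueError, match="tie"):
            wilcoxon_rank_sum([1, 1, 2], [3, 4, 5], mode="exact")

    def test_identical_groups_give_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_matches_scipy_enumeration(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(1, 9, size=2)
            vals = rng.permutation(50)[: n1 + n2].astype(float)
            x, y = vals[:n1], vals[n1:]
            mine = wilcoxon_rank_sum(x, y, mode="exact").p_value
            ref = sps.mannwhitneyu(x, y, method="exact", alternative="two-sided").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_approx_matches_scipy_with_ties(self, rng):
        for _ in range(25):
            x = np.round(rng.normal(0, 1, 15), 1)
            y = np.round(rng.normal(0.4, 1, 12), 1)
            mine = wilcoxon_rank_sum(x, y, mode="normal_approx").p_value
            ref = sps.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_auto_switches_on_size(self):
        x, y = np.arange(1.0, 12.0), np.array([20.0, 21.0])
        assert wilcoxon_rank_sum(x, y).method == "wilcoxon-normal"
        assert wilcoxon_rank_sum(x[:5], y).method == "wilcoxon-exact"


class TestHypergeom:
    def test_complete_overlap_example(self):
        # C(3,3)·C(7,0)/C(10,3) = 1/120
        assert hypergeom_tail(3, 3, 3, 10) == pytest.approx(1 / 120)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail(0, 5, 5, 20) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(4, 3, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_tail(1, 11, 5, 10)

    def test_matches_direct_summation_small_universe(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        direct = sum(
                            math.comb(K, i) * math.comb(N - K, n - i)
                            for i in range(k, min(K, n) + 1)
                            if n - i <= N - K
                        ) / math.comb(N, n)
                        assert hypergeom_tail(k, K, n, N) == pytest.approx(
                            min(1.0, direct), abs=1e-12
                        )

    def test_matches_scipy_sf(self):
        for k, K, n, N in [(5, 40, 30, 500), (2, 10, 10, 100), (17, 60, 25, 80)]:
            ref = sps.hypergeom.sf(k - 1, N, K, n)
            assert hypergeom_tail(k, K, n, N) == pytest.approx(ref, rel=1e-10)


class TestECDF:
    def test_single_value(self):
        f = empirical_cdf([5.0])
        assert f(5.0) == 1.0 and f(4.9) == 0.0

    def test_tied_values(self):
        f = empirical_cdf([1, 2, 2, 4])
        assert f(2) == pytest.approx(0.75)
        assert f(4) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            empirical_cdf([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=30))
    def test_equals_max_rank_over_n(self, values):
        f = empirical_cdf(values)
        v = np.asarray(values)
        ranks = sps.rankdata(v, method="max")
        assert np.allclose(f(v), ranks / v.size)


class TestFoldChange:
    def test_control_mean_sample_has_unit_fold(self):
        ct_t = {"c1": 25.0, "c2": 27.0, "s": 26.0}
        ct_r = {"c1": 20.0, "c2": 22.0, "s": 21.0}
        folds = fold_change_ddct(ct_t, ct_r, ["c1", "c2"])
        assert folds["s"] == pytest.approx(1.0)

    def test_two_cycle_advance_quadruples(self):
        ct_t = {"c": 24.0, "s": 22.0}
        ct_r = {"c": 20.0, "s": 20.0}
        assert fold_change_ddct(ct_t, ct_r, ["c"])["s"] == pytest.approx(4.0)

    def test_control_geometric_mean_is_one(self, rng):
        controls = [f"c{i}" for i in range(6)]
        ct_t = {s: float(v) for s, v in zip(controls, rng.normal(25, 1, 6))}
        ct_r = {s: float(v) for s, v in zip(controls, rng.normal(20, 1, 6))}
        folds = fold_change_ddct(ct_t, ct_r, controls)
        log_folds = np.log([folds[s] for s in controls])
        assert np.exp(log_folds.mean()) == pytest.approx(1.0)

    def test_missing_sample_named(self):
        with pytest.raises(KeyError, match="s2"):
            fold_change_ddct({"s1": 20.0, "s2": 21.0}, {"s1": 18.0}, ["s1"])
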
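"""Exact nonparametric tests against independent brute-force enumeration.

The oracles here enumerate labelings/sign-patterns/permutations directly
with itertools and compute the statistics from raw values, sharing no code
with the implementation's dynamic-programming paths.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata, spearmanr

from natsc.stats import (
    cohens_d,
    mann_whitney_u,
    spearman_exact,
    wilcoxon_signed_rank,
)

from oracles import bf_mann_whitney_p, bf_spearman, bf_wilcoxon_p


# --------------------------------------------------------------------------
# fixture case suites
# --------------------------------------------------------------------------

MW_CASES = [
    ([1, 2], [3, 4]),
    ([3, 1, 4], [1, 5, 9]),           # tie across groups
    ([1, 2, 3, 4], [2, 3, 4, 5]),     # several ties
    ([10, 20, 30], [15, 25]),
    ([1, 1, 1], [2, 2]),              # heavy ties
    ([5], [1, 2, 3]),
    ([0.5, 2.5, 2.5, 7.0], [1.0, 2.5, 6.0, 8.0]),
    ([-3, 0, 3, 6], [-1, 1]),
]

WSRT_CASES = [
    [1, 2, 3, 4, 5],
    [1, -2, 3, -4, 5, -6],
    [2, 2, -2, 4],                    # tied magnitudes
    [1],
    [-1, -2, -3],
    [0, 1, -2, 3, 0, 4],              # zeros dropped
    [1.5, -1.5, 2.5, 3.0, -0.5],
]

SPEARMAN_CASES = [
    ([1, 2, 3], [1, 2, 3]),
    ([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]),
    ([1, 2, 3, 4], [2, 1, 4, 3]),
    ([1, 2, 3, 4, 5, 6], [3, 1, 4, 1.5, 5, 2]),
    ([1, 2, 2, 4, 5], [2, 1, 3, 3, 5]),   # ties in both
    ([1, 2, 3, 4, 5, 6, 7], [7, 6, 5, 4, 3, 2, 1]),
]


class TestMannWhitney:
    @pytest.mark.parametrize("x,y", MW_CASES)
    def test_exact_p_matches_brute_force_bitwise(self, x, y):
        res = mann_whitney_u(x, y, exact_with_ties=True)
        assert res.method.startswith("exact")
        assert res.p_value == bf_mann_whitney_p(x, y)

    def test_frozen_small_example(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3], exact_with_ties=True)
        assert res.p_value == 1.0

    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=6),
        st.lists(st.integers(-5, 5), min_size=1, max_size=6),
    )
    def test_statistic_identity(self, x, y):
        u_xy = mann_whitney_u(x, y, exact_with_ties=True).statistic
        u_yx = mann_whitney_u(y, x, exact_with_ties=True).statistic
        assert u_xy + u_yx == pytest.approx(len(x) * len(y))

    def test_large_sample_uses_normal_approximation(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        res = mann_whitney_u(x, y)
        assert res.method == "normal_approx_tie_corrected"
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(x, y, method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])


class TestWilcoxon:
    @pytest.mark.parametrize("diffs", WSRT_CASES)
    def test_exact_p_matches_brute_force_bitwise(self, diffs):
        res = wilcoxon_signed_rank(diffs, exact_with_ties=True)
        assert res.method.startswith("exact")
        assert res.p_value == bf_wilcoxon_p(diffs)

    def test_frozen_all_positive_example(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.statistic == 15.0
        assert res.p_value == pytest.approx(2 / 32)

    def test_single_difference(self):
        assert wilcoxon_signed_rank([1.0]).p_value == 1.0

    @given(st.lists(st.integers(-9, 9).filter(lambda v: v != 0), min_size=1, max_size=8))
    def test_sign_flip_antisymmetry(self, diffs):
        p1 = wilcoxon_signed_rank(diffs, exact_with_ties=True).p_value
        p2 = wilcoxon_signed_rank([-v for v in diffs], exact_with_ties=True).p_value
        assert p1 == p2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no information"):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_large_sample_matches_scipy_approx(self, rng):
        d = rng.normal(0.3, 1, 30)
        res = wilcoxon_signed_rank(d)
        from scipy.stats import wilcoxon

        ref = wilcoxon(d, correction=True, method="approx")
        assert res.method == "normal_approx_tie_corrected"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestSpearman:
    @pytest.mark.parametrize("x,y", SPEARMAN_CASES)
    def test_exact_p_matches_brute_force(self, x, y):
        res = spearman_exact(x, y)
        rho_ref, p_ref = bf_spearman(x, y)
        assert res.method == "exact_permutation"
        assert res.statistic == pytest.approx(rho_ref, abs=1e-12)
        assert res.p_value == p_ref

    def test_frozen_concordant_examples(self):
        r3 = spearman_exact([1, 2, 3], [1, 2, 3])
        assert (r3.statistic, r3.p_value) == (pytest.approx(1.0), pytest.approx(2 / 6))
        r5 = spearman_exact([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert (r5.statistic, r5.p_value) == (pytest.approx(1.0), pytest.approx(2 / 120))

    def test_reversal_flips_rho_keeps_p(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 3, 1, 5, 6, 4]
        a = spearman_exact(x, y)
        c = spearman_exact(x, [-v for v in y])
        assert c.statistic == pytest.approx(-a.statistic)
        assert c.p_value == a.p_value

    def test_monte_carlo_converges_to_exact(self):
        x = [1, 2, 3, 4, 5, 6, 7]
        y = [2, 1, 4, 3, 7, 5, 6]
        exact = spearman_exact(x, y).p_value
        mc = spearman_exact(x, y, n_resamples=10**5, seed=42, force_monte_carlo=True)
        assert mc.method == "monte_carlo_permutation"
        se = math.sqrt(exact * (1 - exact) / 10**5)
        assert abs(mc.p_value - exact) <= 2 * se + 2 / 10**5

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_exact([1, 1, 1], [1, 2, 3])


class TestCohensD:
    def test_identical_means_zero(self):
        assert cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_hand_pooled_example(self):
        assert cohens_d([0, 2], [2, 4]) == pytest.approx(-2 / math.sqrt(2))

    @given(st.floats(0.1, 10))
    def test_scale_invariance(self, a):
        x, y = np.array([1.0, 2, 4, 5]), np.array([2.0, 3, 6, 9])
        assert cohens_d(a * x, a * y) == pytest.approx(cohens_d(x, y), rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1], [1, 2])
        with pytest.raises(ValueError):
            cohens_d([1, 1], [1, 1])
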
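import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import multinomial

from trailmc.stats import (
    PairedSamples, chi_square_gof, exact_multinomial_test, permutation_test,
)


def pairs(a, b):
    return PairedSamples(list(range(len(a))), np.asarray(a, float), np.asarray(b, float))


class TestPermutationTest:
    def test_identical_groups_give_p_one(self):
        res = permutation_test(pairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.p_value == 1.0

    def test_maximal_separation_three_pairs_one_sided(self):
        # all 2^3 sign patterns enumerated; only the identity is as extreme
        res = permutation_test(pairs([0, 0, 0], [1, 1, 1]), alternative="less")
        assert res.scheme == "exhaustive"
        assert res.p_value == pytest.approx(1 / 8)

    def test_two_sided_maximal_separation(self):
        # identity and full flip both reach |T|, so p = 2/8
        res = permutation_test(pairs([0, 0, 0], [1, 1, 1]))
        assert res.p_value == pytest.approx(2 / 8)

    def test_exhaustive_matches_hand_enumeration(self):
        d = np.array([0.3, -0.1, 0.4])
        res = permutation_test(pairs(d, np.zeros(3)))
        t_obs = d.mean()
        count = sum(
            abs(np.mean(s * d)) >= abs(t_obs) - 1e-12
            for s in itertools.product([-1.0, 1.0], repeat=3)
        )
        assert res.p_value == pytest.approx(count / 8)

    def test_monte_carlo_agrees_with_exhaustive(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.5, 1.0, 10)
        s = pairs(a, b)
        pe = permutation_test(s).p_value
        n_mc = 20_000
        pm = permutation_test(s, n_perm=n_mc, seed=1)
        assert pm.scheme == "monte-carlo"
        se = math.sqrt(pe * (1 - pe) / n_mc)
        assert abs(pm.p_value - pe) < 2 * se + 2 / n_mc

    def test_monte_carlo_p_never_below_add_one_bound(self):
        rng = np.random.default_rng(2)
        s = pairs(rng.normal(5, 0.1, 30), rng.normal(0, 0.1, 30))
        res = permutation_test(s, n_perm=999, seed=0)
        assert res.p_value >= 1 / 1000

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            PairedSamples([1, 2], np.array([1.0]), np.array([1.0, 2.0]))

    def test_type_i_error_calibrated_under_exchangeable_null(self):
        # 1,000 exchangeable paired datasets: rejection rate at alpha=.05
        # must be 0.05 +/- 0.02
        rng = np.random.default_rng(42)
        n_pairs, n_data = 15, 1000
        rejections = 0
        for _ in range(n_data):
            base = rng.normal(10.0, 1.0, n_pairs)
            a = base + rng.normal(0.0, 0.5, n_pairs)
            b = base + rng.normal(0.0, 0.5, n_pairs)
            p = permutation_test(pairs(a, b)).p_value
            rejections += p < 0.05
        assert abs(rejections / n_data - 0.05) <= 0.02

    @given(st.integers(0, 2 ** 32 - 1))
    def test_p_value_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        s = pairs(rng.normal(0, 1, 6), rng.normal(0, 1, 6))
        res = permutation_test(s)
        assert 0 < res.p_value <= 1
        flipped = permutation_test(pairs(s.values_b, s.values_a))
        assert res.p_value == pytest.approx(flipped.p_value, abs=1e-12)


class TestChiSquareGof:
    def test_uniform_counts_statistic_zero(self):
        res = chi_square_gof([10, 10, 10, 10])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_hand_computed_statistic(self):
        # (100 + 0 + 25 + 25) / 10 = 15 on 3 df
        res = chi_square_gof([20, 10, 5, 5])
        assert res.statistic == pytest.approx(15.0)
        assert res.df == 3

    def test_doubling_counts_doubles_statistic(self):
        a = chi_square_gof([20, 10, 5, 5]).statistic
        b = chi_square_gof([40, 20, 10, 10]).statistic
        assert b == pytest.approx(2 * a)

    def test_matches_scipy_reference(self):
        from scipy.stats import chisquare
        res = chi_square_gof([25, 5, 10, 20], [0.4, 0.1, 0.2, 0.3])
        ref = chisquare([25, 5, 10, 20], f_exp=[24, 6, 12, 18])
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_expected_proportion_rejected(self):
        with pytest.raises(ValueError):
            chi_square_gof([1, 2, 3], [0.5, 0.5, 0.0])


class TestExactMultinomial:
    def test_single_observation_uniform_is_one(self):
        assert exact_multinomial_test([1, 0, 0, 0]) == pytest.approx(1.0)

    def test_two_and_three_coin_flips(self):
        # (2,0): outcomes have probs 1/4, 1/2, 1/4 -> p = 1/2
        assert exact_multinomial_test([2, 0]) == pytest.approx(0.5)
        # (3,0): probs 1/8, 3/8, 3/8, 1/8 -> p = 1/4
        assert exact_multinomial_test([3, 0]) == pytest.approx(0.25)

    @pytest.mark.parametrize("n", range(1, 7))
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_equals_brute_force_enumeration(self, n, k):
        rng = np.random.default_rng(n * 17 + k)
        probs = rng.dirichlet(np.ones(k))
        counts = rng.multinomial(n, probs)
        p_obs = multinomial.pmf(counts, n, probs)
        brute = sum(
            multinomial.pmf(v, n, probs)
            for v in itertools.product(range(n + 1), repeat=k) if sum(v) == n
            and multinomial.pmf(v, n, probs) <= p_obs * (1 + 1e-10)
        )
        assert exact_multinomial_test(counts, probs) == pytest.approx(brute, abs=1e-10)

    def test_approaches_chi_square_for_large_samples(self):
        counts = [60, 45, 50, 45]
        p_exact = exact_multinomial_test(counts, budget=10 ** 7)
        p_chi = chi_square_gof(counts).p_value
        assert abs(p_exact - p_chi) < 0.02

    def test_enumeration_budget_guard(self):
        with pytest.raises(ValueError, match="chi_square"):
            exact_multinomial_test([500, 500, 500, 500], budget=1000)
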
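import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from patchlink.stats import (
    bootstrap_pearson,
    chisq_2x2,
    chisq_gof,
    compare_correlations,
    fisher_z_difference,
    poisson_rate_comparison,
    wilcoxon_signed_rank,
)


class TestChisqGof:
    def test_proportional_counts(self):
        stat, df, p = chisq_gof([50, 30, 20], [0.5, 0.3, 0.2])
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_road_example_hand_computed(self):
        stat, df, p = chisq_gof([31, 69], [0.01, 0.99])
        assert stat == pytest.approx(909.0909, abs=0.01)
        assert df == 1
        assert p < 1e-10

    def test_matches_monte_carlo_multinomial(self):
        # analytic chi-square p vs multinomial simulation, n = 30, k = 3
        frac = np.array([0.25, 0.35, 0.40])
        obs = np.array([13, 10, 7])
        stat, _, p = chisq_gof(obs, frac)
        rng = np.random.default_rng(8)
        draws = rng.multinomial(30, frac, size=200000)
        exp = 30 * frac
        sim = (((draws - exp) ** 2) / exp).sum(axis=1)
        assert abs((sim >= stat - 1e-12).mean() - p) < 0.01

    def test_zero_expected_with_observation(self):
        with pytest.raises(ValueError, match="zero expectation"):
            chisq_gof([5, 5], [0.0, 1.0])


class TestChisq2x2:
    def test_identical_rows(self):
        stat, df, p = chisq_2x2([[10, 20], [10, 20]])
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_textbook_formula_oracle(self):
        t = np.array([[10, 20], [20, 10]], float)
        stat, _, _ = chisq_2x2(t)
        n = t.sum()
        oracle = (
            n
            * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2
            / (t.sum(1)[0] * t.sum(1)[1] * t.sum(0)[0] * t.sum(0)[1])
        )
        assert stat == pytest.approx(oracle, abs=1e-12)
        # and against scipy without continuity correction
        sp = sps.chi2_contingency(t, correction=False)
        assert stat == pytest.approx(sp.statistic, abs=1e-10)

    def test_row_swap_invariance(self):
        a, *_ = chisq_2x2([[3, 11], [9, 2]])
        b, *_ = chisq_2x2([[9, 2], [3, 11]])
        assert a == pytest.approx(b, abs=1e-12)

    def test_yates_matches_scipy(self):
        t = [[8, 14], [11, 5]]
        stat, _, p = chisq_2x2(t, yates=True)
        sp = sps.chi2_contingency(np.array(t), correction=True)
        assert stat == pytest.approx(sp.statistic, abs=1e-10)
        assert p == pytest.approx(sp.pvalue, abs=1e-10)

    def test_zero_margin(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_2x2([[0, 0], [5, 5]])


class TestPoissonRateComparison:
    def test_identical_groups(self):
        res = poisson_rate_comparison([4, 5, 6], [4, 5, 6])
        assert res.log_rate_ratio == 0.0
        assert res.p_value == 1.0

    def test_mean_distance_contrast_closed_form(self):
        # groups mirroring summed distances 439 m vs 1356 m, n = 60 each
        a = np.full(60, 439.0)
        b = np.full(60, 1356.0)
        res = poisson_rate_comparison(a, b)
        assert res.mean_b / res.mean_a == pytest.approx(3.0888, abs=1e-3)
        assert res.log_rate_ratio == pytest.approx(1.1277, abs=1e-3)
        assert res.se_log_rr == pytest.approx(
            np.sqrt(1 / 26340 + 1 / 81360), rel=1e-12
        )
        assert res.se_log_rr == pytest.approx(0.00709, abs=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_glm_oracle(self, seed):
        # independent IRLS fit (statsmodels GLM, Poisson family, log link)
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        a = rng.gamma(4.0, 100.0, size=rng.integers(20, 60))
        b = rng.gamma(5.0, 120.0, size=rng.integers(20, 60))
        res = poisson_rate_comparison(a, b)
        y = np.concatenate([a, b])
        X = sm.add_constant(np.r_[np.zeros(len(a)), np.ones(len(b))])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert res.log_rate_ratio == pytest.approx(fit.params[1], abs=1e-6)
        assert res.se_log_rr == pytest.approx(fit.bse[1], abs=1e-6)

    def test_zero_group_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            poisson_rate_comparison([0.0, 0.0], [1.0, 2.0])


class TestBootstrapPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = bootstrap_pearson(x, 2 * x + 1, n_boot=500, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(30), rng.random(30)
        a = bootstrap_pearson(x, y, n_boot=2000, seed=7)
        b = bootstrap_pearson(x, y, n_boot=2000, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bootstrap_pearson(np.ones(10), np.arange(10.0))

    def test_coverage_at_moderate_correlation(self):
        # percentile CI covers rho = 0.4 in 93-97 % of n = 60 samples
        rng = np.random.default_rng(77)
        cov = [[1.0, 0.4], [0.4, 1.0]]
        hits = 0
        for k in range(200):
            xy = rng.multivariate_normal([0, 0], cov, size=60)
            b = bootstrap_pearson(xy[:, 0], xy[:, 1], n_boot=2000, seed=1000 + k)
            hits += b.ci_low <= 0.4 <= b.ci_high
        assert 0.93 * 200 <= hits <= 0.97 * 200


class TestFisherZ:
    def test_equal_correlations(self):
        z, p = fisher_z_difference(0.3, 40, 0.3, 50)
        assert z == 0.0 and p == 1.0

    def test_study_like_values(self):
        z, _ = fisher_z_difference(0.38, 60, 0.06, 60)
        assert z == pytest.approx(1.815, abs=0.005)

    def test_direct_formula_example(self):
        z, _ = fisher_z_difference(0.5, 30, 0.0, 30)
        assert z == pytest.approx(0.5493 / np.sqrt(2 / 27), abs=1e-3)
        assert z == pytest.approx(2.018, abs=0.005)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fisher_z_difference(1.0, 30, 0.0, 30)
        with pytest.raises(ValueError):
            fisher_z_difference(0.5, 3, 0.0, 30)

    def test_compare_correlations_wraps_both(self):
        rng = np.random.default_rng(2)
        x1 = rng.random(40)
        y1 = x1 + rng.normal(0, 0.5, 40)
        x2, y2 = rng.random(40), rng.random(40)
        res = compare_correlations(x1, y1, x2, y2, n_boot=1000, seed=3)
        assert res.boot_ci1[0] < res.r1 < res.boot_ci1[1]
        assert res.fisher_z == pytest.approx(
            fisher_z_difference(res.r1, 40, res.r2, 40)[0]
        )


class TestWilcoxonSignedRank:
    def test_all_positive_small_sample(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 7.0))
        assert res.T_statistic == 0.0
        assert res.exact
        assert res.p_value == pytest.approx(2 / 64)  # one tail 1/64

    @given(st.lists(st.integers(-50, 50), min_size=6, max_size=25).filter(
        lambda d: any(v != 0 for v in d)))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_sign_flip_symmetry(self, diffs):
        d = np.array(diffs, float)
        a = wilcoxon_signed_rank(d)
        b = wilcoxon_signed_rank(-d)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.T_statistic == b.T_statistic

    def test_double_zero_pairs_dropped(self):
        a = np.array([0.0, 0.0, 3.0, 1.0, 4.0, 2.0, 5.0, 1.0])
        b = np.array([0.0, 0.0, 1.0, 2.0, 1.0, 1.0, 2.0, 3.0])
        res = wilcoxon_signed_rank(a, b)
        assert res.n_effective == 6

    def test_t_bounded_by_mean_rank_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.normal(size=15)
            res = wilcoxon_signed_rank(d)
            n = res.n_effective
            assert res.T_statistic <= n * (n + 1) / 4

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_close_to_normal_at_boundary(self, seed):
        # n = 12: worst-case gap between enumeration and the continuity-
        # corrected normal over all T is 0.0137 (found by enumeration)
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=12)
        exact = wilcoxon_signed_rank(d, exact_max_n=12)
        approx = wilcoxon_signed_rank(d, exact_max_n=0)
        assert exact.exact and not approx.exact
        assert abs(exact.p_value - approx.p_value) < 0.014

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.normal(0.4, 1.0, size=40)
        d = d[d != 0]
        res = wilcoxon_signed_rank(d)
        sp = sps.wilcoxon(d, correction=True, mode="approx")
        assert res.T_statistic == sp.statistic
        assert res.p_value == pytest.approx(sp.pvalue, abs=1e-8)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.zeros(5))
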
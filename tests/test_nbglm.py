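"""Dispersion estimation, GLM fitting, Wald/LRT tests and BH adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gc2mat import nbglm

from conftest import make_counts

UNIT_NORM = nbglm.NormalizationFactors(
    np.ones(8), "median_ratios", "geometric_mean"
)
TWO_GROUP = nbglm.one_hot_design(["a"] * 4 + ["b"] * 4)


class TestDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self, rng):
        mu = np.exp(rng.normal(np.log(200), 1, 2000))
        y = rng.poisson(mu[:, None], (2000, 8))
        cm = make_counts(y)
        d = nbglm.estimate_dispersions(cm, TWO_GROUP, nbglm.estimate_size_factors(cm))
        assert np.median(d.shrunk) < 0.01

    def test_recovers_true_dispersion(self, rng):
        alpha = 0.2
        mu = np.exp(rng.normal(np.log(200), 1, 2000))
        lam = rng.gamma(1 / alpha, alpha * mu[:, None], (2000, 8))
        y = rng.poisson(lam)
        cm = make_counts(y)
        d = nbglm.estimate_dispersions(cm, TWO_GROUP, nbglm.estimate_size_factors(cm))
        assert 0.1 <= np.median(d.shrunk) <= 0.4

    def test_shrunk_lies_between_genewise_and_common(self, two_group_counts):
        d = nbglm.estimate_dispersions(
            two_group_counts, TWO_GROUP,
            nbglm.estimate_size_factors(two_group_counts),
        )
        lo = np.minimum(d.genewise, d.common) - 1e-12
        hi = np.maximum(d.genewise, d.common) + 1e-12
        assert np.all((d.shrunk >= lo) & (d.shrunk <= hi))

    def test_full_shrinkage_returns_common(self, two_group_counts):
        # prior_df >> residual_df pins every gene at the common value
        d = nbglm.estimate_dispersions(
            two_group_counts, TWO_GROUP,
            nbglm.estimate_size_factors(two_group_counts), prior_df=1e12,
        )
        np.testing.assert_allclose(d.shrunk, d.common, rtol=1e-4)

    def test_rank_deficient_design_is_an_error(self, two_group_counts):
        with pytest.raises(ValueError, match="full rank"):
            bad = nbglm.Design(
                matrix=np.ones((8, 2)), coef_names=["a", "b"]
            )


class TestGlmFit:
    def test_one_factor_fitted_means_are_group_means(self):
        y = np.array([[10, 10, 20, 20]])
        cm = make_counts(y)
        design = nbglm.one_hot_design(["a", "a", "b", "b"])
        norm = nbglm.NormalizationFactors(
            np.ones(4), "median_ratios", "geometric_mean"
        )
        fit = nbglm.fit_nb_glm(cm, design, norm, 0.1)
        np.testing.assert_allclose(fit.mu[0], [10, 10, 20, 20], rtol=1e-6)

    def test_all_zero_gene_is_degenerate(self):
        y = np.array([[0] * 8, [5] * 8])
        cm = make_counts(y)
        fit = nbglm.fit_nb_glm(cm, TWO_GROUP, UNIT_NORM, 0.1)
        assert fit.degenerate[0] and not fit.degenerate[1]
        assert np.all(fit.mu[0] < 1e-8)  # coefficients pinned at the lower bound

    def test_optimum_beats_grid_search_oracle(self, rng):
        # 2-coefficient toys: the IRLS optimum must dominate a 101x101 grid
        alpha = 0.1
        for _ in range(5):
            mu = np.array([rng.uniform(20, 200), rng.uniform(20, 200)])
            lam = rng.gamma(
                1 / alpha, alpha * np.repeat(mu, 4)[None, :], (1, 8)
            )
            y = rng.poisson(lam)
            cm = make_counts(y)
            fit = nbglm.fit_nb_glm(cm, TWO_GROUP, UNIT_NORM, alpha)
            b = fit.coefficients[0]
            grid = np.linspace(-1.0, 1.0, 101)
            best = -np.inf
            for d0 in grid:
                mus = np.exp(
                    TWO_GROUP.matrix @ (b + np.array([d0, 0]))[:, None]
                ).T
                ll = nbglm.nb_loglik(np.tile(y, (1, 1)), mus, alpha)[0]
                best = max(best, ll)
            for d1 in grid:
                mus = np.exp(
                    TWO_GROUP.matrix @ (b + np.array([0, d1]))[:, None]
                ).T
                best = max(best, nbglm.nb_loglik(y.astype(float), mus, alpha)[0])
            assert fit.loglik[0] >= best - 1e-9


class TestWald:
    def test_null_contrast_gives_p_one(self, two_group_counts):
        fit = nbglm.fit_nb_glm(two_group_counts, TWO_GROUP, UNIT_NORM, 0.1)
        t = nbglm.wald_test(fit, np.zeros(2))
        assert np.all(t["pvalue"] == 1.0)
        assert np.all(t["log2fc"] == 0.0)

    def test_consistency_at_high_depth(self):
        # deterministic counts at means 10000 vs 20000: log2fc is exactly 1
        y = np.array([[10000] * 4 + [20000] * 4])
        cm = make_counts(y)
        fit = nbglm.fit_nb_glm(cm, TWO_GROUP, UNIT_NORM, 0.01)
        t = nbglm.wald_test(fit, np.array([-1.0, 1.0]))
        assert abs(t["log2fc"].iloc[0] - 1.0) < 1e-4

    def test_type_one_error_is_calibrated(self, rng):
        alpha = 0.05
        mu = np.exp(rng.normal(np.log(300), 1, 2000))
        lam = rng.gamma(1 / alpha, alpha * mu[:, None], (2000, 8))
        y = rng.poisson(lam)
        cm = make_counts(y)
        norm = nbglm.estimate_size_factors(cm)
        disp = nbglm.estimate_dispersions(cm, TWO_GROUP, norm)
        fit = nbglm.fit_nb_glm(cm, TWO_GROUP, norm, disp)
        t = nbglm.wald_test(fit, np.array([-1.0, 1.0]))
        assert 0.03 <= (t["pvalue"] < 0.05).mean() <= 0.08


class TestLrt:
    def test_null_statistics_follow_chisquare(self, rng):
        alpha = 0.1
        lam = rng.gamma(1 / alpha, alpha * 1000, (2000, 8))
        y = rng.poisson(lam)
        cm = make_counts(y)
        t = nbglm.lrt_contrast_test(
            cm, TWO_GROUP, UNIT_NORM, alpha, np.array([1.0, -1.0])
        )
        ks = stats.kstest(t["stat"], stats.chi2(1).cdf)
        assert ks.statistic < 0.05

    def test_identical_groups_give_zero_statistic(self):
        a = np.array([[30, 17, 45, 8]])
        y = np.hstack([a, a])  # group b duplicates group a
        cm = make_counts(y)
        t = nbglm.lrt_contrast_test(
            cm, TWO_GROUP, UNIT_NORM, 0.1, np.array([1.0, -1.0])
        )
        assert t["stat"].iloc[0] < 1e-6
        assert t["pvalue"].iloc[0] > 0.999

    def test_matches_poisson_deviance_difference(self, rng):
        y = rng.poisson(50, (50, 8))
        cm = make_counts(y)
        t = nbglm.lrt_contrast_test(
            cm, TWO_GROUP, UNIT_NORM, 0.0, np.array([1.0, -1.0])
        )
        m1, m2, m0 = y[:, :4].mean(1), y[:, 4:].mean(1), y.mean(1)
        with np.errstate(divide="ignore", invalid="ignore"):
            full = (
                np.sum(y[:, :4] * np.log(m1)[:, None], axis=1)
                + np.sum(y[:, 4:] * np.log(m2)[:, None], axis=1)
                - 4 * m1 - 4 * m2
            )
            reduced = np.sum(y * np.log(m0)[:, None], axis=1) - 8 * m0
        np.testing.assert_allclose(t["stat"], 2 * (full - reduced), atol=1e-6)

    def test_statistic_is_nonnegative(self, two_group_counts):
        t = nbglm.lrt_contrast_test(
            two_group_counts, TWO_GROUP, UNIT_NORM, 0.1, np.array([1.0, -1.0])
        )
        assert np.all(t["stat"] >= 0)

    def test_zero_contrast_is_an_error(self, two_group_counts):
        with pytest.raises(ValueError, match="nonzero"):
            nbglm.lrt_contrast_test(
                two_group_counts, TWO_GROUP, UNIT_NORM, 0.1, np.zeros(2)
            )


class TestBH:
    def test_single_p_is_unchanged(self):
        np.testing.assert_allclose(nbglm.bh_adjust([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            nbglm.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            mine = nbglm.bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_nan_entries_are_excluded_from_m(self):
        p = np.array([0.01, np.nan, 0.02])
        out = nbglm.bh_adjust(p)
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.02])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_invariant_under_permutation(self, p, pyrand):
        p = np.array(p)
        perm = np.arange(len(p))
        pyrand.shuffle(perm)
        out = nbglm.bh_adjust(p)
        out_perm = nbglm.bh_adjust(p[perm])
        np.testing.assert_allclose(out[perm], out_perm, atol=1e-12)

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            nbglm.bh_adjust([0.5, 1.5])

    def test_sorted_p_gives_monotone_fdr(self, rng):
        p = np.sort(rng.uniform(0, 1, 100))
        out = nbglm.bh_adjust(p)
        assert np.all(np.diff(out) >= -1e-15)
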
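"""Unit and property tests for the linear-model / moderated-statistics core."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tissueqtl import statcore
from tissueqtl.statcore import (
    AliasedDesignError,
    VariancePrior,
    bh_adjust,
    estimate_variance_prior,
    moderated_f,
    moderated_t,
    ols_fit,
    spearman_corr,
)


def _frame(y_rows, columns):
    return pd.DataFrame(y_rows, index=[f"g{i}" for i in range(len(y_rows))], columns=columns)


class TestOlsFit:
    def test_perfect_linear_fit_has_zero_residual_variance(self):
        y = _frame([[1.0, 2.0, 3.0]], list("abc"))
        X = pd.DataFrame({"intercept": 1.0, "x": [0.0, 1.0, 2.0]}, index=list("abc"))
        fit = ols_fit(y, X)
        np.testing.assert_allclose(fit.coef.loc["g0"], [1.0, 1.0], atol=1e-12)
        assert fit.sigma2.loc["g0"] == pytest.approx(0.0, abs=1e-24)
        assert fit.df_resid.loc["g0"] == 1

    def test_matches_normal_equations_oracle(self):
        # brute-force (X'X)^-1 X'y on the spec's 4-point instance
        y = np.array([1.0, 2.0, 2.0, 5.0])
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        fit = ols_fit(
            _frame([y], list("abcd")),
            pd.DataFrame({"intercept": 1.0, "x": np.arange(4.0)}, index=list("abcd")),
        )
        np.testing.assert_allclose(fit.coef.loc["g0"].to_numpy(), beta_oracle, rtol=1e-12)
        resid = y - X @ beta_oracle
        assert fit.sigma2.loc["g0"] == pytest.approx(resid @ resid / 2, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p, g = rng.integers(8, 30), rng.integers(2, 6), 7
        X = rng.normal(size=(n, p))
        X[:, 0] = 1.0
        Y = rng.normal(size=(g, n))
        design = pd.DataFrame(X, index=[f"s{i}" for i in range(n)], columns=[f"c{j}" for j in range(p)])
        fit = ols_fit(_frame(Y, design.index), design)
        expected = np.linalg.solve(X.T @ X, X.T @ Y.T).T
        np.testing.assert_allclose(fit.coef.to_numpy(), expected, rtol=1e-10, atol=1e-10)

    def test_duplicated_column_raises_naming_it(self, tiny_design):
        design = tiny_design.copy()
        design["x1_copy"] = design["x1"]
        y = _frame([np.arange(8.0)], tiny_design.index)
        with pytest.raises(AliasedDesignError, match="x1_copy"):
            ols_fit(y, design)

    def test_missing_values_use_per_gene_complete_case(self, tiny_design):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(2, 8))
        y[1, 3] = np.nan
        fit = ols_fit(_frame(y, tiny_design.index), tiny_design)
        assert fit.n_used.loc["g0"] == 8
        assert fit.n_used.loc["g1"] == 7
        # the complete-case gene matches a direct fit on its complete rows
        mask = ~np.isnan(y[1])
        X = tiny_design.to_numpy()[mask]
        expected = np.linalg.solve(X.T @ X, X.T @ y[1, mask])
        np.testing.assert_allclose(fit.coef.loc["g1"].to_numpy(), expected, rtol=1e-10)


class TestVariancePrior:
    def test_constant_variances_give_infinite_prior_df(self):
        prior = estimate_variance_prior(np.full(50, 2.5), 10)
        assert np.isinf(prior.d0)
        assert prior.s02 == pytest.approx(2.5, rel=1e-6)

    def test_recovers_generating_hyperparameters(self):
        # s^2 ~ s0^2 * F(d, d0): draw from the scaled-F marginal and re-estimate
        rng = np.random.default_rng(42)
        d0, s02, d = 4.0, 2.0, 10
        s2 = s02 * (rng.chisquare(d, 5000) / d) / (rng.chisquare(d0, 5000) / d0)
        prior = estimate_variance_prior(s2, d)
        assert prior.d0 == pytest.approx(d0, rel=0.15)
        assert prior.s02 == pytest.approx(s02, rel=0.05)

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_variance_prior(np.zeros(20), 5)

    def test_two_genes_warn_wide_tolerance(self):
        with pytest.warns(UserWarning, match="wide-tolerance"):
            estimate_variance_prior(np.array([1.0, 2.0]), 5)

    def test_posterior_variance_between_extremes(self):
        prior = VariancePrior(d0=4.0, s02=4.0)
        s2post = prior.posterior_variance(1.0, 4)
        assert s2post == pytest.approx(2.5)  # (4*4 + 4*1)/8
        assert min(1.0, 4.0) <= s2post <= max(1.0, 4.0)


class TestModeratedT:
    @pytest.fixture
    def fitset(self, tiny_design):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(40, 8))
        return ols_fit(_frame(Y, tiny_design.index), tiny_design)

    def test_d0_zero_reproduces_classical_t(self, fitset):
        prior = VariancePrior(d0=0.0, s02=1.0)
        out = moderated_t(fitset, prior, "x1")
        beta = fitset.coef["x1"]
        se = fitset.stdev_unscaled["x1"] * np.sqrt(fitset.sigma2)
        np.testing.assert_allclose(out["t"], beta / se, rtol=1e-12)
        np.testing.assert_allclose(out["df_total"], fitset.df_resid)

    def test_shrunken_df_and_denominator(self, fitset):
        prior = VariancePrior(d0=4.0, s02=4.0)
        out = moderated_t(fitset, prior, "x1")
        d = fitset.df_resid.iloc[0]
        np.testing.assert_allclose(out["df_total"], 4.0 + d)
        s2post = (4 * 4.0 + d * fitset.sigma2) / (4.0 + d)
        expected = fitset.coef["x1"] / (fitset.stdev_unscaled["x1"] * np.sqrt(s2post))
        np.testing.assert_allclose(out["t"], expected, rtol=1e-12)

    def test_infinite_prior_uses_s0_and_normal_tails(self, fitset):
        prior = VariancePrior(d0=np.inf, s02=2.0)
        out = moderated_t(fitset, prior, "x1")
        expected_t = fitset.coef["x1"] / (fitset.stdev_unscaled["x1"] * np.sqrt(2.0))
        np.testing.assert_allclose(out["t"], expected_t, rtol=1e-12)
        np.testing.assert_allclose(out["p"], 2 * stats.norm.sf(np.abs(out["t"])), rtol=1e-12)

    def test_unknown_coefficient_raises(self, fitset):
        with pytest.raises(KeyError):
            moderated_t(fitset, VariancePrior(1.0, 1.0), "nope")

    def test_null_pvalues_uniform(self):
        # global null: moderated p-values should pass a KS uniformity test
        rng = np.random.default_rng(123)
        n, g = 50, 2000
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n)},
                         index=[f"s{i}" for i in range(n)])
        Y = rng.normal(size=(g, n))
        fit = ols_fit(_frame(Y, X.index), X)
        prior = estimate_variance_prior(fit.sigma2, fit.df_resid)
        out = moderated_t(fit, prior, "x")
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01


class TestModeratedF:
    def test_single_coefficient_equals_t_squared(self, tiny_design):
        rng = np.random.default_rng(5)
        fit = ols_fit(_frame(rng.normal(size=(10, 8)), tiny_design.index), tiny_design)
        prior = VariancePrior(d0=3.0, s02=1.5)
        f = moderated_f(fit, prior, ["x1"])
        t = moderated_t(fit, prior, "x1")
        np.testing.assert_allclose(f["F"], t["t"] ** 2, rtol=1e-10)
        np.testing.assert_allclose(f["p"], t["p"], rtol=1e-10)

    def test_d0_zero_matches_nested_rss_oracle(self):
        # classical F from full-vs-reduced residual sums of squares
        rng = np.random.default_rng(17)
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = rng.normal(size=n)
        design = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                              columns=["intercept", "a", "b", "c"])
        fit = ols_fit(_frame([y], design.index), design)
        out = moderated_f(fit, VariancePrior(d0=0.0, s02=1.0), ["a", "b", "c"])

        def rss(Xm):
            beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
            r = y - Xm @ beta
            return r @ r

        rss_full, rss_red = rss(X), rss(X[:, :1])
        f_oracle = ((rss_red - rss_full) / 3) / (rss_full / (n - 4))
        assert out["F"].iloc[0] == pytest.approx(f_oracle, rel=1e-10)

    def test_zero_under_exact_null(self):
        # identical group means, no within-group noise on the tested contrast
        y = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 0.0])
        design = pd.DataFrame(
            {"intercept": 1.0, "grp": [0.0, 0, 1, 1, 0, 0]},
            index=[f"s{i}" for i in range(6)],
        )
        fit = ols_fit(_frame([y], design.index), design)
        out = moderated_f(fit, VariancePrior(d0=0.0, s02=1.0), ["grp"])
        assert out["F"].iloc[0] == pytest.approx(0.0, abs=1e-20)


class TestBhAdjust:
    def test_spec_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_tied_inputs(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_empty_vector(self):
        assert bh_adjust([]).size == 0

    @staticmethod
    def _brute_force(p):
        p = np.asarray(p)
        m = len(p)
        q = np.empty(m)
        for i, pi in enumerate(p):
            # min over thresholds at or beyond pi of p_(j) * m / j
            candidates = [
                pj * m / (np.sum(p <= pj)) for pj in p if pj >= pi
            ]
            q[i] = min(1.0, min(candidates))
        return q

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_adjust(p), self._brute_force(p), rtol=1e-12, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.randoms(use_true_random=False))
    def test_order_invariance_and_dominance(self, p, rnd):
        q = bh_adjust(p)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q_perm = bh_adjust([p[i] for i in perm])
        np.testing.assert_allclose(q_perm, [q[i] for i in perm], rtol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.uniform(size=500)
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12)


class TestSpearman:
    def test_monotone_and_reversed(self):
        assert spearman_corr([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_corr([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_manual_average_ranks(self):
        # x=(1,1,2) -> ranks (1.5, 1.5, 3); y=(1,2,3) -> ranks (1,2,3)
        rx, ry = np.array([1.5, 1.5, 3.0]), np.array([1.0, 2.0, 3.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr([1, 1, 2], [1, 2, 3]) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=100), rng.integers(0, 5, 100).astype(float)
        assert spearman_corr(x, y) == pytest.approx(stats.spearmanr(x, y).statistic, rel=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            spearman_corr([1, 1, 1], [1, 2, 3])
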
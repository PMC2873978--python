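"""Survey-weighted logistic regression: point estimates, Taylor variance,
Wald inference."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from ewascan.survey import (LonelyPsuError, RankDeficiencyError,
                            SeparationError, SurveyDesign,
                            fit_weighted_logistic, wald_test)


def _two_by_two(n11=10, n10=20, n01=30, n00=40, weights=None):
    """(exposed case, exposed control, unexposed case, unexposed control)."""
    y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    x = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    X = np.c_[np.ones(y.size), x]
    w = np.ones(y.size) if weights is None else weights
    design = SurveyDesign(np.zeros(y.size), np.arange(y.size), w)
    return y, X, design


def _random_logit_data(n=400, seed=0, p=3):
    rng = np.random.default_rng(seed)
    X = np.c_[np.ones(n), rng.normal(size=(n, p))]
    beta = rng.normal(scale=0.5, size=p + 1)
    beta[0] = -1.5
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
    return y, X


class TestPointEstimates:
    def test_two_by_two_matches_closed_form(self):
        y, X, design = _two_by_two()
        fit = fit_weighted_logistic(y, X, design,
                                    term_names=["intercept", "exposed"])
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(30 / 40),
                                                    abs=1e-10)
        assert fit.coefficients[1] == pytest.approx(
            np.log((10 * 40) / (20 * 30)), abs=1e-10)

    def test_constant_weight_rescaling_leaves_beta_unchanged(self):
        y, X, d1 = _two_by_two()
        _, _, d7 = _two_by_two(weights=np.full(100, 7.0))
        b1 = fit_weighted_logistic(y, X, d1).coefficients
        b7 = fit_weighted_logistic(y, X, d7).coefficients
        np.testing.assert_allclose(b1, b7, atol=1e-12)

    def test_weighted_counts_closed_form(self):
        # weight 2 on exposed cases makes the table effectively (20,20,30,40)
        w = np.ones(100)
        w[:10] = 2.0
        y, X, design = _two_by_two(weights=w)
        fit = fit_weighted_logistic(y, X, design)
        assert fit.coefficients[1] == pytest.approx(
            np.log((20 * 40) / (20 * 30)), abs=1e-10)

    def test_matches_unweighted_mle_oracle(self):
        y, X = _random_logit_data(seed=1)
        oracle = sm.Logit(y, X).fit(disp=0)
        design = SurveyDesign(np.zeros(len(y)), np.arange(len(y)),
                              np.ones(len(y)))
        fit = fit_weighted_logistic(y, X, design)
        np.testing.assert_allclose(fit.coefficients, oracle.params,
                                   atol=1e-8)

    def test_duplicating_rows_while_halving_weights_preserves_beta(self):
        y, X = _random_logit_data(seed=2)
        n = len(y)
        d = SurveyDesign(np.zeros(n), np.arange(n), np.ones(n))
        fit = fit_weighted_logistic(y, X, d)
        y2, X2 = np.r_[y, y], np.r_[X, X]
        d2 = SurveyDesign(np.zeros(2 * n), np.arange(2 * n),
                          np.full(2 * n, 0.5))
        fit2 = fit_weighted_logistic(y2, X2, d2)
        np.testing.assert_allclose(fit.coefficients, fit2.coefficients,
                                   atol=1e-8)


class TestTaylorVariance:
    def test_degenerate_design_equals_hand_sandwich(self):
        """One stratum, per-row PSUs, unit weights: the design covariance is
        the independence sandwich A^{-1} (sum u u') A^{-1} scaled n/(n-1)
        (the score sums to zero at the MLE, so centering is immaterial).
        The oracle path uses statsmodels' MLE and direct matrix arithmetic.
        """
        y, X = _random_logit_data(n=500, seed=3)
        n = len(y)
        mle = sm.Logit(y, X).fit(disp=0)
        mu = mle.predict(X)
        U = X * (y - mu)[:, None]
        A = (X * (mu * (1 - mu))[:, None]).T @ X
        a_inv = np.linalg.inv(A)
        oracle = a_inv @ (U.T @ U) @ a_inv * n / (n - 1)
        d = SurveyDesign(np.zeros(n), np.arange(n), np.ones(n))
        fit = fit_weighted_logistic(y, X, d)
        np.testing.assert_allclose(fit.covariance, oracle, rtol=1e-6,
                                   atol=1e-12)

    def test_invariant_to_label_names_and_weight_scale(self):
        y, X = _random_logit_data(n=300, seed=4)
        rng = np.random.default_rng(4)
        strat = rng.integers(5, size=300)
        psu = rng.integers(4, size=300)
        w = rng.uniform(0.5, 3.0, 300)
        f1 = fit_weighted_logistic(y, X, SurveyDesign(strat, psu, w))
        relabel = np.array([f"s{v}" for v in strat])
        repsu = np.array([f"p{v}" for v in psu])
        f2 = fit_weighted_logistic(y, X,
                                   SurveyDesign(relabel, repsu, 13.7 * w))
        np.testing.assert_allclose(f1.covariance, f2.covariance, rtol=1e-8)
        assert f1.df_design == f2.df_design

    def test_identical_psus_contribute_zero_variance(self):
        y, X = _random_logit_data(n=100, seed=5)
        # duplicate the data into two identical PSUs within one stratum
        y2, X2 = np.r_[y, y], np.r_[X, X]
        psu = np.r_[np.zeros(100), np.ones(100)]
        d = SurveyDesign(np.zeros(200), psu, np.ones(200))
        fit = fit_weighted_logistic(y2, X2, d)
        np.testing.assert_allclose(fit.covariance, 0.0, atol=1e-12)

    def test_psu_labels_are_nested_within_strata(self):
        # the same PSU label in two strata must count as two PSUs
        y, X = _random_logit_data(n=200, seed=6)
        strat = np.repeat([0, 1], 100)
        psu = np.tile(np.repeat([0, 1], 50), 2)
        d = SurveyDesign(strat, psu, np.ones(200))
        assert d.n_psu == 4
        assert d.df_design == 2

    def test_lonely_psu_default_error_and_certainty_option(self):
        y, X = _random_logit_data(n=120, seed=7)
        strat = np.r_[np.zeros(40), np.ones(80)]
        psu = np.r_[np.zeros(40), np.repeat([0, 1], 40)]
        d = SurveyDesign(strat, psu, np.ones(120))
        with pytest.raises(LonelyPsuError):
            fit_weighted_logistic(y, X, d)
        fit = fit_weighted_logistic(y, X, d, lonely_psu="certainty")
        assert np.all(np.isfinite(fit.covariance))


class TestErrors:
    def test_rank_deficiency_names_collinear_term(self):
        y, X = _random_logit_data(seed=8)
        Xbad = np.c_[X, X[:, 1]]
        d = SurveyDesign(np.zeros(len(y)), np.arange(len(y)),
                         np.ones(len(y)))
        with pytest.raises(RankDeficiencyError, match="dup"):
            fit_weighted_logistic(y, Xbad, d,
                                  term_names=["intercept", "x1", "x2", "x3",
                                              "dup"])

    def test_complete_separation_raises(self):
        n = 60
        x = np.linspace(-2, 2, n)
        y = (x > 0).astype(float)
        X = np.c_[np.ones(n), x]
        d = SurveyDesign(np.zeros(n), np.arange(n), np.ones(n))
        with pytest.raises(SeparationError):
            fit_weighted_logistic(y, X, d)

    def test_constant_response_rejected(self):
        n = 50
        X = np.c_[np.ones(n), np.linspace(0, 1, n)]
        d = SurveyDesign(np.zeros(n), np.arange(n), np.ones(n))
        with pytest.raises(Exception, match="variation"):
            fit_weighted_logistic(np.ones(n), X, d)


class TestWald:
    def _fit(self):
        y, X = _random_logit_data(seed=9)
        d = SurveyDesign(np.zeros(len(y)), np.arange(len(y)),
                         np.ones(len(y)))
        return fit_weighted_logistic(y, X, d,
                                     term_names=["intercept", "a", "b", "c"])

    def test_zero_beta_gives_p_one(self):
        fit = self._fit()
        fit.coefficients[1] = 0.0
        _, p = wald_test(fit, "a")
        assert p == pytest.approx(1.0)

    def test_two_sided_symmetry(self):
        fit = self._fit()
        _, p_plus = wald_test(fit, "a")
        fit.coefficients[fit.term_index("a")] *= -1
        _, p_minus = wald_test(fit, "a")
        assert p_plus == pytest.approx(p_minus, rel=1e-12)

    def test_large_df_limit_matches_normal(self):
        fit = self._fit()
        fit.df_design = 10 ** 6
        j = fit.term_index("a")
        fit.coefficients[j] = 1.96 * fit.se[j]
        _, p = wald_test(fit, "a")
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_t_reference_uses_design_df(self):
        fit = self._fit()
        fit.df_design = 7
        j = fit.term_index("a")
        t, p = wald_test(fit, "a")
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=7), rel=1e-12)

    def test_unknown_term_raises(self):
        with pytest.raises(KeyError):
            wald_test(self._fit(), "nope")
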
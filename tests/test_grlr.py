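"""Unit tests for the ridge-penalized logistic core.

Oracles: statsmodels for the unpenalized MLE, a direct BFGS
minimization of the explicit penalized objective for the ridge fit.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import chi2

from grlrscan import PenaltySpec, fit_grlr, fit_logistic, model_pvalue, wald_pvalues
from grlrscan.grlr import effective_df

from conftest import make_case_control

LOGIT_05 = -2.9444389791664403


def _pen_objective(X, y, pen_diag):
    """Negative penalized log-likelihood; beta[0] is the intercept."""

    def f(beta):
        eta = beta[0] + X @ beta[1:]
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return -(ll - 0.5 * np.sum(pen_diag * beta[1:] ** 2))

    return f


def test_intercept_only_closed_form():
    y = np.array([1.0] * 5 + [0.0] * 95)
    fit = fit_logistic(np.empty((100, 0)), y)
    assert fit.intercept == pytest.approx(LOGIT_05, abs=1e-12)
    assert fit.eff_df == pytest.approx(1.0, abs=1e-10)
    assert fit.converged


def test_mle_matches_statsmodels(rng):
    X, y = make_case_control(rng)
    fit = fit_logistic(X, y)
    sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(fit.beta, sm_fit.params, atol=1e-6)
    assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-8)
    np.testing.assert_allclose(fit.wald_p, sm_fit.pvalues[1:], atol=1e-5)


def test_ridge_matches_bfgs_oracle(rng):
    X, y = make_case_control(rng, n=100, m=5)
    pen = PenaltySpec(np.array([0.1, 0.3, 0.0, 0.2, 0.4]), lam=2.5)
    fit = fit_grlr(X, y, pen)
    obj = _pen_objective(X, y, pen.lam * pen.diag)
    res = minimize(obj, np.zeros(6), method="BFGS", options={"gtol": 1e-10})
    np.testing.assert_allclose(fit.beta, res.x, atol=1e-5)
    assert fit.penalized_loglik == pytest.approx(-res.fun, abs=1e-8)
    assert fit.penalized_loglik >= -obj(np.zeros(6)) - 1e-12


def test_lambda_to_zero_recovers_mle(rng):
    X, y = make_case_control(rng, n=120, m=3)
    pen = PenaltySpec(np.ones(3) / 3.0, lam=1e-10)
    ridge = fit_grlr(X, y, pen)
    mle = fit_logistic(X, y)
    np.testing.assert_allclose(ridge.beta, mle.beta, atol=1e-4)
    assert ridge.eff_df == pytest.approx(mle.eff_df, abs=1e-4)


def test_effective_df_bounds_and_lambda_monotone(rng):
    X, y = make_case_control(rng, n=90, m=4)
    dfs = []
    for lam in (1e-6, 0.1, 1.0, 10.0, 1e4):
        fit = fit_grlr(X, y, PenaltySpec(np.ones(4) / 4.0, lam=lam))
        assert 1.0 - 1e-8 <= fit.eff_df <= 5.0 + 1e-8
        dfs.append(fit.eff_df)
    assert np.all(np.diff(dfs) < 0)
    assert dfs[-1] == pytest.approx(1.0, abs=5e-2)  # heavy shrinkage -> ~intercept only


def test_effective_df_formula(rng):
    X, y = make_case_control(rng, n=70, m=3)
    pen = PenaltySpec(np.array([0.5, 0.3, 0.2]), lam=3.0)
    fit = fit_grlr(X, y, pen)
    w = fit.fitted_probs * (1.0 - fit.fitted_probs)
    # explicit trace[(X'WX + lam P~)^{-1} X'WX] with intercept column
    X1 = np.column_stack([np.ones(len(y)), X])
    XtWX = (X1 * w[:, None]).T @ X1
    H = XtWX + np.diag(np.concatenate(([0.0], pen.lam * pen.diag)))
    expected = np.trace(np.linalg.solve(H, XtWX))
    assert fit.eff_df == pytest.approx(expected, abs=1e-8)
    assert effective_df(X, w, pen) == pytest.approx(expected, abs=1e-10)


def test_aic_identity(rng):
    X, y = make_case_control(rng)
    fit = fit_grlr(X, y, PenaltySpec(np.ones(4) / 4.0, lam=2.0))
    assert fit.aic == -2.0 * fit.loglik + 2.0 * fit.eff_df


def test_model_pvalue_matches_chi2(rng):
    X, y = make_case_control(rng, effect=1.2)
    fit = fit_grlr(X, y, PenaltySpec(np.ones(4) / 4.0, lam=1.0))
    null = fit_logistic(np.empty((len(y), 0)), y)
    p = model_pvalue(fit, null_fit=null)
    stat = 2.0 * (fit.loglik - null.loglik)
    assert p == pytest.approx(chi2.sf(stat, fit.eff_df - 1.0), rel=1e-10)
    assert model_pvalue(fit, y=y) == pytest.approx(p, rel=1e-12)


def test_model_pvalue_negative_lr_clamped():
    # heavy shrinkage can push the unpenalized LL below the null LL
    rng = np.random.default_rng(7)
    X = rng.binomial(2, 0.5, size=(60, 2)).astype(float)
    y = rng.integers(0, 2, 60).astype(float)
    fit = fit_grlr(X, y, PenaltySpec(np.ones(2), lam=1e6))
    null = fit_logistic(np.empty((60, 0)), y)
    if fit.loglik <= null.loglik:
        assert model_pvalue(fit, null_fit=null) == 1.0


def test_wald_matches_statsmodels_at_mle(rng):
    X, y = make_case_control(rng, n=150, m=3)
    fit = fit_logistic(X, y)
    sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(wald_pvalues(fit), sm_fit.pvalues[1:], atol=1e-5)


def test_sandwich_vcov_formula(rng):
    X, y = make_case_control(rng, n=90, m=3)
    pen = PenaltySpec(np.array([0.2, 0.5, 0.3]), lam=4.0)
    fit = fit_grlr(X, y, pen)
    w = fit.fitted_probs * (1.0 - fit.fitted_probs)
    X1 = np.column_stack([np.ones(len(y)), X])
    XtWX = (X1 * w[:, None]).T @ X1
    H = XtWX + np.diag(np.concatenate(([0.0], pen.lam * pen.diag)))
    Hinv = np.linalg.inv(H)
    np.testing.assert_allclose(fit.vcov, Hinv @ XtWX @ Hinv, atol=1e-8)


def test_constant_column_pinned(rng):
    X, y = make_case_control(rng, m=3)
    X[:, 2] = 1.0  # monomorphic SNP
    fit = fit_grlr(X, y, PenaltySpec(np.ones(3) / 3.0))
    assert fit.coefficients[2] == 0.0
    assert fit.wald_p[2] == 1.0
    assert fit.converged


def test_validation_errors(rng):
    X, y = make_case_control(rng)
    with pytest.raises(ValueError):
        PenaltySpec(np.array([-0.1, 1.0]))
    with pytest.raises(ValueError):
        PenaltySpec(np.ones(2), lam=0.0)
    with pytest.raises(ValueError):
        fit_grlr(X, y, PenaltySpec(np.ones(3)))  # dim mismatch
    with pytest.raises(ValueError):
        fit_logistic(X, np.full(len(y), 2.0))  # non-binary response
    with pytest.raises(ValueError):
        fit_logistic(X, np.zeros(len(y)))  # single class
    with pytest.raises(ValueError):
        model_pvalue(fit_logistic(X, y))  # needs null_fit or y


def test_fitted_probs_are_probabilities(rng):
    X, y = make_case_control(rng)
    fit = fit_grlr(X, y, PenaltySpec(np.ones(4) / 4.0))
    expected = expit(fit.intercept + X @ fit.coefficients)
    np.testing.assert_allclose(fit.fitted_probs, expected, atol=1e-12)
    assert np.all((fit.fitted_probs > 0) & (fit.fitted_probs < 1))
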
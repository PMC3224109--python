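"""Generalized ridge logistic regression (GRLR).

The model is ordinary logistic regression with a quadratic shrinkage
penalty on the SNP coefficients,

    L(beta; lambda, P) = sum_i [y_i log p_i + (1 - y_i) log(1 - p_i)]
                         - (1/2) lambda beta_1' P beta_1,

where ``P`` is a nonnegative-definite (here diagonal) penalty matrix and
``lambda > 0`` a scale constant.  The intercept ``beta_0`` is never
penalized.  Fitting is by damped Newton-Raphson; model complexity is
measured by the effective degrees of freedom
``trace[(X'WX + lambda P)^(-1) X'WX]`` and coefficient variances by the
sandwich ``(X'WX + lambda P)^(-1) X'WX (X'WX + lambda P)^(-1)``, both
evaluated at the converged weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc, expit

from . import _fast


@dataclass
class PenaltySpec:
    """Diagonal penalty matrix together with its scale constant lambda."""

    diag: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.diag = np.asarray(self.diag, dtype=np.float64)
        if np.any(self.diag < 0):
            raise ValueError("penalty diagonal must be nonnegative")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return np.diag(self.diag)

    @classmethod
    def zero(cls, m: int, lam: float = 1.0) -> "PenaltySpec":
        return cls(np.zeros(m), lam)


@dataclass
class GrlrFit:
    """A fitted (possibly penalized) logistic regression model."""

    intercept: float
    coefficients: np.ndarray
    fitted_probs: np.ndarray
    loglik: float
    penalized_loglik: float
    eff_df: float
    vcov: np.ndarray
    wald_p: np.ndarray
    aic: float
    converged: bool
    n_iter: int
    column_ids: list = field(default_factory=list)

    @property
    def beta(self) -> np.ndarray:
        """Full coefficient vector, intercept first."""
        return np.concatenate(([self.intercept], self.coefficients))


def _validate_response(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64).ravel()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("response contains a single class; model is not identifiable")
    return y


def fit_grlr(X, y, penalty: PenaltySpec, column_ids=None) -> GrlrFit:
    """Fit GRLR on genotype columns ``X`` (n x m) with the given penalty.

    Constant columns are retained with their coefficient pinned at zero
    and Wald p-value 1, so repeated fits inside permutation loops never
    abort on monomorphic SNPs.
    """
    y = _validate_response(y)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    if penalty.diag.shape[0] != m:
        raise ValueError("penalty dimension does not match number of columns")

    X1 = np.empty((n, m + 1))
    X1[:, 0] = 1.0
    X1[:, 1:] = X
    pen = np.concatenate(([0.0], penalty.lam * penalty.diag))
    beta, ll, pll, H, eff_df, conv, n_iter = _fast.penalized_logistic_newton(X1, y, pen)

    eta = X1 @ beta
    probs = expit(eta)
    w = probs * (1.0 - probs)
    XtWX = (X1 * w[:, None]).T @ X1

    const = np.zeros(m + 1, dtype=bool)
    if m:
        const[1:] = X[:, :].std(axis=0) == 0.0
    keep = ~const
    vcov = np.full((m + 1, m + 1), np.nan)
    wald = np.ones(m)
    Hk = H[np.ix_(keep, keep)]
    try:
        Hk_inv = np.linalg.inv(Hk)
        Vk = Hk_inv @ XtWX[np.ix_(keep, keep)] @ Hk_inv
        vcov[np.ix_(keep, keep)] = Vk
        se = np.sqrt(np.diag(vcov))
        for j in range(1, m + 1):
            if keep[j] and se[j] > 0 and np.isfinite(se[j]):
                z = abs(beta[j]) / se[j]
                wald[j - 1] = float(erfc(z / np.sqrt(2.0)))
    except np.linalg.LinAlgError:
        conv = False

    aic = -2.0 * ll + 2.0 * eff_df
    return GrlrFit(
        intercept=float(beta[0]),
        coefficients=beta[1:].copy(),
        fitted_probs=probs,
        loglik=ll,
        penalized_loglik=pll,
        eff_df=eff_df,
        vcov=vcov,
        wald_p=wald,
        aic=aic,
        converged=conv,
        n_iter=n_iter,
        column_ids=list(column_ids) if column_ids is not None else list(range(m)),
    )


def fit_logistic(X, y, column_ids=None) -> GrlrFit:
    """Unpenalized maximum-likelihood logistic regression.

    ``X`` may have zero columns, in which case the closed-form
    intercept-only fit ``beta_0 = logit(mean(y))`` is returned with
    ``eff_df = 1``.  Complete separation shows up as non-convergence
    with large coefficients; it is flagged, not raised.
    """
    y = _validate_response(y)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    m = X.shape[1] if X.size or X.ndim == 2 else 0
    # a vanishing ridge gives the MLE while reusing the penalized solver
    return fit_grlr(X, y, PenaltySpec.zero(m, lam=1.0), column_ids=column_ids)


def effective_df(X, w: np.ndarray, penalty: PenaltySpec) -> float:
    """trace[(X'WX + lambda P~)^{-1} X'WX] at weights ``w``.

    ``X`` excludes the intercept column; it is prepended here with a zero
    penalty entry, so the returned value lies in (0, m + 1].
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    X1 = np.empty((n, m + 1))
    X1[:, 0] = 1.0
    X1[:, 1:] = X
    pen = np.concatenate(([0.0], penalty.lam * penalty.diag))
    XtWX = (X1 * np.asarray(w, dtype=np.float64)[:, None]).T @ X1
    H = XtWX.copy()
    H[np.diag_indices_from(H)] += pen
    return float(np.trace(np.linalg.solve(H, XtWX)))


def wald_pvalues(fit: GrlrFit) -> np.ndarray:
    """Two-sided Wald p-values for the SNP coefficients of a fit."""
    return fit.wald_p.copy()


def model_pvalue(fit: GrlrFit, null_fit: GrlrFit | None = None, y=None) -> float:
    """Model-fitness p-value P{E}: LRT of the fit against intercept-only.

    The statistic ``2 (loglik - loglik_null)`` uses the *unpenalized*
    log-likelihood at the penalized estimate and is referred to a
    chi-square with fractional degrees of freedom ``eff_df - 1``.
    Negative statistics (possible under heavy shrinkage) are clamped to
    zero, yielding p = 1.
    """
    if null_fit is not None:
        ll0 = null_fit.loglik
    elif y is not None:
        ll0 = _fast.null_loglik(np.asarray(y, dtype=np.float64))
    else:
        raise ValueError("provide either null_fit or y")
    return _fast.model_pvalue_from(fit.loglik, ll0, fit.eff_df)
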
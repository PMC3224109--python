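"""Lean numerical kernels.

These functions operate on plain ndarrays and return plain tuples; the
public dataclass-based API in :mod:`grlrscan.grlr` and
:mod:`grlrscan.scan` wraps them.  The replication engine in
:mod:`grlrscan.power` calls them directly because a power study fits
hundreds of thousands of small logistic models and cannot afford object
construction per fit.

Conventions: genotype matrices are ``(n_individuals, n_snps)`` with
additive coding 0/1/2, phenotypes are 0/1 vectors, and every penalized
fit carries the intercept as an unpenalized leading column.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import chdtrc, erfc, expit

# Elementwise budget per chunk of the batched single-locus scan; keeps
# peak memory of the (B, N, n) temporaries around a few hundred MB.
_CHUNK_ELEMS = 4_000_000


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Log-likelihood of a logistic model at linear predictor ``eta``."""
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def null_loglik(y: np.ndarray) -> float:
    """Log-likelihood of the intercept-only logistic model (closed form)."""
    n = y.shape[0]
    ybar = float(np.mean(y))
    if ybar <= 0.0 or ybar >= 1.0:
        return 0.0
    return n * (ybar * math.log(ybar) + (1.0 - ybar) * math.log(1.0 - ybar))


def batch_single_locus_pvalues(
    G: np.ndarray,
    Y: np.ndarray,
    max_iter: int = 30,
    tol: float = 1e-9,
) -> np.ndarray:
    """Wald p-values of one-SNP logistic regressions, batched.

    Fits ``logit P(y=1) = b0 + b1 * x`` for every (label vector, SNP)
    pair by Newton-Raphson with a closed-form 2x2 solve, vectorized over
    both axes.

    Parameters
    ----------
    G : (n, N) array of genotype codes 0/1/2.
    Y : (B, n) array of 0/1 label vectors (rows are e.g. the observed
        labels plus permutations).

    Returns
    -------
    (B, N) array of two-sided Wald p-values for the slope.  Monomorphic
    SNPs and numerically degenerate fits get p = 1.
    """
    g = np.asarray(G, dtype=np.float64)
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    n, N = g.shape
    B = Y.shape[0]
    out = np.empty((B, N))
    rows_per_chunk = max(1, _CHUNK_ELEMS // max(1, N * n))
    for lo in range(0, B, rows_per_chunk):
        hi = min(B, lo + rows_per_chunk)
        out[lo:hi] = _batch_single_locus_chunk(g, Y[lo:hi], max_iter, tol)
    return out


def _batch_single_locus_chunk(g, Y, max_iter, tol):
    n, N = g.shape
    B = Y.shape[0]
    gT = np.ascontiguousarray(g.T)[None, :, :]          # (1, N, n)
    poly = g.std(axis=0) > 0.0                          # polymorphic SNPs
    ybar = Y.mean(axis=1)
    with np.errstate(divide="ignore"):
        b0 = np.tile(np.log(ybar / (1.0 - ybar))[:, None], (1, N))
    b1 = np.zeros((B, N))
    Ye = Y[:, None, :]                                  # (B, 1, n)
    active = np.broadcast_to(poly, (B, N)).copy()
    usable = active.copy()
    for _ in range(max_iter):
        eta = b0[:, :, None] + b1[:, :, None] * gT
        p = expit(eta)
        w = p * (1.0 - p)
        r = Ye - p
        g0 = r.sum(axis=-1)
        g1 = (r * gT).sum(axis=-1)
        h00 = w.sum(axis=-1)
        h01 = (w * gT).sum(axis=-1)
        h11 = (w * gT * gT).sum(axis=-1)
        det = h00 * h11 - h01 * h01
        ok = det > 1e-10
        safe = np.where(ok, det, 1.0)
        db0 = np.where(ok, (h11 * g0 - h01 * g1) / safe, 0.0)
        db1 = np.where(ok, (h00 * g1 - h01 * g0) / safe, 0.0)
        upd = active & ok
        b0 += np.where(upd, db0, 0.0)
        b1 += np.where(upd, db1, 0.0)
        # cap runaway coefficients under (quasi-)complete separation
        np.clip(b0, -30.0, 30.0, out=b0)
        np.clip(b1, -30.0, 30.0, out=b1)
        usable &= ok | ~active
        active &= ok & (np.abs(db0) + np.abs(db1) > tol)
        if not active.any():
            break
    # information at the final estimate
    eta = b0[:, :, None] + b1[:, :, None] * gT
    w = expit(eta)
    w *= 1.0 - w
    h00 = w.sum(axis=-1)
    h01 = (w * gT).sum(axis=-1)
    h11 = (w * gT * gT).sum(axis=-1)
    det = h00 * h11 - h01 * h01
    good = usable & np.broadcast_to(poly, (B, N)) & (det > 1e-10)
    se = np.sqrt(np.where(good, h00 / np.where(good, det, 1.0), np.inf))
    z = np.abs(b1) / se
    pvals = erfc(z / math.sqrt(2.0))
    pvals[~good] = 1.0
    return np.clip(pvals, 0.0, 1.0)


def penalized_logistic_newton(
    X1: np.ndarray,
    y: np.ndarray,
    pen: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    max_halvings: int = 20,
):
    """Maximize the ridge-penalized Bernoulli log-likelihood.

    Objective: ``sum_i [y_i log p_i + (1-y_i) log(1-p_i)] - 0.5 * beta' D beta``
    where ``D = diag(pen)`` already folds in the scale constant lambda and
    ``pen[0] = 0`` keeps the intercept unpenalized.  Damped Newton with
    step-halving; the penalized log-likelihood never decreases across
    accepted steps.

    Parameters
    ----------
    X1 : (n, m+1) design with leading intercept column.
    pen : (m+1,) nonnegative penalty diagonal (lambda * P entries).

    Returns
    -------
    beta, loglik, pen_loglik, H, eff_df, converged, n_iter
        ``H`` is the penalized observed information at the estimate;
        ``eff_df = trace(H^{-1} X'WX)``.
    """
    X1 = np.asarray(X1, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m1 = X1.shape
    pen = np.asarray(pen, dtype=np.float64)

    # constant columns (other than the intercept) carry no information and
    # would make the system singular when unpenalized; pin them at zero
    keep = np.empty(m1, dtype=bool)
    keep[0] = True
    for j in range(1, m1):
        col = X1[:, j]
        keep[j] = (col != col[0]).any()
    if keep.all():
        Xk, penk = X1, pen
    else:
        Xk = X1[:, keep]
        penk = pen[keep]
    mk = Xk.shape[1]
    diag_step = mk + 1  # stride of the diagonal in a flattened (mk, mk) array

    beta = np.zeros(mk)
    ybar = float(np.mean(y))
    if 0.0 < ybar < 1.0:
        beta[0] = _logit(ybar)
    eta = Xk @ beta
    pll = bernoulli_loglik(y, eta) - 0.5 * float(penk @ (beta**2))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(eta)
        w = p * (1.0 - p)
        grad = Xk.T @ (y - p)
        grad -= penk * beta
        H = (Xk * w[:, None]).T @ Xk
        H.flat[::diag_step] += penk
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return _expand_fail(beta, keep, m1, y, eta, pll)
        new_beta = beta + step
        new_eta = Xk @ new_beta
        new_pll = bernoulli_loglik(y, new_eta) - 0.5 * float(penk @ (new_beta**2))
        halvings = 0
        while new_pll < pll - 1e-12 and halvings < max_halvings:
            step *= 0.5
            new_beta = beta + step
            new_eta = Xk @ new_beta
            new_pll = bernoulli_loglik(y, new_eta) - 0.5 * float(penk @ (new_beta**2))
            halvings += 1
        if new_pll < pll - 1e-12:
            break  # cannot improve; treat current point as the optimum
        beta, eta = new_beta, new_eta
        if abs(new_pll - pll) <= tol * (abs(pll) + 1.0):
            pll = new_pll
            converged = True
            break
        pll = new_pll

    p = expit(eta)
    w = p * (1.0 - p)
    XtWX = (Xk * w[:, None]).T @ Xk
    H = XtWX.copy()
    H.flat[::diag_step] += penk
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return _expand_fail(beta, keep, m1, y, eta, pll)
    eff_df = float(np.trace(Hinv @ XtWX))
    ll = bernoulli_loglik(y, eta)

    beta_full = np.zeros(m1)
    beta_full[keep] = beta
    H_full = np.zeros((m1, m1))
    H_full[np.ix_(keep, keep)] = H
    return beta_full, ll, pll, H_full, eff_df, converged, it


def _expand_fail(beta, keep, m1, y, eta, pll):
    beta_full = np.zeros(m1)
    beta_full[keep] = beta
    return beta_full, bernoulli_loglik(y, eta), pll, np.zeros((m1, m1)), float(np.sum(keep)), False, 0


def grlr_fit_lean(Xm: np.ndarray, y: np.ndarray, lam: float, pdiag: np.ndarray):
    """Fit a GRLR model on genotype columns ``Xm`` with penalty diag ``pdiag``.

    Returns ``(beta, loglik, eff_df, aic, converged)`` where ``beta`` has
    the intercept first.
    """
    n = Xm.shape[0]
    X1 = np.empty((n, Xm.shape[1] + 1))
    X1[:, 0] = 1.0
    X1[:, 1:] = Xm
    pen = np.concatenate(([0.0], lam * np.asarray(pdiag, dtype=np.float64)))
    beta, ll, _, _, eff_df, conv, _ = penalized_logistic_newton(X1, y, pen)
    aic = -2.0 * ll + 2.0 * eff_df
    return beta, ll, eff_df, aic, conv


def model_pvalue_from(ll: float, ll0: float, eff_df: float) -> float:
    """Model-fitness p-value: LRT against the intercept-only model.

    The statistic ``2 (ll - ll0)`` is referred to a chi-square with the
    fractional degrees of freedom ``eff_df - 1``; negative statistics
    (possible under heavy shrinkage) are clamped to zero, giving p = 1.
    """
    stat = max(0.0, 2.0 * (ll - ll0))
    df = max(eff_df - 1.0, 1e-8)
    if stat == 0.0:
        return 1.0
    return float(chdtrc(df, stat))


def penalty_weights(
    positions: np.ndarray,
    center: int,
    members: np.ndarray,
    renormalize_over: np.ndarray | None = None,
) -> np.ndarray:
    """Distance-proportional penalty diagonal over ``members``.

    Entry j is ``|D_j - D_center| / sum_k |D_k - D_center|`` where the
    normalizing sum runs over ``members`` (default) or over
    ``renormalize_over``; the center gets 0 and the entries sum to 1
    unless every distance is zero.
    """
    d = np.abs(positions[members] - positions[center]).astype(np.float64)
    norm_set = members if renormalize_over is None else renormalize_over
    s = float(np.sum(np.abs(positions[norm_set] - positions[center])))
    if s <= 0.0:
        return np.zeros(len(members))
    return d / s


def forward_select_lean(
    Xr: np.ndarray,
    y: np.ndarray,
    center: int,
    positions: np.ndarray,
    surviving: np.ndarray,
    lam: float,
    renormalize: bool = True,
    aic_tol: float = 1e-9,
):
    """Greedy forward selection inside one search region, GRLR at each step.

    Parameters
    ----------
    Xr : (n, q) genotype columns of the region.
    center : region-local index of the center SNP (always in the model).
    positions : (q,) base-pair positions of the region members.
    surviving : (q,) boolean mask of truncation survivors (center forced in).
    lam : penalty scale.
    renormalize : re-normalize penalty weights to unit trace over the
        SNPs currently in the model (default); otherwise weights stay
        fixed at their normalization over the surviving set.

    Returns
    -------
    selected, aic_path, model_p, n_skipped
        ``selected`` is the ordered list of region-local indices
        (center first), ``aic_path`` the AIC after each accepted step,
        ``model_p`` the LRT model-fitness p-value of the final fit.
    """
    y = np.asarray(y, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.float64)
    ll0 = null_loglik(y)
    surv_idx = np.flatnonzero(np.asarray(surviving, dtype=bool))

    def _pdiag(model: list[int]) -> np.ndarray:
        mem = np.asarray(model)
        if renormalize:
            return penalty_weights(positions, center, mem)
        return penalty_weights(positions, center, mem, renormalize_over=surv_idx)

    selected = [center]
    _, ll, eff_df, aic, conv = grlr_fit_lean(Xr[:, selected], y, lam, _pdiag(selected))
    aic_path = [aic]
    best_ll, best_df = ll, eff_df
    n_skipped = 0
    remaining = [int(j) for j in surv_idx if j != center]
    while remaining:
        best_j = -1
        best_aic = aic - aic_tol
        best_fit = None
        for j in remaining:
            cols = selected + [j]
            b, llj, dfj, aicj, convj = grlr_fit_lean(Xr[:, cols], y, lam, _pdiag(cols))
            if not convj:
                n_skipped += 1
                continue
            if aicj < best_aic:
                best_aic = aicj
                best_j = j
                best_fit = (llj, dfj)
        if best_j < 0:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        aic = best_aic
        aic_path.append(aic)
        best_ll, best_df = best_fit
    model_p = model_pvalue_from(best_ll, ll0, best_df)
    return selected, aic_path, model_p, n_skipped
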
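"""Compiled inner loops for the replication engine.

The power study fits hundreds of thousands of small logistic models;
these numba kernels mirror the ndarray implementations in
:mod:`grlrscan._fast` (same initialization, same damped-Newton rule,
same convergence tolerances) and are cross-checked against them in the
test suite.  The public API keeps using the ndarray path; only
:mod:`grlrscan.power` calls into here.

Singular Newton systems are detected through a hand-rolled Cholesky
factorization (the penalized Hessian is symmetric positive definite
whenever it is nonsingular), which avoids exception handling inside
compiled code: a failed factorization marks the fit as non-converged
and the caller skips that candidate.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _chol_factor(H):
    """In-place lower Cholesky of H; returns False on (near-)singularity."""
    m = H.shape[0]
    for j in range(m):
        s = H[j, j]
        for k in range(j):
            s -= H[j, k] * H[j, k]
        if s <= 1e-12:
            return False
        H[j, j] = math.sqrt(s)
        for i in range(j + 1, m):
            t = H[i, j]
            for k in range(j):
                t -= H[i, k] * H[j, k]
            H[i, j] = t / H[j, j]
    return True


@njit(cache=True)
def _chol_solve(L, b, x):
    """Solve L L' x = b given the lower factor L."""
    m = L.shape[0]
    for i in range(m):
        t = b[i]
        for k in range(i):
            t -= L[i, k] * x[k]
        x[i] = t / L[i, i]
    for i in range(m - 1, -1, -1):
        t = x[i]
        for k in range(i + 1, m):
            t -= L[k, i] * x[k]
        x[i] = t / L[i, i]


@njit(cache=True)
def _chol_inv_diag(L, out):
    """Diagonal of (L L')^{-1} given the lower factor L."""
    m = L.shape[0]
    col = np.empty(m)
    e = np.empty(m)
    for j in range(m):
        for i in range(m):
            e[i] = 1.0 if i == j else 0.0
        _chol_solve(L, e, col)
        out[j] = col[j]


@njit(cache=True)
def _pen_loglik(Xk, y, beta, penk, eta):
    """Penalized Bernoulli log-likelihood; fills eta as a side effect."""
    n, mk = Xk.shape
    ll = 0.0
    for i in range(n):
        v = 0.0
        for j in range(mk):
            v += Xk[i, j] * beta[j]
        eta[i] = v
        if v > 0.0:
            ll += y[i] * v - (v + math.log1p(math.exp(-v)))
        else:
            ll += y[i] * v - math.log1p(math.exp(v))
    pterm = 0.0
    for j in range(mk):
        pterm += penk[j] * beta[j] * beta[j]
    return ll - 0.5 * pterm


@njit(cache=True)
def _newton_pen(Xk, y, penk, max_iter, tol, max_halvings):
    """Damped Newton for the ridge-penalized logistic model.

    ``Xk`` must already contain the intercept column first and no
    constant genotype columns.  Returns
    ``(beta, loglik, eff_df, converged)``.
    """
    n, mk = Xk.shape
    beta = np.zeros(mk)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    if 0.0 < ybar < 1.0:
        beta[0] = math.log(ybar / (1.0 - ybar))
    eta = np.empty(n)
    pll = _pen_loglik(Xk, y, beta, penk, eta)

    grad = np.empty(mk)
    H = np.empty((mk, mk))
    step = np.empty(mk)
    new_beta = np.empty(mk)
    new_eta = np.empty(n)
    w = np.empty(n)
    converged = False

    for _ in range(max_iter):
        for j in range(mk):
            grad[j] = -penk[j] * beta[j]
        for i in range(n):
            p = 1.0 / (1.0 + math.exp(-eta[i]))
            w[i] = p * (1.0 - p)
            r = y[i] - p
            for j in range(mk):
                grad[j] += Xk[i, j] * r
        for j in range(mk):
            for k in range(j + 1):
                s = 0.0
                for i in range(n):
                    s += w[i] * Xk[i, j] * Xk[i, k]
                H[j, k] = s
                H[k, j] = s
            H[j, j] += penk[j]
        if not _chol_factor(H):
            return beta, _pen_loglik(Xk, y, beta, np.zeros(mk), eta), float(mk), False
        _chol_solve(H, grad, step)
        for j in range(mk):
            new_beta[j] = beta[j] + step[j]
        new_pll = _pen_loglik(Xk, y, new_beta, penk, new_eta)
        halvings = 0
        while new_pll < pll - 1e-12 and halvings < max_halvings:
            for j in range(mk):
                step[j] *= 0.5
                new_beta[j] = beta[j] + step[j]
            new_pll = _pen_loglik(Xk, y, new_beta, penk, new_eta)
            halvings += 1
        if new_pll < pll - 1e-12:
            break
        for j in range(mk):
            beta[j] = new_beta[j]
        for i in range(n):
            eta[i] = new_eta[i]
        if abs(new_pll - pll) <= tol * (abs(pll) + 1.0):
            pll = new_pll
            converged = True
            break
        pll = new_pll

    # information matrices at the estimate
    for i in range(n):
        p = 1.0 / (1.0 + math.exp(-eta[i]))
        w[i] = p * (1.0 - p)
    for j in range(mk):
        for k in range(j + 1):
            s = 0.0
            for i in range(n):
                s += w[i] * Xk[i, j] * Xk[i, k]
            H[j, k] = s
            H[k, j] = s
        H[j, j] += penk[j]
    if not _chol_factor(H):
        return beta, _pen_loglik(Xk, y, beta, np.zeros(mk), eta), float(mk), False
    hinv_diag = np.empty(mk)
    _chol_inv_diag(H, hinv_diag)
    eff_df = float(mk)
    for j in range(mk):
        eff_df -= penk[j] * hinv_diag[j]
    ll = _pen_loglik(Xk, y, beta, np.zeros(mk), eta)
    return beta, ll, eff_df, converged


@njit(cache=True)
def _fit_model(Xr, y, cols, ncols, dist, lam, renormalize, surv_dist_sum):
    """Fit the GRLR model on region columns ``cols[:ncols]``.

    Returns (loglik, eff_df, aic, ok).  Constant columns are dropped
    from the system (their coefficient is pinned at zero).
    """
    n = Xr.shape[0]
    # penalty normalization over the in-model SNPs or the surviving set
    dsum = 0.0
    if renormalize:
        for c in range(ncols):
            dsum += dist[cols[c]]
    else:
        dsum = surv_dist_sum
    # count non-constant columns
    mk = 1
    use = np.empty(ncols, np.bool_)
    for c in range(ncols):
        j = cols[c]
        v0 = Xr[0, j]
        const = True
        for i in range(1, n):
            if Xr[i, j] != v0:
                const = False
                break
        use[c] = not const
        if not const:
            mk += 1
    Xk = np.empty((n, mk))
    penk = np.empty(mk)
    for i in range(n):
        Xk[i, 0] = 1.0
    penk[0] = 0.0
    idx = 1
    for c in range(ncols):
        if use[c]:
            j = cols[c]
            for i in range(n):
                Xk[i, idx] = Xr[i, j]
            penk[idx] = lam * (dist[j] / dsum) if dsum > 0.0 else 0.0
            idx += 1
    beta, ll, eff_df, ok = _newton_pen(Xk, y, penk, 50, 1e-8, 20)
    aic = -2.0 * ll + 2.0 * eff_df
    return ll, eff_df, aic, ok


@njit(cache=True)
def forward_select_kernel(Xr, y, center, positions, surv_mask, lam, renormalize):
    """Greedy forward selection in one region (compiled path).

    Same procedure as :func:`grlrscan._fast.forward_select_lean`:
    start from the center SNP, add the surviving SNP lowering the AIC
    most, stop when no strict decrease (tolerance 1e-9) remains.

    Returns ``(selected, n_selected, loglik, eff_df)``; the caller turns
    the final log-likelihood and effective df into the model-fitness
    p-value.
    """
    q = Xr.shape[1]
    dist = np.empty(q)
    surv_dist_sum = 0.0
    for j in range(q):
        dist[j] = abs(positions[j] - positions[center])
        if surv_mask[j]:
            surv_dist_sum += dist[j]

    selected = np.empty(q, np.int64)
    selected[0] = center
    nsel = 1
    remaining = np.empty(q, np.int64)
    nrem = 0
    for j in range(q):
        if surv_mask[j] and j != center:
            remaining[nrem] = j
            nrem += 1

    cols = np.empty(q, np.int64)
    cols[0] = center
    ll, eff_df, aic, ok = _fit_model(
        Xr, y, cols, 1, dist, lam, renormalize, surv_dist_sum
    )
    best_ll, best_df = ll, eff_df

    while nrem > 0:
        best_aic = aic - 1e-9
        best_r = -1
        cand_ll = 0.0
        cand_df = 0.0
        for r in range(nrem):
            for c in range(nsel):
                cols[c] = selected[c]
            cols[nsel] = remaining[r]
            llj, dfj, aicj, okj = _fit_model(
                Xr, y, cols, nsel + 1, dist, lam, renormalize, surv_dist_sum
            )
            if not okj:
                continue
            if aicj < best_aic:
                best_aic = aicj
                best_r = r
                cand_ll = llj
                cand_df = dfj
        if best_r < 0:
            break
        selected[nsel] = remaining[best_r]
        nsel += 1
        remaining[best_r] = remaining[nrem - 1]
        nrem -= 1
        aic = best_aic
        best_ll, best_df = cand_ll, cand_df
    return selected[:nsel], nsel, best_ll, best_df


@njit(cache=True)
def single_locus_kernel(G, Y, max_iter=30, tol=1e-9):
    """Per-(label row, SNP) Wald p-values of one-SNP logistic fits.

    Compiled equivalent of
    :func:`grlrscan._fast.batch_single_locus_pvalues` (same Newton
    rules, same degenerate-fit conventions).
    """
    n, N = G.shape
    B = Y.shape[0]
    out = np.ones((B, N))
    sqrt2 = math.sqrt(2.0)
    for s in range(N):
        x0 = G[0, s]
        mono = True
        for i in range(1, n):
            if G[i, s] != x0:
                mono = False
                break
        if mono:
            continue
        for b in range(B):
            ybar = 0.0
            for i in range(n):
                ybar += Y[b, i]
            ybar /= n
            b0 = math.log(ybar / (1.0 - ybar))
            b1 = 0.0
            usable = True
            for _ in range(max_iter):
                g0 = 0.0
                g1 = 0.0
                h00 = 0.0
                h01 = 0.0
                h11 = 0.0
                for i in range(n):
                    x = G[i, s]
                    p = 1.0 / (1.0 + math.exp(-(b0 + b1 * x)))
                    w = p * (1.0 - p)
                    r = Y[b, i] - p
                    g0 += r
                    g1 += r * x
                    h00 += w
                    h01 += w * x
                    h11 += w * x * x
                det = h00 * h11 - h01 * h01
                if det <= 1e-10:
                    usable = False
                    break
                db0 = (h11 * g0 - h01 * g1) / det
                db1 = (h00 * g1 - h01 * g0) / det
                b0 += db0
                b1 += db1
                if b0 > 30.0:
                    b0 = 30.0
                elif b0 < -30.0:
                    b0 = -30.0
                if b1 > 30.0:
                    b1 = 30.0
                elif b1 < -30.0:
                    b1 = -30.0
                if abs(db0) + abs(db1) <= tol:
                    break
            if not usable:
                continue
            h00 = 0.0
            h01 = 0.0
            h11 = 0.0
            for i in range(n):
                x = G[i, s]
                p = 1.0 / (1.0 + math.exp(-(b0 + b1 * x)))
                w = p * (1.0 - p)
                h00 += w
                h01 += w * x
                h11 += w * x * x
            det = h00 * h11 - h01 * h01
            if det <= 1e-10:
                continue
            se = math.sqrt(h00 / det)
            out[b, s] = math.erfc(abs(b1) / se / sqrt2)
    return out
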
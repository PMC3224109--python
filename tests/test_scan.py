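"""Unit tests for the sliding-window scan pipeline.

The forward-selection oracle re-implements the greedy rule with an
independent penalized fit (BFGS on the explicit objective, effective df
from the trace formula) and must agree step by step.
"""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import chi2

from grlrscan import (
    ScanConfig,
    SearchRegion,
    build_penalty,
    build_regions,
    forward_select,
    run_scan,
    scan_statistic,
    single_locus_scan,
    truncate_region,
)
from grlrscan.scan import write_scan_report


def _sim_window(rng, n=100, m=21, causal=None, effect=1.0, maf=0.4):
    G = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    causal = [m // 2] if causal is None else [c for c in causal if c < m]
    eta = -1.0 + effect * G[:, causal].sum(axis=1)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)
    if y.min() == y.max():  # pragma: no cover
        y[0] = 1 - y[0]
    return G, y


# ---------------------------------------------------------------- single locus


def test_single_locus_matches_statsmodels(rng):
    G, y = _sim_window(rng, m=6)
    pvals = single_locus_scan(G, y)
    for j in range(6):
        smf = sm.Logit(y, sm.add_constant(G[:, j].astype(float))).fit(disp=0)
        assert pvals[j] == pytest.approx(smf.pvalues[1], abs=1e-6)


def test_single_locus_monomorphic_gets_one(rng):
    G, y = _sim_window(rng, m=4)
    G[:, 2] = 1
    pvals = single_locus_scan(G, y)
    assert pvals[2] == 1.0


def test_single_locus_missing_complete_case(rng):
    G, y = _sim_window(rng, m=5)
    G = G.astype(np.int8)
    G[::7, 3] = -1  # sprinkle missing genotypes into one SNP
    pvals = single_locus_scan(G, y, missing=-1)
    mask = G[:, 3] != -1
    smf = sm.Logit(y[mask], sm.add_constant(G[mask, 3].astype(float))).fit(disp=0)
    assert pvals[3] == pytest.approx(smf.pvalues[1], abs=1e-6)
    # other SNPs unaffected
    full = single_locus_scan(G[:, :3], y)
    np.testing.assert_allclose(pvals[:3], full, atol=1e-12)


def test_single_locus_validation(rng):
    G, y = _sim_window(rng)
    with pytest.raises(ValueError):
        single_locus_scan(G, np.full_like(y, 2))
    with pytest.raises(ValueError):
        single_locus_scan(G, np.zeros_like(y))


# -------------------------------------------------------------------- regions


def test_build_regions_threshold_and_clipping():
    p = np.ones(21)
    p[0] = p[10] = p[20] = 0.01
    cfg = ScanConfig(flank=10)
    regions = build_regions(p, np.arange(1, 22), cfg)
    assert [r.center for r in regions] == [0, 10, 20]
    r0, r10, r20 = regions
    assert r0.members.tolist() == list(range(0, 11))       # clipped left
    assert (r0.flank_u, r0.flank_v) == (0, 10)
    assert r10.members.tolist() == list(range(0, 21))      # full window
    assert r20.members.tolist() == list(range(10, 21))     # clipped right
    assert (r20.flank_u, r20.flank_v) == (10, 0)


def test_build_regions_top_s():
    p = np.linspace(0.001, 0.9, 21)
    cfg = ScanConfig(flank=3, top_s=2, seed_threshold=None)
    regions = build_regions(p, np.arange(1, 22), cfg)
    assert [r.center for r in regions] == [0, 1]


def test_build_regions_respects_chromosome_breaks():
    p = np.full(10, 0.01)
    chrom = np.array([1] * 5 + [2] * 5)
    cfg = ScanConfig(flank=4)
    regions = build_regions(p, np.arange(1, 11), cfg, chromosomes=chrom)
    for r in regions:
        assert len(set(chrom[r.members])) == 1  # never crosses the break


def test_build_regions_empty_seed_set():
    cfg = ScanConfig(flank=3)
    assert build_regions(np.full(9, 0.9), np.arange(1, 10), cfg) == []


def test_build_regions_needs_seed_rule():
    cfg = ScanConfig(flank=3, top_s=None, seed_threshold=None)
    with pytest.raises(ValueError):
        build_regions(np.full(9, 0.9), np.arange(1, 10), cfg)


# -------------------------------------------------------------------- penalty


def test_penalty_weights_unit_trace_center_zero():
    region = SearchRegion(
        center=10,
        members=np.arange(21),
        positions=np.arange(1.0, 22.0),
        flank_u=10,
        flank_v=10,
    )
    pen = build_penalty(region, lam=1.0)
    # positions 1..21, center position 11: weight_j = |j - 11| / 110
    expected = np.abs(np.arange(1, 22) - 11) / 110.0
    np.testing.assert_allclose(pen.diag, expected, atol=1e-14)
    assert pen.diag[10] == 0.0
    assert pen.diag.sum() == pytest.approx(1.0, abs=1e-12)


def test_penalty_single_member_region():
    region = SearchRegion(
        center=0, members=np.array([0]), positions=np.array([5.0]),
        flank_u=0, flank_v=0,
    )
    pen = build_penalty(region)
    np.testing.assert_array_equal(pen.diag, [0.0])


# ----------------------------------------------------------------- truncation


def test_truncation_drops_high_p_center_exempt():
    region = SearchRegion(
        center=5, members=np.arange(11), positions=np.arange(1.0, 12.0),
        flank_u=5, flank_v=5,
    )
    p = np.full(11, 0.5)
    p[2] = 0.01
    trunc = truncate_region(region, p, t=0.05)
    assert trunc.surviving.tolist() == [2, 5]  # survivor + exempt center
    with pytest.raises(ValueError):
        truncate_region(region, p, t=0.0)


# ---------------------------------------------------- forward selection oracle


def _oracle_fit(X, y, lam, pdiag):
    """Independent penalized fit: BFGS + trace formula for eff df."""
    m = X.shape[1]

    def negobj(beta):
        eta = beta[0] + X @ beta[1:]
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return -(ll - 0.5 * lam * np.sum(pdiag * beta[1:] ** 2))

    res = minimize(negobj, np.zeros(m + 1), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    beta = res.x
    eta = beta[0] + X @ beta[1:]
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    X1 = np.column_stack([np.ones(len(y)), X])
    XtWX = (X1 * w[:, None]).T @ X1
    H = XtWX + np.diag(np.concatenate(([0.0], lam * pdiag)))
    eff_df = float(np.trace(np.linalg.solve(H, XtWX)))
    return ll, eff_df, -2.0 * ll + 2.0 * eff_df


def _oracle_forward(G, y, positions, center, surviving, lam):
    """Greedy AIC forward selection, penalty renormalized per step."""
    y = y.astype(float)
    selected = [center]
    remaining = [j for j in surviving if j != center]

    def pdiag(model):
        d = np.abs(positions[model] - positions[center]).astype(float)
        s = d.sum()
        return d / s if s > 0 else d

    ll, df, aic = _oracle_fit(G[:, selected].astype(float), y, lam, pdiag(selected))
    path = [aic]
    while remaining:
        cand = []
        for j in remaining:
            cols = selected + [j]
            cand.append((j, _oracle_fit(G[:, cols].astype(float), y, lam, pdiag(cols))))
        j_best, (llb, dfb, aicb) = min(cand, key=lambda t: t[1][2])
        if aicb >= aic - 1e-9:
            break
        selected.append(j_best)
        remaining.remove(j_best)
        ll, df, aic = llb, dfb, aicb
        path.append(aic)
    n = len(y)
    ybar = y.mean()
    ll0 = n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
    stat = max(0.0, 2.0 * (ll - ll0))
    model_p = 1.0 if stat == 0.0 else float(chi2.sf(stat, max(df - 1.0, 1e-8)))
    return selected, path, model_p


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_forward_selection_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    G, y = _sim_window(rng, n=80, m=5, causal=(2, 4), effect=0.9)
    positions = np.arange(1.0, 6.0)
    region = SearchRegion(
        center=2, members=np.arange(5), positions=positions,
        flank_u=2, flank_v=2, surviving=np.arange(5),
    )
    cfg = ScanConfig(flank=2, lam=1.0)
    result = forward_select(region, G, y, cfg)
    sel_o, path_o, p_o = _oracle_forward(G, y, positions, 2, list(range(5)), 1.0)
    assert result.selected.tolist() == sel_o
    np.testing.assert_allclose(result.aic_path, path_o, atol=1e-4)
    assert result.model_p == pytest.approx(p_o, abs=1e-5)


def test_forward_selection_invariants(rng):
    G, y = _sim_window(rng, n=100, m=21, causal=(10, 14))
    p = single_locus_scan(G, y)
    cfg = ScanConfig()
    regions = build_regions(p, np.arange(1, 22), cfg)
    for region in regions:
        trunc = truncate_region(region, p, cfg.truncation_t)
        rr = forward_select(trunc, G, y, cfg)
        assert rr.selected[0] == region.center          # center seeds the model
        assert np.all(np.diff(rr.aic_path) < 0)         # strict AIC decrease
        allowed = set(trunc.surviving.tolist()) | {region.center}
        assert set(rr.selected.tolist()) <= allowed
        assert 0.0 <= rr.model_p <= 1.0


# ------------------------------------------------------------------ full scan


def test_scan_statistic_min_and_empty():
    with pytest.raises(ValueError):
        scan_statistic([])


def test_run_scan_end_to_end(rng):
    G, y = _sim_window(rng, n=120, m=21, causal=(10,), effect=1.3)
    res = run_scan(G, np.arange(1, 22), y, ScanConfig())
    assert res.best_region is not None
    assert res.statistic == min(r.model_p for r in res.regions)
    assert 10 in res.selected


def test_run_scan_no_seeds(rng):
    G = rng.binomial(2, 0.4, size=(60, 9)).astype(np.int8)
    y = np.array([0, 1] * 30, dtype=np.int8)
    # make every single-locus p large by using pure-noise labels repeatedly
    for _ in range(20):
        p = single_locus_scan(G, y)
        if p.min() > 0.05:
            break
        y = np.random.default_rng(int(p[0] * 1e6)).permutation(y)
    else:  # pragma: no cover
        pytest.skip("could not construct an all-null window")
    res = run_scan(G, np.arange(1, 10), y, ScanConfig())
    assert res.best_region is None
    assert res.statistic == 1.0
    assert res.selected.size == 0


def test_write_scan_report(tmp_path, rng):
    G, y = _sim_window(rng, n=100, m=21, causal=(10,), effect=1.2)
    res = run_scan(G, np.arange(1, 22), y, ScanConfig())
    out = tmp_path / "report.tsv"
    write_scan_report(res, str(out))
    text = out.read_text()
    assert text.startswith("center\tmembers\tselected\taic_path\tmodel_p\n")
    assert "#scan_statistic" in text


def test_scan_config_validation():
    with pytest.raises(ValueError):
        ScanConfig(flank=0)
    with pytest.raises(ValueError):
        ScanConfig(truncation_t=0.0)
    with pytest.raises(ValueError):
        ScanConfig(lam=-1.0)
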
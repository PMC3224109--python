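"""Sliding-window scan: regions, truncation, forward selection.

The scan proceeds in four steps.  (1) Single-locus logistic regression
gives a p-value per SNP.  (2) Each seed SNP (top-S smallest p, or all
SNPs below a seed threshold) becomes the center of a search region of
``u`` SNPs on each side, clipped at chromosome boundaries.  (3) SNPs
whose single-locus p-value exceeds the truncation threshold ``t`` are
excluded from the region (the center is exempt: it seeds the model).
(4) Forward selection adds one SNP at a time, refitting the GRLR model
with a distance-proportional penalty at every step and keeping the
addition that lowers the AIC most, until no addition lowers it.  The
scan statistic is the minimum over regions of the model-fitness p-value
P{E_i} of the final model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _fast
from .grlr import PenaltySpec

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Tuning parameters of the scan."""

    flank: int = 10                 # u = v: SNPs on each side of a seed
    truncation_t: float = 0.05      # single-locus p-value cutoff inside a region
    lam: float = 1.0                # penalty scale lambda
    top_s: int | None = None        # seed the top-S SNPs by p-value ...
    seed_threshold: float | None = 0.05  # ... or all SNPs with p <= threshold
    renormalize_penalty: bool = True  # unit trace over in-model SNPs (default)

    def __post_init__(self) -> None:
        if self.flank < 1:
            raise ValueError("flank must be >= 1")
        if not (0.0 < self.truncation_t <= 1.0):
            raise ValueError("truncation_t must lie in (0, 1]")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class SearchRegion:
    """A window of SNP indices around a center SNP."""

    center: int                      # global SNP index of the seed
    members: np.ndarray              # global indices, contiguous, same chromosome
    positions: np.ndarray            # base-pair positions of the members
    flank_u: int
    flank_v: int
    surviving: np.ndarray | None = None  # truncation survivors (global indices)

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.center not in self.members:
            raise ValueError("center must be a member of the region")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing within a region")

    @property
    def center_local(self) -> int:
        return int(np.flatnonzero(self.members == self.center)[0])


@dataclass
class RegionResult:
    region: SearchRegion
    selected: np.ndarray             # global SNP indices, center first
    model_p: float
    aic_path: list = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.aic_path)


@dataclass
class ScanResult:
    regions: list
    statistic: float
    best_region: RegionResult | None

    @property
    def selected(self) -> np.ndarray:
        if self.best_region is None:
            return np.array([], dtype=int)
        return self.best_region.selected


def single_locus_scan(genotypes, y, missing: int = -1) -> np.ndarray:
    """Per-SNP Wald p-values from one-SNP logistic regressions.

    Missing genotypes (coded ``missing``) are dropped per SNP
    (complete-case within each single-locus fit).  Monomorphic SNPs get
    p = 1.
    """
    G = np.asarray(genotypes)
    y = np.asarray(y, dtype=np.float64)
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("phenotype must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("need at least one case and one control")
    has_missing = np.any(G == missing)
    if not has_missing:
        return _fast.batch_single_locus_pvalues(G, y[None, :])[0]
    pvals = np.ones(G.shape[1])
    for j in range(G.shape[1]):
        col = G[:, j]
        mask = col != missing
        yj = y[mask]
        if yj.size == 0 or yj.min() == yj.max():
            continue
        pvals[j] = _fast.batch_single_locus_pvalues(col[mask, None], yj[None, :])[0, 0]
    return pvals


def build_regions(pvalues, positions, config: ScanConfig, chromosomes=None):
    """Search regions around seed SNPs.

    Seeds are the ``top_s`` SNPs with smallest p-value when
    ``config.top_s`` is set, otherwise all SNPs with
    ``p <= config.seed_threshold``.  Each region spans ``flank`` SNPs on
    both sides of its seed, clipped at chromosome boundaries (a region
    never crosses a chromosome break).  An empty seed set yields an
    empty list.
    """
    pvalues = np.asarray(pvalues, dtype=np.float64)
    positions = np.asarray(positions, dtype=np.float64)
    n = pvalues.shape[0]
    if chromosomes is None:
        chromosomes = np.zeros(n, dtype=int)
    chromosomes = np.asarray(chromosomes)

    if config.top_s is not None:
        seeds = np.argsort(pvalues, kind="stable")[: config.top_s]
    elif config.seed_threshold is not None:
        seeds = np.flatnonzero(pvalues <= config.seed_threshold)
    else:
        raise ValueError("ScanConfig needs top_s or seed_threshold to pick seeds")

    regions = []
    for s in np.sort(seeds):
        chrom = chromosomes[s]
        same = np.flatnonzero(chromosomes == chrom)
        lo_bound, hi_bound = same[0], same[-1]
        lo = max(lo_bound, s - config.flank)
        hi = min(hi_bound, s + config.flank)
        members = np.arange(lo, hi + 1)
        regions.append(
            SearchRegion(
                center=int(s),
                members=members,
                positions=positions[members],
                flank_u=int(s - lo),
                flank_v=int(hi - s),
            )
        )
    return regions


def build_penalty(region: SearchRegion, lam: float = 1.0) -> PenaltySpec:
    """Distance-proportional diagonal penalty over the region's members.

    Entry j is ``|D_j - D_center| / sum_k |D_k - D_center|``; the center
    gets 0 and the trace is 1 (a single-member region gets the 1x1 zero
    matrix).
    """
    members_local = np.arange(len(region.members))
    w = _fast.penalty_weights(region.positions, region.center_local, members_local)
    return PenaltySpec(w, lam)


def truncate_region(region: SearchRegion, pvalues, t: float) -> SearchRegion:
    """Drop members whose single-locus p-value exceeds ``t``.

    The center SNP survives unconditionally: it seeds the model before
    any candidate is considered.
    """
    if not (0.0 < t <= 1.0):
        raise ValueError("truncation threshold must lie in (0, 1]")
    pvalues = np.asarray(pvalues, dtype=np.float64)
    keep = pvalues[region.members] <= t
    keep[region.center_local] = True
    return SearchRegion(
        center=region.center,
        members=region.members,
        positions=region.positions,
        flank_u=region.flank_u,
        flank_v=region.flank_v,
        surviving=region.members[keep],
    )


def forward_select(region: SearchRegion, genotypes, y, config: ScanConfig) -> RegionResult:
    """Greedy forward selection in one region, GRLR at each step.

    Starts from the center SNP, then repeatedly adds the surviving SNP
    whose addition lowers the AIC the most; stops when no addition gives
    a strict decrease (tolerance 1e-9).  Candidates whose GRLR fit fails
    to converge are skipped with a warning.
    """
    G = np.asarray(genotypes, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    surviving = region.surviving if region.surviving is not None else region.members
    surv_mask = np.isin(region.members, surviving)
    surv_mask[region.center_local] = True
    selected_local, aic_path, model_p, n_skipped = _fast.forward_select_lean(
        G[:, region.members],
        y,
        region.center_local,
        region.positions,
        surv_mask,
        config.lam,
        renormalize=config.renormalize_penalty,
    )
    if n_skipped:
        logger.warning(
            "region centered at SNP %d: %d non-converged candidate fits skipped",
            region.center,
            n_skipped,
        )
    return RegionResult(
        region=region,
        selected=region.members[np.asarray(selected_local)],
        model_p=model_p,
        aic_path=aic_path,
    )


def scan_statistic(region_results) -> tuple[float, RegionResult]:
    """Minimum model-fitness p-value over regions, with its argmin."""
    if not region_results:
        raise ValueError("scan statistic undefined for an empty region list")
    best = min(region_results, key=lambda r: r.model_p)
    return best.model_p, best


def run_scan(genotypes, positions, y, config: ScanConfig, chromosomes=None) -> ScanResult:
    """Full pipeline: single-locus scan, seeding, truncation, forward
    selection, min-over-regions statistic.

    Returns a ScanResult with ``statistic = 1.0`` and no best region
    when no SNP qualifies as a seed.
    """
    pvals = single_locus_scan(genotypes, y)
    regions = build_regions(pvals, positions, config, chromosomes=chromosomes)
    results = []
    for region in regions:
        trunc = truncate_region(region, pvals, config.truncation_t)
        results.append(forward_select(trunc, genotypes, y, config))
    if not results:
        return ScanResult(regions=[], statistic=1.0, best_region=None)
    stat, best = scan_statistic(results)
    return ScanResult(regions=results, statistic=stat, best_region=best)


def write_scan_report(result: ScanResult, path: str, snp_ids=None) -> None:
    """Region-per-row TSV report plus a summary row with the scan statistic."""
    def _name(j):
        return snp_ids[j] if snp_ids is not None else f"snp{j + 1}"

    with open(path, "w") as fh:
        fh.write("center\tmembers\tselected\taic_path\tmodel_p\n")
        for rr in result.regions:
            fh.write(
                "{}\t{}\t{}\t{}\t{:.6g}\n".format(
                    _name(rr.region.center),
                    ",".join(_name(j) for j in rr.region.members),
                    ",".join(_name(j) for j in rr.selected),
                    ",".join(f"{a:.4f}" for a in rr.aic_path),
                    rr.model_p,
                )
            )
        sel = ",".join(_name(j) for j in result.selected)
        fh.write(f"#scan_statistic\t{result.statistic:.6g}\tselected={sel}\n")
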
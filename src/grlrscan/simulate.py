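"""Case-control genotype simulator.

One replication generates a susceptibility window of ``n_snps`` markers.
Latent liabilities come from a multivariate normal with unit variances
and a banded correlation (``r`` for index distance 1..5, zero beyond);
each latent value is cut at the Hardy-Weinberg thresholds
``qnorm((1-f)^2)`` and ``qnorm(1-f^2)`` to give additive genotype codes
0/1/2, so marginal genotype frequencies are ``(1-f)^2, 2f(1-f), f^2``.
Disease status is Bernoulli with

    logit P(y=1) = beta_0 + sum_j beta_j x_j  over the causal SNPs,

where ``beta_0`` is calibrated so the population prevalence equals the
target (0.05 by default).  Individuals are drawn from the population and
kept by rejection sampling until the case and control quotas are filled.

One causal SNP always sits at the center of the window; the remaining
causal SNPs are placed uniformly at random among the other indices.  The
base-pair position of the b-th SNP is b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

BAND_WIDTH = 5  # latent correlation extends over index distance 1..5


class SimulationError(RuntimeError):
    """Invalid simulation configuration or failed calibration."""


@dataclass
class SimConfig:
    """Parameters of one simulation condition."""

    n_snps: int = 21
    n_causal: int = 2
    maf: float = 0.5
    corr: float = 0.0
    n_cases: int = 50
    n_controls: int = 50
    prevalence: float = 0.05
    effect_sizes: np.ndarray | None = None  # default: all 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_causal > self.n_snps:
            raise SimulationError("n_causal must not exceed n_snps")
        if not (0.0 < self.maf <= 0.5):
            raise SimulationError("maf must lie in (0, 0.5]")
        if not (0.0 < self.prevalence < 1.0):
            raise SimulationError("prevalence must lie in (0, 1)")
        if not (0.0 <= self.corr < 1.0):
            raise SimulationError("corr must lie in [0, 1)")
        if self.effect_sizes is None:
            self.effect_sizes = np.ones(self.n_causal)
        else:
            self.effect_sizes = np.asarray(self.effect_sizes, dtype=np.float64)
            if self.effect_sizes.shape[0] != self.n_causal:
                raise SimulationError("effect_sizes length must equal n_causal")

    @property
    def center_index(self) -> int:
        """0-based index of the window's center SNP."""
        return self.n_snps // 2


@dataclass
class SimulatedDataset:
    genotypes: np.ndarray          # (n, n_snps) int8, codes 0/1/2
    phenotypes: np.ndarray         # (n,) int8, 1 = case
    causal_indices: np.ndarray     # ordered, center first
    intercept_used: float
    positions: np.ndarray          # base pairs; position of SNP b is b
    config: SimConfig = field(repr=False, default=None)


def build_covariance(n_snps: int, corr: float, band: int = BAND_WIDTH) -> np.ndarray:
    """Banded latent correlation matrix: 1 on the diagonal, ``corr`` for
    index distance 1..band, 0 beyond.

    Raises if the matrix is not positive semi-definite (smallest
    eigenvalue below -1e-10), which happens for large ``corr``.
    """
    if n_snps < 1:
        raise SimulationError("n_snps must be >= 1")
    if not (0.0 <= corr < 1.0):
        raise SimulationError("corr must lie in [0, 1)")
    idx = np.arange(n_snps)
    dist = np.abs(idx[:, None] - idx[None, :])
    sigma = np.where(dist == 0, 1.0, np.where(dist <= band, corr, 0.0))
    if corr > 0.0 and np.linalg.eigvalsh(sigma).min() < -1e-10:
        raise SimulationError(
            f"banded correlation {corr} is indefinite for n_snps={n_snps}"
        )
    return sigma


def genotype_thresholds(maf: float) -> tuple[float, float]:
    """Latent cutpoints: below the first -> AA (0), above the second -> BB (2)."""
    return float(norm.ppf((1.0 - maf) ** 2)), float(norm.ppf(1.0 - maf**2))


def latent_to_genotype(z, maf: float):
    """Map latent N(0,1) values to genotype codes via the HWE thresholds."""
    lo, hi = genotype_thresholds(maf)
    z = np.asarray(z, dtype=np.float64)
    g = np.ones(z.shape, dtype=np.int8)
    g[z < lo] = 0
    g[z > hi] = 2
    if g.ndim == 0:
        return int(g)
    return g


def _causal_cov(causal: np.ndarray, corr: float) -> np.ndarray:
    dist = np.abs(causal[:, None] - causal[None, :])
    return np.where(dist == 0, 1.0, np.where(dist <= BAND_WIDTH, corr, 0.0))


def _genotype_pmf(maf: float) -> np.ndarray:
    return np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])


def _exact_score_distribution(maf: float, betas: np.ndarray):
    """Distribution of sum_j beta_j x_j for independent HWE genotypes."""
    pmf = _genotype_pmf(maf)
    values = np.array([0.0])
    probs = np.array([1.0])
    for b in betas:
        values = (values[:, None] + b * np.array([0.0, 1.0, 2.0])[None, :]).ravel()
        probs = (probs[:, None] * pmf[None, :]).ravel()
    return values, probs


def calibrate_intercept(
    config: SimConfig,
    causal_indices: np.ndarray | None = None,
    n_draws: int = 200_000,
    rng: np.random.Generator | None = None,
    tol: float = 1e-6,
) -> float:
    """Intercept beta_0 giving the target population prevalence.

    For independent causal genotypes (``corr == 0`` or a single causal
    SNP, or causal SNPs all further than the correlation band apart) the
    prevalence is computed by exact enumeration over the joint genotype
    distribution; otherwise by Monte Carlo over ``n_draws`` draws of the
    correlated causal genotypes.  The root is found by bracketing
    bisection (Brent), exploiting monotonicity of prevalence in beta_0.
    """
    betas = config.effect_sizes
    k = config.n_causal
    if k == 0 or np.all(betas == 0.0):
        return float(math.log(config.prevalence / (1.0 - config.prevalence)))

    if causal_indices is None:
        causal_indices = np.arange(k)
    causal_indices = np.asarray(causal_indices)
    cov = _causal_cov(causal_indices, config.corr)
    independent = np.allclose(cov, np.eye(k))

    if independent:
        values, probs = _exact_score_distribution(config.maf, betas)

        def prevalence(b0: float) -> float:
            return float(np.sum(probs * expit(b0 + values)))

    else:
        if rng is None:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [0 if config.seed is None else int(config.seed), 7021]
                )
            )
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
        z = rng.standard_normal((n_draws, k)) @ chol.T
        scores = latent_to_genotype(z, config.maf).astype(np.float64) @ betas

        def prevalence(b0: float) -> float:
            return float(np.mean(expit(b0 + scores)))

    try:
        b0 = brentq(lambda b: prevalence(b) - config.prevalence, -60.0, 20.0, xtol=tol)
    except ValueError as exc:  # pragma: no cover - pathological configs
        raise SimulationError(f"intercept calibration failed: {exc}") from exc
    return float(b0)


def _causal_layout(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Center SNP first, remaining causal SNPs uniform among the others."""
    center = config.center_index
    others = np.delete(np.arange(config.n_snps), center)
    extra = rng.choice(others, size=config.n_causal - 1, replace=False)
    return np.concatenate(([center], np.sort(extra))).astype(np.int64)


def _correlation_pattern(causal: np.ndarray) -> tuple:
    """Which causal pairs fall inside the latent correlation band.

    The calibrated intercept depends on the causal layout only through
    this pattern, so it keys the calibration cache.
    """
    k = len(causal)
    return tuple(
        int(abs(causal[i] - causal[j]) <= BAND_WIDTH)
        for i in range(k)
        for j in range(i + 1, k)
    )


def simulate_dataset(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    calibration_cache: dict | None = None,
    batch_size: int = 2000,
    max_batches: int = 5000,
) -> SimulatedDataset:
    """Draw one case-control dataset under the configured disease model.

    Population individuals are generated in batches and assigned to the
    case or control pool by Bernoulli disease status until both quotas
    (``n_cases``, ``n_controls``) are exactly filled.  The per-layout
    calibrated intercept may be shared across replications through
    ``calibration_cache`` (keyed by MAF, correlation pattern and effect
    sizes).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    causal = _causal_layout(config, rng)

    key = (
        config.n_causal,
        round(config.maf, 12),
        round(config.corr, 12),
        tuple(np.round(config.effect_sizes, 12)),
        round(config.prevalence, 12),
        # at zero latent correlation the layout pattern cannot affect the
        # calibrated intercept, so all layouts share one cache entry
        _correlation_pattern(causal) if config.corr != 0.0 else (),
    )
    if calibration_cache is not None and key in calibration_cache:
        beta0 = calibration_cache[key]
    else:
        beta0 = calibrate_intercept(config, causal_indices=causal)
        if calibration_cache is not None:
            calibration_cache[key] = beta0

    sigma = build_covariance(config.n_snps, config.corr)
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(config.n_snps))
    betas = config.effect_sizes

    cases, controls = [], []
    n_case_needed, n_ctrl_needed = config.n_cases, config.n_controls
    for _ in range(max_batches):
        z = rng.standard_normal((batch_size, config.n_snps)) @ chol.T
        g = latent_to_genotype(z, config.maf)
        risk = expit(beta0 + g[:, causal].astype(np.float64) @ betas)
        affected = rng.random(batch_size) < risk
        if len(cases) < n_case_needed:
            cases.extend(g[affected])
        if len(controls) < n_ctrl_needed:
            controls.extend(g[~affected])
        if len(cases) >= n_case_needed and len(controls) >= n_ctrl_needed:
            break
    else:  # pragma: no cover
        raise SimulationError(
            "rejection sampling did not fill the case quota; "
            "intercept appears mis-calibrated"
        )

    geno = np.vstack([cases[:n_case_needed], controls[:n_ctrl_needed]]).astype(np.int8)
    pheno = np.concatenate(
        [np.ones(n_case_needed, dtype=np.int8), np.zeros(n_ctrl_needed, dtype=np.int8)]
    )
    return SimulatedDataset(
        genotypes=geno,
        phenotypes=pheno,
        causal_indices=causal,
        intercept_used=beta0,
        positions=np.arange(1, config.n_snps + 1),
        config=config,
    )


def write_plink_text(dataset: SimulatedDataset, prefix: str, chromosome: int = 1) -> None:
    """Write a dataset as a PLINK text .ped/.map pair.

    Genotype 0/1/2 becomes A A / A B / B B with B the minor allele;
    phenotype uses the PLINK convention 2 = affected, 1 = unaffected.
    """
    n, m = dataset.genotypes.shape
    allele_pairs = {0: "A A", 1: "A B", 2: "B B"}
    with open(prefix + ".ped", "w") as fh:
        for i in range(n):
            pheno = 2 if dataset.phenotypes[i] == 1 else 1
            row = [f"F{i + 1}", f"I{i + 1}", "0", "0", "0", str(pheno)]
            row.extend(allele_pairs[int(g)] for g in dataset.genotypes[i])
            fh.write("\t".join(row) + "\n")
    with open(prefix + ".map", "w") as fh:
        for j in range(m):
            fh.write(f"{chromosome}\tsnp{j + 1}\t0\t{int(dataset.positions[j])}\n")


def write_genotype_tsv(dataset: SimulatedDataset, geno_path: str, pheno_path: str) -> None:
    """Write a plain TSV genotype matrix (individuals x SNPs) plus a
    phenotype file (one 0/1 label per line)."""
    header = "\t".join(f"snp{j + 1}" for j in range(dataset.genotypes.shape[1]))
    with open(geno_path, "w") as fh:
        fh.write(header + "\n")
        for row in dataset.genotypes:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")
    with open(pheno_path, "w") as fh:
        for v in dataset.phenotypes:
            fh.write(f"{int(v)}\n")
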
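"""Permutation-based global p-values.

Significance of a scan (or competitor) statistic is judged against its
distribution under random case-control label switching: the genotype
matrix stays fixed, the labels are shuffled L times (preserving case and
control counts), and the entire statistic pipeline re-runs on each
shuffle -- including seeding and truncation, which are re-derived under
the permuted labels.

The empirical p-value defaults to ``#{perm stat as or more extreme}/L``,
which can equal 0 exactly; the strictly valid ``(count+1)/(L+1)``
estimator is available via ``estimator="add-one"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PermutationResult:
    observed_stat: float
    perm_stats: np.ndarray
    empirical_p: float
    n_perms: int
    seed: int | None = None


def empirical_pvalue(
    observed: float, perm_stats: np.ndarray, estimator: str = "count"
) -> float:
    """Fraction of permutation statistics as or more extreme (smaller or
    equal) than the observed one."""
    perm_stats = np.asarray(perm_stats, dtype=np.float64)
    count = int(np.sum(perm_stats <= observed))
    if estimator == "count":
        return count / perm_stats.size
    if estimator == "add-one":
        return (count + 1) / (perm_stats.size + 1)
    raise ValueError(f"unknown estimator {estimator!r}")


def permute_labels(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One random switch of the case-control labels (counts preserved)."""
    return rng.permutation(y)


def permute_and_rescan(
    genotypes,
    y,
    statistic_fn,
    n_perms: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    estimator: str = "count",
    no_region_sentinel: float = 1.0,
) -> PermutationResult:
    """Global empirical p-value for ``statistic_fn`` by label permutation.

    ``statistic_fn(genotypes, labels)`` must run the full pipeline from
    scratch for the given labels and return a scalar for which smaller
    values are more extreme (a p-value-type statistic or a sum of log
    p-values).  A pipeline that finds no seed regions should return
    ``None``; such permutations contribute the non-significant sentinel
    statistic (1.0 for p-value statistics).
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    y = np.asarray(y)

    def _eval(labels):
        stat = statistic_fn(genotypes, labels)
        return no_region_sentinel if stat is None else float(stat)

    observed = _eval(y)
    perm_stats = np.empty(n_perms)
    for b in range(n_perms):
        perm_stats[b] = _eval(permute_labels(y, rng))
    return PermutationResult(
        observed_stat=observed,
        perm_stats=perm_stats,
        empirical_p=empirical_pvalue(observed, perm_stats, estimator),
        n_perms=n_perms,
        seed=seed,
    )


def zero_count_ci_upper(n_perms: int, confidence: float = 0.95) -> float:
    """One-sided upper confidence bound for a proportion with zero
    successes in ``n_perms`` trials: ``1 - (1 - confidence)^(1/L)``.

    With L = 1000 permutations and an empirical p-value of 0, the 95%
    interval for the true p extends from 0 to 0.003.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    return 1.0 - (1.0 - confidence) ** (1.0 / n_perms)
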
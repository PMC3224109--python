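"""Comparison methods for the power study.

Three single-locus-p-value based statistics, each calibrated by the same
case-control label permutation machinery as the GRLR scan:

* minP — the smallest single-locus p-value;
* FPM (Fisher product method) — slide a fixed-size window across the
  region, sum log p within each window, take the minimum over windows;
* TPM (truncated product method) — like FPM but only p-values at or
  below a truncation threshold enter the sum (an empty qualifying set
  contributes 0, the log of a product of no terms).

For all three, smaller statistics are more extreme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_TINY_P = 1e-300  # p = 0 is clamped here before taking logs


@dataclass
class WindowStatConfig:
    window_size: int = 5
    tpm_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (0.0 < self.tpm_threshold <= 1.0):
            raise ValueError("tpm_threshold must lie in (0, 1]")


def minp_statistic(pvalues) -> float:
    """Smallest single-locus p-value."""
    pvalues = np.asarray(pvalues, dtype=np.float64)
    if pvalues.size == 0:
        raise ValueError("minp_statistic needs at least one p-value")
    return float(pvalues.min())


def _window_sums(pvalues: np.ndarray, config: WindowStatConfig, truncate: bool):
    p = np.atleast_2d(np.asarray(pvalues, dtype=np.float64))
    if p.shape[1] < config.window_size:
        raise ValueError("need at least window_size p-values")
    logs = np.log(np.clip(p, _TINY_P, 1.0))
    if truncate:
        logs = np.where(p <= config.tpm_threshold, logs, 0.0)
    return sliding_window_view(logs, config.window_size, axis=1).sum(axis=-1)


def fpm_statistic(pvalues, config: WindowStatConfig | None = None) -> float:
    """Minimum over sliding windows of the sum of log p-values."""
    config = config or WindowStatConfig()
    return float(_window_sums(pvalues, config, truncate=False).min())


def tpm_statistic(pvalues, config: WindowStatConfig | None = None) -> float:
    """FPM restricted to p-values at or below the truncation threshold."""
    config = config or WindowStatConfig()
    return float(_window_sums(pvalues, config, truncate=True).min())


def window_statistics_rows(pvalue_rows, config: WindowStatConfig, truncate: bool):
    """Batched window statistics for many p-value vectors at once.

    Returns ``(stats, argmin_start)`` where ``stats[b]`` is the min
    window sum of row b and ``argmin_start[b]`` the 0-based start index
    of the winning window.  Used by the replication engine, where the
    rows are the observed labels plus permutations.
    """
    sums = _window_sums(pvalue_rows, config, truncate)
    return sums.min(axis=1), sums.argmin(axis=1)
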
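"""Multiple-testing correction for correlated methylation bins.

Overlapping 500 bp bins at 250 bp step are strongly locally correlated, so
the Bonferroni denominator should be the *effective* number of independent
tests, not the raw bin count. The effective count follows the
eigenvalue-counting rule of Li & Ji (2005): for a correlation matrix with
eigenvalues λ, each eigenvalue contributes

    f(λ) = 1{λ >= 1} + (λ − floor(λ)),

so a block of perfectly correlated bins counts once and uncorrelated bins
count fully. For tractability at epigenome scale the bin set is split into
contiguous genomic blocks per chromosome (long-range and inter-chromosome
methylation correlation treated as negligible) and block contributions are
summed.

FDR under dependency uses the Benjamini–Yekutieli step-up (delegated to
statsmodels), valid under arbitrary dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = ["MeffResult", "li_ji_meff", "effective_tests", "genomewide_threshold",
           "fdr_dependency"]


@dataclass
class MeffResult:
    """Effective number of independent tests and the implied threshold."""

    block_meff: list[float]
    total_meff: float
    alpha: float
    block_size: int
    n_bins: int
    n_dropped: int
    per_chrom: dict[str, float] = field(default_factory=dict)

    @property
    def threshold(self) -> float:
        return self.alpha / self.total_meff


def li_ji_meff(values: np.ndarray) -> float:
    """Li–Ji effective test count for one dense block of bin values.

    ``values``: (n_samples, n_bins) array; bins must have positive variance.
    Eigenvalues of the bin correlation matrix are clamped at 0 (numerical
    dust) and counted as 1{|λ| >= 1} + fractional part of |λ|.
    """
    n_bins = values.shape[1]
    if n_bins == 1:
        return 1.0
    corr = np.corrcoef(values, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.abs(np.clip(lam, 0.0, None))
    # snap to integers within numerical dust so e.g. an exact rank-1 block
    # (eigenvalue k - O(eps)) does not pick up a spurious fractional part
    eps = 1e-9
    frac = np.clip(lam - np.floor(lam + eps), 0.0, None)
    contrib = (lam >= 1.0 - eps).astype(float) + frac
    return float(contrib.sum())


def effective_tests(
    matrix: pd.DataFrame,
    bins: pd.DataFrame,
    block_size: int = 5000,
    alpha: float = 0.05,
) -> MeffResult:
    """Blockwise Li–Ji effective number of tests over a bin set.

    Bins are ordered by genomic coordinate; blocks are contiguous coordinate
    ranges and never span chromosomes. Zero-variance bins are dropped with a
    warning (they carry no test).
    """
    if matrix.shape[1] < 2:
        raise InputError("need at least 2 bins")
    if block_size < 1:
        raise InputError("block_size must be >= 1")
    order = bins.loc[matrix.columns].sort_values(["chrom", "start"]).index
    values = matrix.loc[:, order].to_numpy(dtype=float)
    variances = values.var(axis=0)
    dropped = int((variances == 0).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} zero-variance bins from Meff", stacklevel=2)
    keep = variances > 0
    values = values[:, keep]
    chroms = bins.loc[order, "chrom"].to_numpy()[keep]

    block_meff: list[float] = []
    per_chrom: dict[str, float] = {}
    for chrom in pd.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        total_c = 0.0
        for lo in range(0, len(idx), block_size):
            block = values[:, idx[lo : lo + block_size]]
            m = li_ji_meff(block)
            block_meff.append(m)
            total_c += m
        per_chrom[str(chrom)] = total_c
    total = float(sum(block_meff))
    return MeffResult(
        block_meff=block_meff,
        total_meff=total,
        alpha=alpha,
        block_size=block_size,
        n_bins=int(keep.sum()),
        n_dropped=dropped,
        per_chrom=per_chrom,
    )


def genomewide_threshold(meff: MeffResult) -> float:
    """Per-test significance level alpha / Meff (epigenome-wide threshold)."""
    if meff.total_meff < 1:
        raise InputError("total Meff must be >= 1")
    return meff.alpha / meff.total_meff


def fdr_dependency(pvalues) -> np.ndarray:
    """Benjamini–Yekutieli q-values (FDR under arbitrary dependency).

    Output order matches input order; q-values are capped at 1 and are never
    below the raw p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_by")
    return q
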
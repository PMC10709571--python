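"""Low-expression filtering and TMM normalization.

TMM (trimmed mean of M-values) computes, for each library against a reference
library, per-gene log-ratios M and average log-abundances A over genes
expressed in both, doubly trims them (30% on M, 5% on A by default), and
takes a precision-weighted mean of the surviving M values.  The resulting
scaling factor times the raw library size is the effective library size
``N_i`` used as the GLM offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_design import CountTable, StackedCounts

__all__ = ["NormFactors", "filter_low_expression", "tmm_factors"]

#: minimum genes that must survive trimming before falling back to factor 1
MIN_TRIMMED_GENES = 10


@dataclass
class NormFactors:
    """Per-column library sizes, TMM factors and effective sizes.

    TMM factors are rescaled so that their geometric mean is exactly 1;
    ``effective_size = lib_size * tmm_factor``.
    """

    column_ids: list[str]
    lib_sizes: np.ndarray
    tmm_factors: np.ndarray

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.tmm_factors

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "column_id": self.column_ids,
            "lib_size": self.lib_sizes.astype(np.int64),
            "tmm_factor": self.tmm_factors,
            "effective_size": self.effective_sizes,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_low_expression(counts: CountTable | StackedCounts,
                          min_count: int = 5,
                          max_low_fraction: float = 0.30):
    """Drop genes expressed below *min_count* in too many columns.

    A gene is dropped iff the fraction of columns with count < ``min_count``
    is strictly greater than ``max_low_fraction`` (a gene low in exactly 30%
    of the columns is kept).  For stacked tables the rule is applied over all
    n*k columns jointly.

    Returns ``(filtered, kept_ids, dropped_ids)``; an empty result is a
    warning, not an error.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if not 0.0 <= max_low_fraction <= 1.0:
        raise ValueError("max_low_fraction must be in [0, 1]")
    mat = counts.counts
    low_frac = (mat < min_count).mean(axis=1)
    keep_mask = low_frac <= max_low_fraction
    kept = [g for g, k in zip(counts.gene_ids, keep_mask) if k]
    dropped = [g for g, k in zip(counts.gene_ids, keep_mask) if not k]
    if not kept:
        warnings.warn("all genes dropped by the low-expression filter")
    filtered = counts.select_genes(kept) if kept else _empty_like(counts)
    return filtered, kept, dropped


def _empty_like(counts: CountTable | StackedCounts):
    if isinstance(counts, StackedCounts):
        return StackedCounts([], list(counts.columns),
                             np.empty((0, len(counts.columns)), dtype=np.int64),
                             sep=counts.sep)
    return CountTable([], list(counts.sample_ids),
                      np.empty((0, len(counts.sample_ids)), dtype=np.int64))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Doubly-trimmed weighted mean of M-values for one column vs the reference.

    Genes with a zero count in either column are excluded; weights are the
    inverse asymptotic (delta-method) variances of M.  Returns the log2 factor.
    """
    mask = (obs > 0) & (ref > 0)
    if mask.sum() == 0:
        warnings.warn("no genes shared with reference; TMM factor set to 1")
        return 0.0
    o = obs[mask].astype(float)
    r = ref[mask].astype(float)
    po = o / lib_obs
    pr = r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) variance of M; weights are its inverse
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    w = 1.0 / v
    n = len(M)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(M)
    ra = rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep.sum() < MIN_TRIMMED_GENES:
        warnings.warn(
            f"only {int(keep.sum())} genes survive TMM trimming; factor set to 1"
        )
        return 0.0
    wk = w[keep]
    if not np.any(wk > 0):
        return 0.0
    return float(np.sum(wk * M[keep]) / np.sum(wk))


def tmm_factors(counts: CountTable | StackedCounts | np.ndarray,
                column_ids: list[str] | None = None,
                ref_column: int | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> NormFactors:
    """Compute TMM normalization factors for every column of a count matrix.

    The reference column, when not given, is the one whose 75th percentile of
    library-size-scaled counts is closest to the mean of those percentiles.
    Factors are rescaled to geometric mean 1.
    """
    if isinstance(counts, (CountTable, StackedCounts)):
        mat = counts.counts
        if column_ids is None:
            column_ids = (counts.column_ids if isinstance(counts, StackedCounts)
                          else list(counts.sample_ids))
    else:
        mat = np.asarray(counts)
    if column_ids is None:
        column_ids = [f"col{j}" for j in range(mat.shape[1])]
    lib = mat.sum(axis=0).astype(float)
    if np.any(lib <= 0):
        bad = [column_ids[j] for j in np.flatnonzero(lib <= 0)]
        raise ValueError(f"zero-sum column(s): {bad}")
    if ref_column is None:
        q75 = np.quantile(mat / lib, 0.75, axis=0)
        ref_column = int(np.argmin(np.abs(q75 - q75.mean())))
    log_f = np.array([
        _tmm_pair(mat[:, j], mat[:, ref_column], lib[j], lib[ref_column],
                  trim_m, trim_a)
        for j in range(mat.shape[1])
    ])
    factors = 2.0 ** (log_f - log_f.mean())  # geometric mean exactly 1
    return NormFactors(list(column_ids), mat.sum(axis=0), factors)
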
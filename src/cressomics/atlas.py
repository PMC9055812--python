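"""Tissue expression atlas: TMM normalization, Tau specificity, class bins.

The Tau index summarizes how concentrated a gene's expression is in one
tissue:

    tau = sum_i (1 - x_hat_i) / (n - 1),   x_hat_i = x_i / max_i x_i

over the per-tissue mean normalized expression x_i (log2(x+1)
transformed by default). tau = 0 means uniform expression, tau = 1 a
single expressing tissue. Counts are first normalized between samples
with the trimmed mean of M-values (TMM): per-sample scaling factors are
the weighted mean of gene-wise log ratios against a reference sample
after trimming the 30% most extreme log-ratios (M) and the 5% most
extreme average intensities (A), rescaled to geometric mean 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAU_CLASS_BINS = ((0.0, 0.2, "low"), (0.2, 0.8, "intermediate"), (0.8, 1.0, "high"))


@dataclass
class ExpressionMatrix:
    """Gene x sample raw counts with a sample -> tissue grouping."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    sample_tissues: dict[str, str]
    excluded_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.counts < 0).any().any():
            raise ValueError("counts must be non-negative")
        unmapped = set(self.counts.columns) - set(self.sample_tissues)
        if unmapped:
            raise ValueError(f"samples without tissue label: {sorted(unmapped)}")


@dataclass
class TauResult:
    tau: pd.Series  # per-gene tau, NaN = missing
    tissue_means: pd.DataFrame  # genes x tissues mean normalized expression
    classes: pd.Series  # low / intermediate / high / missing


def _quantile_factor(counts: np.ndarray, lib_size: float, p: float = 0.75) -> float:
    return float(np.quantile(counts / lib_size, p))


def tmm_normalize(
    matrix: ExpressionMatrix,
    log_ratio_trim: float = 0.3,
    abs_intensity_trim: float = 0.05,
    do_weighting: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """TMM scaling factors and the normalized count matrix.

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean upper quartile. Factors are rescaled to geometric
    mean 1. Normalized value = count / (library size x factor) x 1e6
    (TMM-normalized counts per million), which makes downstream
    statistics invariant under a global rescaling of all library sizes.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    lib_sizes = counts.sum(axis=0)
    if (lib_sizes == 0).any():
        raise ValueError("all-zero sample")
    f75 = np.array(
        [_quantile_factor(counts[:, j], lib_sizes[j]) for j in range(counts.shape[1])]
    )
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        factors[j] = _tmm_pair(
            counts[:, j],
            counts[:, ref],
            lib_sizes[j],
            lib_sizes[ref],
            log_ratio_trim,
            abs_intensity_trim,
            do_weighting,
        )
    factors /= np.exp(np.mean(np.log(factors)))
    norm = counts / (lib_sizes * factors) * 1e6
    return (
        pd.Series(factors, index=matrix.counts.columns, name="tmm_factor"),
        pd.DataFrame(norm, index=matrix.counts.index, columns=matrix.counts.columns),
    )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    log_ratio_trim: float,
    abs_intensity_trim: float,
    do_weighting: bool,
) -> float:
    """Trimmed, precision-weighted mean of M-values of obs against ref."""
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic binomial precision weights (delta method)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if len(m) == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:  # identical (up to scaling) libraries
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * log_ratio_trim) + 1, n - np.floor(n * log_ratio_trim)
    lo_a, hi_a = (
        np.floor(n * abs_intensity_trim) + 1,
        n - np.floor(n * abs_intensity_trim),
    )
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    if do_weighting:
        f = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
    else:
        f = float(np.nanmean(m[keep]))
    if not np.isfinite(f):
        f = 0.0
    return float(2**f)


def tau_specificity(
    normalized: pd.DataFrame,
    sample_tissues: dict[str, str],
    excluded_samples: list[str] | None = None,
    log_transform: bool = True,
) -> TauResult:
    """Per-gene Tau from a normalized count matrix.

    Excluded samples are dropped before per-tissue averaging; genes with
    zero maximal expression are reported as missing rather than 0.
    """
    excluded = set(excluded_samples or [])
    kept = [c for c in normalized.columns if c not in excluded]
    tissues = sorted({sample_tissues[c] for c in kept})
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues after exclusion")
    means = pd.DataFrame(
        {
            t: normalized[[c for c in kept if sample_tissues[c] == t]].mean(axis=1)
            for t in tissues
        }
    )
    x = np.log2(means + 1.0) if log_transform else means.copy()
    xmax = x.max(axis=1)
    missing = (xmax <= 0) | x.isna().any(axis=1)
    xhat = x.div(xmax, axis=0)
    n = len(tissues)
    tau = (1.0 - xhat).sum(axis=1) / (n - 1)
    tau[missing] = np.nan
    classes = classify_tau(tau)
    return TauResult(
        tau=tau.rename("tau"), tissue_means=means, classes=classes
    )


def classify_tau(tau: pd.Series) -> pd.Series:
    """Specificity classes: [0,0.2) low, [0.2,0.8) intermediate, [0.8,1] high."""
    cls = pd.Series("missing", index=tau.index, name="class")
    for lo, hi, name in TAU_CLASS_BINS:
        if hi == 1.0:
            m = (tau >= lo) & (tau <= hi)
        else:
            m = (tau >= lo) & (tau < hi)
        cls[m.fillna(False)] = name
    return cls


def atlas_summary(
    result: TauResult, k: int = 30, high_threshold: float = 0.8
) -> tuple[pd.Series, dict[str, pd.DataFrame]]:
    """Class counts and the top-k most expressed high-specificity genes.

    Per tissue: among genes with tau >= ``high_threshold``, take the k
    with the highest mean expression in that tissue and report their
    log2 expression relative to the per-gene cross-tissue mean.
    """
    class_counts = result.classes.value_counts()
    top: dict[str, pd.DataFrame] = {}
    high = result.tau >= high_threshold
    log_expr = np.log2(result.tissue_means + 1.0)
    rel = log_expr.sub(log_expr.mean(axis=1), axis=0)
    for tissue in result.tissue_means.columns:
        qual = result.tissue_means.loc[high.fillna(False), tissue].sort_values(
            ascending=False
        )
        if len(qual) < k:
            logger.info(
                "tissue %s: only %d genes with tau >= %.2f", tissue, len(qual), high_threshold
            )
        ids = qual.index[:k]
        top[tissue] = pd.DataFrame(
            {
                "gene": ids,
                "expression": qual.loc[ids].to_numpy(),
                "relative_log2": rel.loc[ids, tissue].to_numpy(),
                "tau": result.tau.loc[ids].to_numpy(),
            }
        )
    return class_counts, top
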
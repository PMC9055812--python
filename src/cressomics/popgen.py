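"""Population-genetic summaries: variant classes under a QD filter and
sliding-window linkage-disequilibrium decay.

LD is computed as the squared Pearson correlation (r^2) of genotype
dosages between marker pairs within a sliding window of marker indices
(composite LD; with highly selfing, inbred accessions this is nearly
equivalent to haplotype r^2). Decay is summarized by a LOESS fit of r^2
on physical distance and the smallest distance at which the fitted curve
first reaches r^2 <= 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

VARIANT_CLASSES = ("SNP", "insertion", "deletion")


@dataclass
class VariantTable:
    """Variant records: scaffold, position, class, qd, effect, exonic."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.records["class"].unique()) - set(VARIANT_CLASSES)
        if bad:
            raise ValueError(f"unknown variant classes: {sorted(bad)}")
        if "qd" in self.records and (self.records["qd"].dropna() < 0).any():
            raise ValueError("QD must be non-negative")


@dataclass
class GenotypeMatrix:
    """Markers x samples dosage matrix (0/1/2, NaN = missing)."""

    positions: pd.DataFrame  # scaffold, position; strictly increasing per scaffold
    dosages: np.ndarray  # shape (n_markers, n_samples)
    samples: list[str]

    def __post_init__(self) -> None:
        self.positions = self.positions.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.positions), len(self.samples)):
            raise ValueError("dosage matrix shape mismatch")
        for _, grp in self.positions.groupby("scaffold"):
            pos = grp["position"].to_numpy()
            if (np.diff(pos) <= 0).any():
                raise ValueError("positions must be strictly increasing per scaffold")


def _round_half_even(x: float, decimals: int = 1) -> float:
    return float(np.round(x, decimals))


def variant_class_summary(
    table: VariantTable, min_qd: float = 2000.0
) -> dict[str, object]:
    """Counts and one-decimal percentages per variant class after QD filter.

    Records with a QD below ``min_qd`` are removed (records without a QD
    value are kept). Also breaks exonic records down by effect label.
    """
    r = table.records
    if "qd" in r.columns:
        keep = r["qd"].isna() | (r["qd"] >= min_qd)
        if not keep.all():  # avoid copying large tables that pass wholesale
            r = r[keep]
    total = len(r)
    if total == 0:
        raise ValueError("no variants left after QD filter")
    tally = r["class"].value_counts()
    counts = {cls: int(tally.get(cls, 0)) for cls in VARIANT_CLASSES}
    pct = {cls: _round_half_even(100.0 * n / total) for cls, n in counts.items()}
    out: dict[str, object] = {"total": total, "counts": counts, "percent": pct}
    if "exonic" in r.columns:
        ex = r[r["exonic"].fillna(False).astype(bool)]
        out["exonic_total"] = len(ex)
        if "effect" in r.columns:
            out["exonic_effects"] = ex["effect"].value_counts().to_dict()
    return out


def pairwise_r2(matrix: GenotypeMatrix, window_markers: int = 40) -> pd.DataFrame:
    """r^2 for every same-scaffold marker pair within the index window.

    Returns a frame with columns ``distance`` (bp) and ``r2``. Pairs with
    fewer than 2 complete samples and monomorphic markers are skipped.
    """
    if len(matrix.positions) < 2:
        raise ValueError("need at least 2 markers")
    rows_d: list[np.ndarray] = []
    rows_r: list[np.ndarray] = []
    for scaffold, grp in matrix.positions.groupby("scaffold", sort=True):
        idx = grp.index.to_numpy()
        pos = grp["position"].to_numpy()
        dos = matrix.dosages[idx]
        n = len(idx)
        for lag in range(1, min(window_markers, n - 1) + 1):
            a = dos[:-lag]
            b = dos[lag:]
            ok = np.isfinite(a) & np.isfinite(b)
            n_ok = ok.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                am = np.where(ok, a, 0.0)
                bm = np.where(ok, b, 0.0)
                sa = am.sum(axis=1)
                sb = bm.sum(axis=1)
                saa = (am * am).sum(axis=1)
                sbb = (bm * bm).sum(axis=1)
                sab = (am * bm).sum(axis=1)
                cov = sab - sa * sb / n_ok
                va = saa - sa * sa / n_ok
                vb = sbb - sb * sb / n_ok
                r2 = cov * cov / (va * vb)
            valid = (n_ok >= 2) & (va > 0) & (vb > 0)
            rows_d.append((pos[lag:] - pos[:-lag])[valid])
            rows_r.append(r2[valid])
    return pd.DataFrame(
        {"distance": np.concatenate(rows_d), "r2": np.concatenate(rows_r)}
    )


@dataclass
class LdDecayResult:
    grid: np.ndarray
    fitted: np.ndarray
    crossing_bp: float | None  # None when the curve never reaches the threshold
    curve_minimum: float
    threshold: float


def ld_decay_distance(
    pairs: pd.DataFrame,
    threshold: float = 0.2,
    loess_span: float = 0.3,
    grid_points: int = 400,
) -> LdDecayResult:
    """LOESS fit of r^2 vs distance and the threshold crossing distance.

    The crossing is the smallest grid distance where the fitted curve
    first reaches <= ``threshold`` (linear interpolation between grid
    points). If the whole fitted curve starts at or below the threshold,
    the smallest observed distance is returned; if it never reaches the
    threshold, ``crossing_bp`` is None and the curve minimum is reported.
    """
    if len(pairs) < 50:
        raise ValueError("need at least 50 pairs to fit a decay curve")
    d = pairs["distance"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    fit = lowess(r2, d, frac=loess_span, return_sorted=True)
    grid = np.linspace(d.min(), d.max(), grid_points)
    fitted = np.interp(grid, fit[:, 0], fit[:, 1])
    below = fitted <= threshold
    if not below.any():
        return LdDecayResult(grid, fitted, None, float(fitted.min()), threshold)
    i = int(np.argmax(below))
    if i == 0:
        crossing = float(grid[0])
    else:
        x0, x1 = grid[i - 1], grid[i]
        y0, y1 = fitted[i - 1], fitted[i]
        crossing = float(x0 + (y0 - threshold) / (y0 - y1) * (x1 - x0))
    return LdDecayResult(grid, fitted, crossing, float(fitted.min()), threshold)


def ld_decay_scale(pairs: pd.DataFrame, n_bins: int = 30) -> float:
    """Exponential decay scale of r^2 with distance.

    Bins pairs by distance quantiles and fits ``a * exp(-d/s) + c`` to
    the bin means (the additive floor c absorbs the finite-sample upward
    bias of r^2 estimates). Returns the scale s in bp.
    """
    from scipy.optimize import curve_fit

    d = pairs["distance"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    edges = np.unique(np.quantile(d, np.linspace(0, 1, n_bins + 1)))
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (d >= lo) & (d < hi)
        if m.sum() >= 5:
            centers.append(d[m].mean())
            means.append(r2[m].mean())
    x = np.asarray(centers)
    y = np.asarray(means)

    def model(dd, a, s, c):
        return a * np.exp(-dd / s) + c

    s0 = max(x.mean(), 1.0)
    (a, s, c), _ = curve_fit(
        model, x, y, p0=(max(y.max(), 0.1), s0, max(y.min(), 0.0)),
        bounds=([0, 1e-6, 0], [2, x.max() * 10, 1]), maxfev=20000
    )
    return float(s)
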
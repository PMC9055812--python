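"""Assembly QC: k-mer genome-size estimation and duplicate-contig purging.

Genome size follows the classic k-mer spectrum estimate

    genome size = total k-mer observations / peak depth

after discarding the low-multiplicity error spike. The duplicate purge
emulates manual curation of an over-assembled haploid genome: contigs
are walked from the low-depth end of the depth distribution and removed
until the retained length approximates an independently estimated genome
size, never discarding a contig that carries a non-duplicated BUSCO gene
(the walk skips it and removes the next-lowest-depth contig instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KmerHistogram:
    """k-mer multiplicity spectrum: distinct-k-mer counts per multiplicity."""

    multiplicity: np.ndarray
    count: np.ndarray
    k: int = 101

    def __post_init__(self) -> None:
        self.multiplicity = np.asarray(self.multiplicity, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=np.int64)
        if len(self.multiplicity) != len(self.count):
            raise ValueError("multiplicity and count lengths differ")
        if len(np.unique(self.multiplicity)) != len(self.multiplicity):
            raise ValueError("multiplicities must be unique")
        if (self.count < 0).any() or (self.multiplicity < 1).any():
            raise ValueError("counts must be >= 0 and multiplicities >= 1")
        order = np.argsort(self.multiplicity)
        self.multiplicity = self.multiplicity[order]
        self.count = self.count[order]


@dataclass
class ContigDepthTable:
    """Per-contig length, mean mapped depth and BUSCO hit labels.

    ``contigs`` columns: id, length, depth, n_busco_single,
    n_busco_duplicated.
    """

    contigs: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.contigs
        if (c["length"] <= 0).any():
            raise ValueError("contig lengths must be positive")
        if (c["depth"] < 0).any():
            raise ValueError("contig depths must be non-negative")


@dataclass
class GenomeSizeEstimate:
    genome_size: int
    peak_depth: int
    total_kmers: int
    single_copy_fraction: float
    error_cutoff: int


def kmer_genome_size(
    histogram: KmerHistogram, error_cutoff: int | None = None
) -> GenomeSizeEstimate:
    """Estimate genome size from a k-mer spectrum.

    The error region is everything below the first local minimum of the
    spectrum (or below an explicit ``error_cutoff`` multiplicity); the
    peak is the most populous multiplicity above it. Size is the floor of
    total retained k-mer observations over the peak depth. The
    single-copy fraction is the observation mass within
    [peak/2, 3*peak/2] over the retained total.
    """
    m, c = histogram.multiplicity, histogram.count
    if error_cutoff is None:
        # first local minimum of the count curve
        mins = np.where((c[1:-1] <= c[:-2]) & (c[1:-1] <= c[2:]))[0]
        if len(mins) == 0:
            raise ValueError(
                "no valley between error spike and main peak; pass error_cutoff"
            )
        error_cutoff = int(m[mins[0] + 1])
    retained = m > error_cutoff
    if not retained.any():
        raise ValueError("error_cutoff removes the whole histogram")
    peak_idx = np.argmax(c[retained])
    peak = int(m[retained][peak_idx])
    total = int(np.sum(m[retained] * c[retained]))
    size = total // peak
    win = retained & (m >= peak / 2) & (m <= 3 * peak / 2)
    single = float(np.sum(m[win] * c[win]) / total) if total else 0.0
    return GenomeSizeEstimate(size, peak, total, single, error_cutoff)


@dataclass
class DepthModes:
    modes: list[float]
    duplicated_mass: float  # length fraction below the inter-mode valley
    valley: float | None


def depth_modes(table: ContigDepthTable, bandwidth: float | None = None) -> DepthModes:
    """Length-weighted kernel density of contig depths and its modes.

    With a bimodal distribution (duplicated contigs mapping at ~half
    depth), reports both mode locations and the length fraction below
    the valley between the two largest modes.
    """
    c = table.contigs
    if len(c) < 10:
        raise ValueError("need at least 10 contigs")
    depths = c["depth"].to_numpy(dtype=float)
    weights = c["length"].to_numpy(dtype=float)
    if np.allclose(depths, depths[0]):
        return DepthModes([float(depths[0])], 0.0, None)
    kde = stats.gaussian_kde(depths, weights=weights, bw_method=bandwidth)
    grid = np.linspace(0, depths.max() * 1.2, 512)
    dens = kde(grid)
    is_max = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    modes = grid[1:-1][is_max]
    heights = dens[1:-1][is_max]
    order = np.argsort(heights)[::-1]
    modes = modes[order]
    if len(modes) < 2:
        return DepthModes([float(m) for m in modes], 0.0, None)
    m1, m2 = sorted(modes[:2])
    between = (grid > m1) & (grid < m2)
    valley = float(grid[between][np.argmin(dens[between])])
    below = weights[depths < valley].sum() / weights.sum()
    return DepthModes(
        sorted(float(m) for m in modes), float(below), valley
    )


@dataclass
class PurgeReport:
    kept: list[str]
    removed: list[str]
    kept_length: int
    removed_length: int
    target_size: int
    tolerance: float
    protected_overflow: bool = False


def purge_duplicates(
    table: ContigDepthTable, target_size: int, tolerance: float = 0.02
) -> PurgeReport:
    """Greedy low-depth-first purge of duplicated contigs.

    Contigs are sorted by ascending depth (ties: longer first, then id)
    and removed consecutively until the retained length falls within
    ``target_size * (1 + tolerance)``. Contigs carrying at least one
    single-status BUSCO are protected: the walk skips them and removes
    the next-lowest-depth unprotected contig instead. If the protected
    length alone exceeds the band, everything protected is kept and the
    report flags the overflow.
    """
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    c = table.contigs.copy()
    c["_protected"] = c["n_busco_single"] > 0
    c = c.sort_values(
        ["depth", "length", "id"], ascending=[True, False, True], kind="mergesort"
    )
    budget = target_size * (1 + tolerance)
    retained = int(c["length"].sum())
    removed: list[str] = []
    for _, row in c.iterrows():
        if retained <= budget:
            break
        if row["_protected"]:
            continue
        removed.append(row["id"])
        retained -= int(row["length"])
    protected_overflow = retained > budget
    kept = [i for i in table.contigs["id"] if i not in set(removed)]
    return PurgeReport(
        kept=kept,
        removed=removed,
        kept_length=retained,
        removed_length=int(table.contigs["length"].sum()) - retained,
        target_size=target_size,
        tolerance=tolerance,
        protected_overflow=protected_overflow,
    )
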
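"""Genomic feature context: density tracks, overlap classes and block painting.

Operates on a :class:`GenomeAnnotation` of typed intervals (genes with
exon/intron substructure, TEs labelled by superfamily) and on locus
tables from the sRNA pipeline. Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["scaffold", "start", "end", "strand", "type", "id"]

TE_PREFIX = "TE:"
TE_SUPERFAMILIES = ("Gypsy", "Copia", "LINE", "Helitron", "MuLE", "other")


@dataclass
class GenomeAnnotation:
    """Typed genomic intervals on named scaffolds.

    ``intervals`` columns: scaffold, start, end, strand, type, id; type
    is ``gene``, ``exon``, ``intron`` or ``TE:<superfamily>``.
    """

    intervals: pd.DataFrame
    scaffold_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.scaffold_lengths.items():
            if length <= 0:
                raise ValueError(f"zero-length scaffold {name!r}")
        iv = self.intervals
        if len(iv):
            if (iv["end"] <= iv["start"]).any():
                raise ValueError("empty or inverted interval in annotation")
            lengths = iv["scaffold"].map(self.scaffold_lengths)
            if lengths.isna().any() or (iv["end"] > lengths).any():
                raise ValueError("interval outside scaffold bounds")

    def of_type(self, *types: str) -> pd.DataFrame:
        return self.intervals[self.intervals["type"].isin(types)]

    @property
    def genes(self) -> pd.DataFrame:
        return self.of_type("gene")

    @property
    def tes(self) -> pd.DataFrame:
        return self.intervals[self.intervals["type"].str.startswith(TE_PREFIX)]


@dataclass
class BlockPainting:
    """Ancestral-karyotype segments in gene-index space per scaffold."""

    segments: pd.DataFrame  # scaffold, start_index, end_index, label
    labelled_genes_covered: int


def density_tracks(
    annotation: GenomeAnnotation, window: int = 1_000_000
) -> pd.DataFrame:
    """Per-window feature counts by interval midpoint membership.

    Windows tile each scaffold (last window truncated); every feature is
    counted exactly once, in the window containing its midpoint.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    iv = annotation.intervals
    for scaffold, length in annotation.scaffold_lengths.items():
        n_win = int(np.ceil(length / window))
        sub = iv[iv["scaffold"] == scaffold]
        mid = ((sub["start"] + sub["end"]) // 2).to_numpy()
        win_of = np.minimum(mid // window, n_win - 1)
        for w in range(n_win):
            m = win_of == w
            counts = sub.loc[m, "type"].value_counts()
            base = {
                "scaffold": scaffold,
                "window_start": w * window,
                "window_end": min((w + 1) * window, length),
            }
            for t, c in counts.items():
                rows.append({**base, "type": t, "count": int(c)})
            if not counts.size:
                rows.append({**base, "type": None, "count": 0})
    return pd.DataFrame(rows)


def gene_density_partition(gene_track: pd.DataFrame) -> pd.DataFrame:
    """Label windows gene-enriched/depleted around the mean density.

    The threshold is the mean of per-window gene counts: windows strictly
    above the mean are ``enriched``, all others ``depleted``. The result
    frame carries ``mean_per_window`` and ``median_per_window`` columns
    (both are reported; the mean is the classifier).
    """
    if gene_track.empty:
        raise ValueError("need at least one window")
    counts = gene_track["count"].to_numpy(dtype=float)
    mean = counts.mean()
    median = float(np.median(counts))
    out = gene_track.copy()
    out["label"] = np.where(counts > mean, "enriched", "depleted")
    out["mean_per_window"] = mean
    out["median_per_window"] = median
    return out


def _overlaps_any(
    start: int, end: int, starts: np.ndarray, ends: np.ndarray
) -> bool:
    """True if [start, end) overlaps any of the (sorted-by-start) intervals."""
    i = np.searchsorted(starts, end)  # intervals with start < end
    return bool((ends[:i] > start).any())


def intersect_fraction(
    loci: pd.DataFrame,
    annotation: GenomeAnnotation,
    precedence: tuple[str, ...] = ("exon", "intron", "TE", "intergenic"),
) -> tuple[pd.Series, pd.Series]:
    """Assign each locus its first overlapping precedence class.

    ``"TE"`` matches any TE superfamily; ``"intergenic"`` is the fallback
    for loci overlapping none of the earlier classes. Returns the
    per-locus class series and the class fractions (summing to 1).
    """
    by_class: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    iv = annotation.intervals
    for cls in precedence:
        if cls == "intergenic":
            continue
        if cls == "TE":
            sub = annotation.tes
        else:
            sub = iv[iv["type"] == cls]
        per_scaf = {}
        for scaffold, grp in sub.groupby("scaffold"):
            grp = grp.sort_values("start")
            per_scaf[scaffold] = (grp["start"].to_numpy(), grp["end"].to_numpy())
        by_class[cls] = per_scaf

    labels = []
    for _, row in loci.iterrows():
        assigned = "intergenic" if "intergenic" in precedence else None
        for cls in precedence:
            if cls == "intergenic":
                continue
            tab = by_class[cls].get(row["scaffold"])
            if tab is not None and _overlaps_any(row["start"], row["end"], *tab):
                assigned = cls
                break
        labels.append(assigned)
    classes = pd.Series(labels, index=loci.index, name="class")
    fractions = classes.value_counts(normalize=True)
    return classes, fractions


def distance_to_nearest(
    loci: pd.DataFrame, targets: pd.DataFrame, threshold: int = 1500
) -> tuple[pd.Series, float]:
    """Gap to the nearest target interval on the same scaffold.

    Distance is 0 for overlapping intervals, otherwise the minimum gap;
    loci on scaffolds without targets get NaN. Also returns the fraction
    of non-missing loci within ``threshold`` bp.
    """
    if targets.empty:
        raise ValueError("target set is empty")
    per_scaf: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for scaffold, grp in targets.groupby("scaffold"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = np.maximum.accumulate(grp["end"].to_numpy())
        per_scaf[scaffold] = (starts, ends)
    dists = []
    for _, row in loci.iterrows():
        tab = per_scaf.get(row["scaffold"])
        if tab is None:
            dists.append(np.nan)
            continue
        starts, ends = tab
        s, e = row["start"], row["end"]
        i = np.searchsorted(starts, e)
        d = np.inf
        if i > 0:
            gap_left = s - ends[i - 1]  # nearest interval ending before/at s
            d = max(0, gap_left)
        if i < len(starts):
            d = min(d, starts[i] - e)
        dists.append(float(d))
    dist = pd.Series(dists, index=loci.index, name="distance")
    within = float((dist.dropna() <= threshold).mean()) if dist.notna().any() else np.nan
    return dist, within


def te_contained_genes(
    genes: pd.DataFrame, tes: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Genes lying fully inside a single TE body, and the MuLE subset.

    A gene is contained when one TE interval covers its whole span; it is
    flagged Pack-MULE-like when any overlapping TE is of the MuLE
    superfamily.
    """
    contained: list[str] = []
    mule: list[str] = []
    per_scaf: dict[str, pd.DataFrame] = {
        s: g.sort_values("start") for s, g in tes.groupby("scaffold")
    }
    for _, gene in genes.iterrows():
        tab = per_scaf.get(gene["scaffold"])
        if tab is None:
            continue
        s, e = gene["start"], gene["end"]
        overlapping = tab[(tab["start"] < e) & (tab["end"] > s)]
        if ((overlapping["start"] <= s) & (overlapping["end"] >= e)).any():
            contained.append(gene["id"])
            if overlapping["type"].eq(f"{TE_PREFIX}MuLE").any():
                mule.append(gene["id"])
    return contained, mule


def _segment_valid(
    counts: dict[str, int], n_labelled: int, min_run: int, max_dissent: float
) -> str | None:
    """Majority label if the run qualifies as a block segment, else None."""
    if n_labelled < min_run:
        return None
    best = max(counts.values())
    if best / n_labelled < 1 - max_dissent:
        return None
    return min(l for l, c in counts.items() if c == best)


def assign_ancestral_blocks(
    gene_order: pd.DataFrame,
    min_run: int = 5,
    max_dissent: float = 0.2,
) -> BlockPainting:
    """Paint ancestral-karyotype blocks from per-gene ortholog labels.

    ``gene_order`` must have genes ordered by position with columns
    ``scaffold, id, block`` (block may be NA for genes without an
    ortholog). A run of genes becomes a segment when it contains at
    least ``min_run`` labelled genes and its majority label accounts for
    at least ``1 - max_dissent`` of them; unlabelled genes never break a
    run. Among all valid non-overlapping segmentations, the one covering
    the most labelled genes is chosen (ties: fewer segments, leftmost),
    via an exact dynamic program per scaffold.
    """
    seg_rows = []
    covered_total = 0
    for scaffold, grp in gene_order.groupby("scaffold", sort=True):
        labels = [
            None if pd.isna(b) else str(b) for b in grp["block"].tolist()
        ]
        n = len(labels)
        # candidate segments [i, j) with their majority label and coverage
        candidates: list[tuple[int, int, str, int]] = []
        for i in range(n):
            if labels[i] is None:
                continue  # canonical segments start on a labelled gene
            counts: dict[str, int] = {}
            n_lab = 0
            for j in range(i, n):
                if labels[j] is not None:
                    counts[labels[j]] = counts.get(labels[j], 0) + 1
                    n_lab += 1
                    lab = _segment_valid(counts, n_lab, min_run, max_dissent)
                    if lab is not None:
                        candidates.append((i, j + 1, lab, n_lab))
        # DP over gene index: best (coverage, -n_segments) using genes < j,
        # with a backpointer (segment taken ending at j, or None for skip)
        score = [(0, 0)] * (n + 1)
        back: list[tuple[int, str] | None] = [None] * (n + 1)
        by_end: dict[int, list[tuple[int, int, str, int]]] = {}
        for c in candidates:
            by_end.setdefault(c[1], []).append(c)
        for j in range(1, n + 1):
            score[j], back[j] = score[j - 1], None
            for (i, _, lab, cov) in by_end.get(j, []):
                cand = (score[i][0] + cov, score[i][1] - 1)
                if cand > score[j]:
                    score[j], back[j] = cand, (i, lab)
        j = n
        chosen: list[tuple[int, int, str]] = []
        while j > 0:
            if back[j] is None:
                j -= 1
            else:
                i, lab = back[j]
                chosen.append((i, j, lab))
                j = i
        covered_total += score[n][0]
        for i, jj, lab in reversed(chosen):
            seg_rows.append(
                {"scaffold": scaffold, "start_index": i, "end_index": jj, "label": lab}
            )
    segments = pd.DataFrame(
        seg_rows, columns=["scaffold", "start_index", "end_index", "label"]
    )
    return BlockPainting(segments=segments, labelled_genes_covered=covered_total)
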
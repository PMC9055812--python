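"""Feature context: densities, overlap classes, distances, block painting."""

import numpy as np
import pandas as pd
import pytest

from cressomics import context
from cressomics.context import (
    GenomeAnnotation,
    assign_ancestral_blocks,
    density_tracks,
    distance_to_nearest,
    gene_density_partition,
    intersect_fraction,
    te_contained_genes,
)


def ann_from(rows, lengths):
    df = pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "strand", "type", "id"]
    )
    return GenomeAnnotation(df, lengths)


def test_annotation_rejects_zero_length_scaffold():
    with pytest.raises(ValueError):
        ann_from([], {"s1": 0})


def test_density_tracks_midpoint_rule():
    rows = [
        ("s1", 100, 200, "+", "gene", "g1"),
        ("s1", 300, 400, "+", "gene", "g2"),
        ("s1", 500, 600, "+", "gene", "g3"),
        # straddles the window boundary; midpoint 1050 -> window 1
        ("s1", 900, 1200, "+", "gene", "g4"),
    ]
    ann = ann_from(rows, {"s1": 2000})
    track = density_tracks(ann, window=1000)
    gene = track[track["type"] == "gene"]
    counts = dict(zip(gene["window_start"], gene["count"]))
    assert counts == {0: 3, 1000: 1}
    assert gene["count"].sum() == 4


def test_gene_density_partition_mean_rule():
    track = pd.DataFrame(
        {"scaffold": "s1", "window_start": [0, 1, 2], "count": [10, 20, 60]}
    )
    out = gene_density_partition(track)
    assert list(out["label"]) == ["depleted", "depleted", "enriched"]
    assert out["mean_per_window"].iloc[0] == pytest.approx(30.0)
    assert out["median_per_window"].iloc[0] == pytest.approx(20.0)


def test_gene_density_partition_all_equal_counts():
    track = pd.DataFrame({"scaffold": "s1", "window_start": [0, 1], "count": [5, 5]})
    out = gene_density_partition(track)
    assert set(out["label"]) == {"depleted"}  # nothing strictly above the mean


def test_intersect_fraction_precedence():
    rows = [
        ("s1", 0, 1000, "+", "gene", "g1"),
        ("s1", 0, 100, "+", "exon", "g1.e1"),
        ("s1", 100, 900, "+", "intron", "g1.i1"),
        ("s1", 900, 1000, "+", "exon", "g1.e2"),
        ("s1", 950, 2000, "+", "TE:Gypsy", "t1"),
    ]
    ann = ann_from(rows, {"s1": 3000})
    loci = pd.DataFrame(
        {
            "scaffold": ["s1", "s1", "s1"],
            "start": [200, 920, 2500],
            "end": [250, 980, 2550],
        }
    )
    classes, fractions = intersect_fraction(loci, ann)
    assert list(classes) == ["intron", "exon", "intergenic"]
    assert fractions.sum() == pytest.approx(1.0, abs=1e-12)


def test_distance_to_nearest_basics():
    targets = pd.DataFrame(
        {"scaffold": ["s1", "s1"], "start": [1000, 5000], "end": [2000, 6000]}
    )
    loci = pd.DataFrame(
        {
            "scaffold": ["s1", "s1", "s1", "s2"],
            "start": [1500, 3400, 7600, 0],
            "end": [1600, 3500, 7700, 100],
        }
    )
    dist, within = distance_to_nearest(loci, targets, threshold=1500)
    assert dist.iloc[0] == 0  # overlapping
    assert dist.iloc[1] == 1400  # within threshold
    assert dist.iloc[2] == 1600  # outside threshold
    assert np.isnan(dist.iloc[3])  # target-free scaffold
    assert within == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        distance_to_nearest(loci, targets.iloc[0:0])


def test_distance_to_nearest_matches_bruteforce():
    rng = np.random.default_rng(23)
    for _ in range(5):
        n_t = int(rng.integers(1, 50))
        targets = pd.DataFrame(
            {
                "scaffold": "s1",
                "start": (s := rng.integers(0, 100_000, n_t)),
                "end": s + rng.integers(50, 3000, n_t),
            }
        )
        loci = pd.DataFrame(
            {
                "scaffold": "s1",
                "start": (l := rng.integers(0, 100_000, 40)),
                "end": l + 100,
            }
        )
        dist, _ = distance_to_nearest(loci, targets)
        for i, row in loci.iterrows():
            best = min(
                max(t.start - row.end, row.start - t.end, 0)
                for t in targets.itertuples()
            )
            assert dist.iloc[i] == best


def test_te_contained_genes_rules():
    genes = pd.DataFrame(
        {
            "scaffold": ["s1", "s1", "s1"],
            "start": [100, 40, 500],
            "end": [200, 350, 600],
            "id": ["inside", "sticks_out", "far"],
        }
    )
    tes = pd.DataFrame(
        {
            "scaffold": ["s1"],
            "start": [50],
            "end": [300],
            "type": ["TE:MuLE"],
        }
    )
    contained, mule = te_contained_genes(genes, tes)
    assert contained == ["inside"]
    assert mule == ["inside"]
    # sharing the TE start but extending past its end is not containment
    tes2 = tes.assign(start=40, end=340)
    contained2, _ = te_contained_genes(genes, tes2)
    assert contained2 == ["inside"]
    # widening the TE past the gene end makes it contained
    tes3 = tes.assign(start=40, end=360)
    contained3, _ = te_contained_genes(genes, tes3)
    assert sorted(contained3) == ["inside", "sticks_out"]


def test_te_contained_recovers_planted_genes(annotation):
    ann, truth = annotation
    contained, mule = te_contained_genes(ann.genes, ann.tes)
    planted = sorted(truth.loc[truth["kind"] == "te_embedded_gene", "id"])
    assert sorted(contained) == planted
    assert sorted(mule) == planted  # planted hosts are MuLE elements


def order_frame(labels, scaffold="s1"):
    return pd.DataFrame(
        {
            "scaffold": scaffold,
            "id": [f"g{i}" for i in range(len(labels))],
            "block": labels,
        }
    )


def test_blocks_simple_run():
    painting = assign_ancestral_blocks(order_frame(["A"] * 6))
    assert len(painting.segments) == 1
    seg = painting.segments.iloc[0]
    assert (seg["start_index"], seg["end_index"], seg["label"]) == (0, 6, "A")


def test_blocks_short_run_unassigned():
    painting = assign_ancestral_blocks(order_frame(["B", "B", "B"]))
    assert painting.segments.empty


def test_blocks_tolerates_dissent_and_gaps():
    labels = ["A", "A", "A", "A", "B", "A", "A", "A", "A", "A"]
    painting = assign_ancestral_blocks(order_frame(labels))
    assert len(painting.segments) == 1
    assert painting.segments.iloc[0]["label"] == "A"
    assert painting.labelled_genes_covered == 10
    # unlabelled genes do not break runs
    gapped = ["A", "A", None, "A", None, "A", "A"]
    painting = assign_ancestral_blocks(order_frame(gapped))
    assert len(painting.segments) == 1
    assert painting.labelled_genes_covered == 5


def _bruteforce_blocks(labels, min_run=5, max_dissent=0.2):
    """Exhaustive search over non-overlapping valid segments, maximizing
    labelled-gene coverage (ties: fewer segments)."""
    n = len(labels)

    def valid(i, j):
        lab = [l for l in labels[i:j] if l is not None]
        if len(lab) < min_run:
            return None
        best = max(lab.count(l) for l in set(lab))
        if best / len(lab) < 1 - max_dissent:
            return None
        return len(lab)

    best_result = (0, 0)
    from itertools import combinations

    cuts = list(range(n + 1))
    # enumerate all segment sets via recursion
    def rec(pos, cov, nseg):
        nonlocal best_result
        best_result = max(best_result, (cov, -nseg))
        for i in range(pos, n):
            for j in range(i + 1, n + 1):
                v = valid(i, j)
                if v is not None:
                    rec(j, cov + v, nseg + 1)

    rec(0, 0, 0)
    return best_result


def test_blocks_match_exhaustive_oracle():
    rng = np.random.default_rng(31)
    alphabet = ["A", "B", None]
    for _ in range(8):
        n = int(rng.integers(6, 14))
        labels = [alphabet[k] for k in rng.integers(0, 3, n)]
        painting = assign_ancestral_blocks(order_frame(labels), min_run=3)
        cov_or = _bruteforce_blocks(labels, min_run=3)[0]
        assert painting.labelled_genes_covered == cov_or
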
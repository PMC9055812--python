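"""Cluster discovery, consensus annotation and locus metrics."""

import numpy as np
import pandas as pd
import pytest

from cressomics import srna
from cressomics.srna import (
    SrnaCluster,
    SrnaLibrary,
    consensus_loci,
    discover_clusters,
    phase_score,
    rpm_normalize,
    tissue_partition,
)

from conftest import make_reads


def lib(rows, library_id="L1", tissue="leaf", rep=1, total=1_000_000):
    return SrnaLibrary(library_id, tissue, rep, make_reads(rows), total)


@pytest.mark.parametrize(
    "count,total,expected",
    [(2, 1_000_000, 2.0), (0, 123, 0.0), (5, 2_000_000, 2.5)],
)
def test_rpm_normalize(count, total, expected):
    assert rpm_normalize(count, total) == expected


def test_rpm_rejects_bad_totals():
    with pytest.raises(ValueError):
        rpm_normalize(1, 0)
    with pytest.raises(ValueError):
        rpm_normalize(-1, 10)


def test_discover_clusters_merges_within_pad():
    library = lib(
        [("s1", 100, 23, "+", 2, "U"), ("s1", 150, 23, "+", 2, "U")], total=1_000_000
    )
    clusters = discover_clusters(library, min_rpm=2.0, island_pad=75)
    assert [(c.start, c.end) for c in clusters] == [(100, 173)]
    assert clusters[0].rpm == 4.0


def test_discover_clusters_rpm_floor():
    # a 1-read island in a 1M-read library is 1 RPM -> dropped; 2 reads kept
    one = lib([("s1", 100, 24, "+", 1, "U")])
    two = lib([("s1", 100, 24, "+", 2, "U")])
    assert discover_clusters(one) == []
    assert len(discover_clusters(two)) == 1


def test_discover_clusters_empty_library():
    assert discover_clusters(lib([])) == []


def _bruteforce_islands(reads, pad):
    """Union over the pairwise gap graph (connected components)."""
    items = list(reads[["start", "end"]].itertuples(index=False))
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            gap = max(items[i].start, items[j].start) - min(items[i].end, items[j].end)
            if gap <= pad:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(
        (min(items[i].start for i in c), max(items[i].end for i in c))
        for c in comps.values()
    )


def test_discover_clusters_matches_gap_graph_oracle():
    rng = np.random.default_rng(11)
    for trial in range(20):
        n = int(rng.integers(1, 200))
        starts = rng.integers(0, 5000, n)
        rows = [("s1", int(s), int(rng.integers(20, 25)), "+", 1, "U") for s in starts]
        library = lib(rows, total=1000)  # low total so every island clears RPM
        got = [(c.start, c.end) for c in discover_clusters(library, min_rpm=0.0)]
        assert got == _bruteforce_islands(library.reads, 75)


def clusters_of(intervals, library_id, rpm=5.0):
    return [
        SrnaCluster("s1", s, e, rpm, 10, library_id) for s, e in intervals
    ]


def test_consensus_requires_min_libraries():
    tissue_map = {f"L{i}": "leaf" for i in range(1, 4)}
    support3 = {
        "L1": clusters_of([(100, 200)], "L1"),
        "L2": clusters_of([(100, 200)], "L2"),
        "L3": clusters_of([(100, 200)], "L3"),
    }
    assert len(consensus_loci(support3, tissue_map)) == 1
    support2 = {
        "L1": clusters_of([(100, 200)], "L1"),
        "L2": clusters_of([(100, 200)], "L2"),
        "L3": clusters_of([(500, 600)], "L3"),
    }
    assert consensus_loci(support2, tissue_map) == []


@pytest.mark.parametrize("gap,n_expected", [(25, 1), (26, 2)])
def test_consensus_merge_gap_semantics(gap, n_expected):
    tissue_map = {f"L{i}": "leaf" for i in range(1, 4)}
    intervals = [(100, 200), (200 + gap, 300 + gap)]
    clusters = {f"L{i}": clusters_of(intervals, f"L{i}") for i in range(1, 4)}
    assert len(consensus_loci(clusters, tissue_map)) == n_expected


@pytest.mark.parametrize("rpm,kept", [(0.4, 0), (0.5, 1)])
def test_consensus_rpm_rescue_boundary(rpm, kept):
    tissue_map = {f"L{i}": "leaf" for i in range(1, 4)}
    clusters = {
        f"L{i}": clusters_of([(100, 200)], f"L{i}", rpm=rpm) for i in range(1, 4)
    }
    assert len(consensus_loci(clusters, tissue_map)) == kept


def test_consensus_warns_on_undersized_tissue():
    with pytest.warns(UserWarning):
        out = consensus_loci(
            {"L1": clusters_of([(0, 50)], "L1")}, {"L1": "leaf"}, min_libraries=3
        )
    assert out == []


def _bruteforce_consensus(clusters_by_library, tissue_map, span, min_lib=3,
                          merge_gap=25, rescue=0.5):
    """Per-base vote consensus on a single scaffold of length `span`."""
    tissues = {}
    for lib_id, tissue in tissue_map.items():
        tissues.setdefault(tissue, []).append(lib_id)
    per_tissue = []
    for tissue, lib_ids in sorted(tissues.items()):
        votes = np.zeros(span, dtype=int)
        for lib_id in lib_ids:
            cov = np.zeros(span, dtype=bool)
            for c in clusters_by_library[lib_id]:
                cov[c.start : c.end] = True
            votes += cov
        keep = votes >= min_lib
        # maximal runs
        runs = []
        i = 0
        while i < span:
            if keep[i]:
                j = i
                while j < span and keep[j]:
                    j += 1
                runs.append([i, j])
                i = j
            else:
                i += 1
        merged = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            max_rpm = 0.0
            for lib_id in lib_ids:
                tot = sum(
                    c.rpm
                    for c in clusters_by_library[lib_id]
                    if c.start < e and c.end > s
                )
                max_rpm = max(max_rpm, tot)
            if max_rpm >= rescue:
                per_tissue.append((s, e, tissue))
    # cross-tissue union of overlapping/touching
    per_tissue.sort()
    out = []
    for s, e, tissue in per_tissue:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
            out[-1][2].add(tissue)
        else:
            out.append([s, e, {tissue}])
    return [(s, e, frozenset(t)) for s, e, t in out]


def test_consensus_matches_per_base_vote_oracle():
    rng = np.random.default_rng(5)
    span = 50_000
    tissues = ["leaf", "root"]
    for trial in range(10):
        tissue_map = {}
        clusters = {}
        for t in tissues:
            for r in range(3):
                lib_id = f"{t}{r}"
                tissue_map[lib_id] = t
                n = int(rng.integers(3, 25))
                starts = np.sort(rng.integers(0, span - 400, n))
                ivs = []
                last = -(10**9)
                for s in starts:
                    e = int(s + rng.integers(30, 400))
                    if s - last < 1:
                        continue
                    ivs.append((int(s), min(e, span)))
                    last = e
                # non-overlapping within a library, like real cluster calls
                ivs = _disjoint(ivs)
                clusters[lib_id] = [
                    SrnaCluster("s1", s, e, float(rng.uniform(0.2, 5)), 5, lib_id)
                    for s, e in ivs
                ]
        got = consensus_loci(clusters, tissue_map)
        expect = _bruteforce_consensus(clusters, tissue_map, span)
        assert [(l.start, l.end, l.tissues_of_origin) for l in got] == expect


def _disjoint(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s < out[-1][1]:
            continue
        out.append((s, e))
    return out


def test_consensus_loci_never_overlap(srna_libraries):
    libraries, _ = srna_libraries
    loci = srna.run_pipeline(libraries)
    by_scaf = {}
    for l in loci:
        by_scaf.setdefault(l.scaffold, []).append((l.start, l.end))
    for ivs in by_scaf.values():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert s2 >= e1


def test_consensus_monotonic_in_thresholds(srna_libraries):
    libraries, _ = srna_libraries
    clusters = {
        l.library_id: discover_clusters(l) for l in libraries
    }
    tissue_map = {l.library_id: l.tissue for l in libraries}
    base = len(consensus_loci(clusters, tissue_map))
    with pytest.warns(UserWarning):  # 4 > replicates per tissue
        stricter_libs = len(consensus_loci(clusters, tissue_map, min_libraries=4))
    stricter_rpm = len(consensus_loci(clusters, tissue_map, min_rpm_rescue=5.0))
    assert stricter_libs <= base
    assert stricter_rpm <= base


def test_classify_locus_size_classes():
    # 90% of mass at 24 nt -> heterochromatic class
    reads = make_reads(
        [("s1", 0, 24, "+", 9, "U"), ("s1", 30, 21, "+", 1, "A")]
    )
    size_class, _, freq = srna.classify_locus(reads)
    assert size_class == "23-24"
    assert freq["U"] == pytest.approx(0.9)
    all21 = make_reads([("s1", 0, 21, "+", 5, "U")])
    assert srna.classify_locus(all21)[0] == "20-22"
    half = make_reads([("s1", 0, 24, "+", 5, "U"), ("s1", 30, 21, "+", 5, "U")])
    assert srna.classify_locus(half)[0] == "mixed"


def test_classify_locus_complexity_definition():
    reads = make_reads([("s1", 100, 24, "+", 10, "U")])
    _, complexity, _ = srna.classify_locus(reads)
    assert complexity == pytest.approx(0.1)


def test_classify_locus_rejects_empty():
    with pytest.raises(ValueError):
        srna.classify_locus(make_reads([]))


def test_phase_score_degenerate_perfect_register():
    rows = [("s1", 240 + 24 * k, 24, "+", 1, "U") for k in range(50)]
    res = phase_score(make_reads(rows), 24)
    assert res.score == 1.0
    assert res.phased


def test_phase_score_too_few_reads():
    res = phase_score(make_reads([("s1", 0, 24, "+", 3, "U")]), 24)
    assert not res.phased
    assert res.reason == "too_few_reads"


def test_phase_score_type_one_error_controlled():
    """Uniform 5' ends should essentially never be called phased."""
    rng = np.random.default_rng(13)
    false_pos = 0
    n_loci = 2000
    for _ in range(n_loci):
        starts = rng.integers(0, 480, 40)
        reads = make_reads([("s1", int(s), 24, "+", 1, "U") for s in starts])
        false_pos += phase_score(reads, 24).phased
    assert false_pos / n_loci <= 0.07


def test_phase_score_power_with_off_register_noise():
    rng = np.random.default_rng(17)
    detected = 0
    n_loci = 300
    for _ in range(n_loci):
        on = rng.random(40) >= 0.1
        starts = np.where(on, rng.integers(0, 20, 40) * 24, rng.integers(0, 480, 40))
        reads = make_reads([("s1", int(s), 24, "+", 1, "U") for s in starts])
        detected += phase_score(reads, 24).phased
    assert detected / n_loci >= 0.95


def test_tissue_partition_conservation(srna_libraries):
    libraries, _ = srna_libraries
    loci = srna.run_pipeline(libraries)
    part = tissue_partition(loci)
    assert sum(part.values()) == len(loci)
    all_tissues = frozenset(l.tissue for l in libraries)
    assert part.get(all_tissues, 0) > 0  # shared-in-all loci exist
    private = {k: v for k, v in part.items() if len(k) == 1}
    assert private  # private loci exist


def test_pipeline_recovers_planted_and_rejects_noise(annotation, srna_libraries, config):
    ann, _ = annotation
    libraries, truth = srna_libraries
    loci = srna.run_pipeline(libraries)
    eligible = truth[truth["meets_thresholds"]]
    hits = 0
    for _, t in eligible.iterrows():
        if any(
            l.scaffold == t["scaffold"] and l.start < t["end"] and l.end > t["start"]
            for l in loci
        ):
            hits += 1
    assert hits / len(eligible) >= 0.95
    # tissue-private planted loci keep their tissue of origin
    private = truth[~truth["tissues"].str.contains(",")]
    for _, t in private.head(10).iterrows():
        overlapping = [
            l
            for l in loci
            if l.scaffold == t["scaffold"] and l.start < t["end"] and l.end > t["start"]
        ]
        assert overlapping
        for l in overlapping:
            assert l.tissues_of_origin == frozenset([t["tissues"]])


def test_pipeline_noise_only_yields_no_loci(annotation, config):
    from cressomics import simulate

    ann, _ = annotation
    cfg = simulate.SimulationConfig(seed=config.seed)
    cfg.srna.n_planted_loci = 0
    libraries, _ = simulate.gen_srna_libraries(ann, cfg)
    assert srna.run_pipeline(libraries) == []
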
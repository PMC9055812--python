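"""Small-RNA locus discovery and multi-library consensus annotation.

The annotation strategy mirrors common plant sRNA practice: clusters of
aligned 20-24-nt reads are called de novo in every library at a 2-RPM
floor, clusters from replicate libraries of one tissue are intersected
(an interval survives where at least ``min_libraries`` libraries agree),
nearby survivors are padded together, weakly expressed per-tissue loci
are dropped, and finally the per-tissue annotations are unioned into one
consensus set that remembers which tissues contributed each locus.

Coordinates are 0-based half-open throughout (BED native).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

READ_COLUMNS = ["scaffold", "start", "end", "length", "strand", "count", "five_prime"]

#: read lengths retained after adapter trimming
MIN_READ_LEN = 20
MAX_READ_LEN = 24


@dataclass
class SrnaLibrary:
    """One aligned small-RNA library.

    ``reads`` is a DataFrame with columns ``scaffold, start, end, length,
    strand, count, five_prime``; ``total_mapped_reads`` is the library-size
    denominator used for RPM (total mapped 20-24-nt reads).
    """

    library_id: str
    tissue: str
    replicate: int
    reads: pd.DataFrame
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ValueError("total_mapped_reads must be positive")
        bad = self.reads[(self.reads["length"] < MIN_READ_LEN) | (self.reads["length"] > MAX_READ_LEN)]
        if len(bad):
            raise ValueError(f"{len(bad)} reads outside the {MIN_READ_LEN}-{MAX_READ_LEN}-nt range")
        if int(self.reads["count"].sum()) > self.total_mapped_reads:
            raise ValueError("sum of read counts exceeds total_mapped_reads")


@dataclass(frozen=True)
class SrnaCluster:
    """A per-library read island that cleared the RPM floor."""

    scaffold: str
    start: int
    end: int
    rpm: float
    read_count: int
    library_id: str


@dataclass
class PhaseResult:
    register: int
    score: float
    p_value: float
    phased: bool
    reason: str | None = None


@dataclass
class SrnaLocus:
    """A consensus sRNA locus with per-tissue provenance."""

    scaffold: str
    start: int
    end: int
    tissues_of_origin: frozenset[str]
    tissue_max_rpm: dict[str, float]
    size_class: str | None = None
    complexity: float | None = None
    five_prime_freq: dict[str, float] | None = None
    phase_result: PhaseResult | None = None

    def __post_init__(self) -> None:
        if not self.tissues_of_origin:
            raise ValueError("locus must carry at least one tissue of origin")


def rpm_normalize(count: float, library_total: int) -> float:
    """Reads-per-million: ``count * 1e6 / library_total``."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * 1e6 / library_total


def discover_clusters(
    library: SrnaLibrary, min_rpm: float = 2.0, island_pad: int = 75
) -> list[SrnaCluster]:
    """Call read islands de novo in one library.

    Reads separated by gaps of at most ``island_pad`` nt are merged into
    islands; islands whose summed abundance is below ``min_rpm`` are
    discarded. Returns non-overlapping clusters sorted by position.
    """
    clusters: list[SrnaCluster] = []
    if library.reads.empty:
        return clusters
    for scaffold, grp in library.reads.groupby("scaffold", sort=True):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        counts = grp["count"].to_numpy()
        run_end = np.maximum.accumulate(ends)
        # a new island begins where the gap to everything before exceeds the pad
        new_island = np.empty(len(grp), dtype=bool)
        new_island[0] = True
        new_island[1:] = starts[1:] - run_end[:-1] > island_pad
        island_id = np.cumsum(new_island) - 1
        for i in range(island_id[-1] + 1):
            m = island_id == i
            n_reads = int(counts[m].sum())
            rpm = rpm_normalize(n_reads, library.total_mapped_reads)
            if rpm >= min_rpm:
                clusters.append(
                    SrnaCluster(
                        scaffold=str(scaffold),
                        start=int(starts[m].min()),
                        end=int(run_end[m].max()),
                        rpm=rpm,
                        read_count=n_reads,
                        library_id=library.library_id,
                    )
                )
    return clusters


def _coverage_intervals(
    intervals: list[tuple[int, int]], min_depth: int
) -> list[tuple[int, int]]:
    """Maximal intervals covered by >= min_depth of the input intervals."""
    if not intervals:
        return []
    events: dict[int, int] = {}
    for s, e in intervals:
        events[s] = events.get(s, 0) + 1
        events[e] = events.get(e, 0) - 1
    out: list[tuple[int, int]] = []
    depth = 0
    open_at: int | None = None
    for pos in sorted(events):
        depth += events[pos]
        if depth >= min_depth and open_at is None:
            open_at = pos
        elif depth < min_depth and open_at is not None:
            out.append((open_at, pos))
            open_at = None
    return out


def _merge_gap(intervals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Merge sorted intervals whose separation is <= gap."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def consensus_loci(
    clusters_by_library: dict[str, list[SrnaCluster]],
    tissue_map: dict[str, str],
    min_libraries: int = 3,
    merge_gap: int = 25,
    min_rpm_rescue: float = 0.5,
) -> list[SrnaLocus]:
    """Build the multi-tissue consensus locus annotation.

    Per tissue: multi-intersect replicate-library clusters keeping
    intervals covered by clusters from at least ``min_libraries``
    libraries, pad survivors separated by <= ``merge_gap`` nt together,
    and drop per-tissue loci whose maximum cluster RPM over all that
    tissue's libraries is below ``min_rpm_rescue``. Finally, union
    overlapping per-tissue loci across tissues, retaining tissue of
    origin information.
    """
    for lib_id in clusters_by_library:
        if lib_id not in tissue_map:
            raise ValueError(f"library {lib_id!r} missing from tissue_map")

    tissues: dict[str, list[str]] = {}
    for lib_id in clusters_by_library:
        tissues.setdefault(tissue_map[lib_id], []).append(lib_id)

    # (scaffold, start, end, tissue, max_rpm) per-tissue loci
    per_tissue: list[tuple[str, int, int, str, float]] = []
    for tissue, lib_ids in sorted(tissues.items()):
        if len(lib_ids) < min_libraries:
            warnings.warn(
                f"tissue {tissue!r} has {len(lib_ids)} libraries < min_libraries="
                f"{min_libraries}; it contributes no loci",
                stacklevel=2,
            )
            continue
        scaffolds = sorted(
            {c.scaffold for lib in lib_ids for c in clusters_by_library[lib]}
        )
        for scaffold in scaffolds:
            by_lib = {
                lib: [
                    (c.start, c.end, c.rpm)
                    for c in clusters_by_library[lib]
                    if c.scaffold == scaffold
                ]
                for lib in lib_ids
            }
            flat = [(s, e) for lib in lib_ids for (s, e, _) in by_lib[lib]]
            kept = _coverage_intervals(flat, min_libraries)
            for s, e in _merge_gap(kept, merge_gap):
                max_rpm = 0.0
                for lib in lib_ids:
                    lib_rpm = sum(
                        r for (cs, ce, r) in by_lib[lib] if cs < e and ce > s
                    )
                    max_rpm = max(max_rpm, lib_rpm)
                if max_rpm >= min_rpm_rescue:
                    per_tissue.append((scaffold, s, e, tissue, max_rpm))

    # cross-tissue union of overlapping (or touching) per-tissue loci
    loci: list[SrnaLocus] = []
    per_tissue.sort(key=lambda t: (t[0], t[1], t[2]))
    i = 0
    while i < len(per_tissue):
        scaffold, s, e, tissue, rpm = per_tissue[i]
        members = [(tissue, rpm)]
        j = i + 1
        while j < len(per_tissue) and per_tissue[j][0] == scaffold and per_tissue[j][1] <= e:
            e = max(e, per_tissue[j][2])
            members.append((per_tissue[j][3], per_tissue[j][4]))
            j += 1
        tissue_rpm: dict[str, float] = {}
        for t, r in members:
            tissue_rpm[t] = max(tissue_rpm.get(t, 0.0), r)
        loci.append(
            SrnaLocus(
                scaffold=scaffold,
                start=s,
                end=e,
                tissues_of_origin=frozenset(tissue_rpm),
                tissue_max_rpm=tissue_rpm,
            )
        )
        i = j
    return loci


def classify_locus(reads: pd.DataFrame) -> tuple[str, float, dict[str, float]]:
    """Size class, sequence complexity and 5' nucleotide bias of a locus.

    Size class is ``"23-24"`` when >=80% of the read mass (copy-weighted)
    has length 23-24 nt, ``"20-22"`` when >=80% has length 20-22 nt, and
    ``"mixed"`` otherwise. Complexity is the number of distinct
    (start, length, strand) read positions divided by the total read
    copies, in (0, 1]. The 5' frequency is copy-weighted over A/C/G/U.
    """
    if reads.empty:
        raise ValueError("cannot classify a locus with zero reads")
    counts = reads["count"].to_numpy(dtype=float)
    total = counts.sum()
    lengths = reads["length"].to_numpy()
    hc_mass = counts[(lengths >= 23) & (lengths <= 24)].sum() / total
    small_mass = counts[(lengths >= 20) & (lengths <= 22)].sum() / total
    if hc_mass >= 0.8:
        size_class = "23-24"
    elif small_mass >= 0.8:
        size_class = "20-22"
    else:
        size_class = "mixed"
    distinct = len(reads[["start", "length", "strand"]].drop_duplicates())
    complexity = distinct / total
    nt = reads["five_prime"].str.upper().str.replace("T", "U", regex=False)
    freq = {b: 0.0 for b in "ACGU"}
    mass = pd.Series(counts).groupby(nt.to_numpy()).sum()
    for b, v in mass.items():
        if b in freq:
            freq[b] = float(v) / total
    return size_class, float(complexity), freq


def phase_score(
    reads: pd.DataFrame,
    register: int,
    min_reads: int = 10,
    alpha: float = 0.05,
    min_score: float = 0.5,
) -> PhaseResult:
    """Detect phased (register-periodic) 5'-end accumulation.

    Only reads of exactly ``register`` nt contribute. The 5' end of a
    plus-strand read is its start; of a minus-strand read, ``end - 1``.
    The score is the largest fraction of 5'-end mass falling on a single
    register offset; the p-value is the binomial tail of that best offset
    under a uniform-offset null, Bonferroni-corrected by the register.
    """
    if register not in (21, 24):
        raise ValueError("register must be 21 or 24")
    sub = reads[reads["length"] == register]
    if sub.empty or int(sub["count"].sum()) < min_reads:
        return PhaseResult(register, 0.0, 1.0, False, reason="too_few_reads")
    five = np.where(
        sub["strand"].to_numpy() == "+",
        sub["start"].to_numpy(),
        sub["end"].to_numpy() - 1,
    )
    offsets = five % register
    counts = sub["count"].to_numpy(dtype=float)
    mass = np.zeros(register)
    np.add.at(mass, offsets, counts)
    n = int(counts.sum())
    k = int(mass.max())
    score = k / n
    p = min(1.0, register * float(stats.binom.sf(k - 1, n, 1.0 / register)))
    return PhaseResult(register, score, p, bool(p < alpha and score >= min_score))


def tissue_partition(loci: list[SrnaLocus]) -> dict[frozenset[str], int]:
    """Venn partition of loci by their exact tissue-of-origin subset."""
    out: dict[frozenset[str], int] = {}
    for locus in loci:
        out[locus.tissues_of_origin] = out.get(locus.tissues_of_origin, 0) + 1
    return out


def reads_in_interval(
    libraries: list[SrnaLibrary], scaffold: str, start: int, end: int
) -> pd.DataFrame:
    """Pooled reads from all libraries overlapping [start, end)."""
    parts = []
    for lib in libraries:
        r = lib.reads
        m = (r["scaffold"] == scaffold) & (r["start"] < end) & (r["end"] > start)
        if m.any():
            parts.append(r[m])
    if not parts:
        return pd.DataFrame(columns=READ_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def annotate_loci(
    loci: list[SrnaLocus],
    libraries: list[SrnaLibrary],
    phase_registers: tuple[int, ...] = (21, 24),
) -> list[SrnaLocus]:
    """Fill size class, complexity, 5' bias and phasing on consensus loci."""
    for locus in loci:
        reads = reads_in_interval(libraries, locus.scaffold, locus.start, locus.end)
        if reads.empty:
            continue
        locus.size_class, locus.complexity, locus.five_prime_freq = classify_locus(reads)
        best: PhaseResult | None = None
        for reg in phase_registers:
            res = phase_score(reads, reg)
            if best is None or (res.phased and not best.phased) or (
                res.phased == best.phased and res.p_value < best.p_value
            ):
                best = res
        locus.phase_result = best
    return loci


def run_pipeline(
    libraries: list[SrnaLibrary],
    min_rpm: float = 2.0,
    island_pad: int = 75,
    min_libraries: int = 3,
    merge_gap: int = 25,
    min_rpm_rescue: float = 0.5,
) -> list[SrnaLocus]:
    """Full per-library discovery -> consensus -> locus annotation chain."""
    clusters = {
        lib.library_id: discover_clusters(lib, min_rpm=min_rpm, island_pad=island_pad)
        for lib in libraries
    }
    tissue_map = {lib.library_id: lib.tissue for lib in libraries}
    loci = consensus_loci(
        clusters,
        tissue_map,
        min_libraries=min_libraries,
        merge_gap=merge_gap,
        min_rpm_rescue=min_rpm_rescue,
    )
    return annotate_loci(loci, libraries)


def loci_to_frame(loci: list[SrnaLocus]) -> pd.DataFrame:
    """BED6+-style table of consensus loci (one row per locus)."""
    rows = []
    for loc in loci:
        ph = loc.phase_result
        rows.append(
            {
                "scaffold": loc.scaffold,
                "start": loc.start,
                "end": loc.end,
                "tissues": ",".join(sorted(loc.tissues_of_origin)),
                "max_rpm": max(loc.tissue_max_rpm.values()),
                "size_class": loc.size_class,
                "complexity": loc.complexity,
                "five_prime_U": (loc.five_prime_freq or {}).get("U"),
                "phase_register": ph.register if ph else None,
                "phase_score": ph.score if ph else None,
                "phase_p": ph.p_value if ph else None,
                "phased": ph.phased if ph else None,
            }
        )
    return pd.DataFrame(rows)
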
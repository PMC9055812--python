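"""Seeded synthetic-data generators with recorded planted truth.

Every downstream stage of the toolkit can be exercised without any
sequencing data: the generators emulate a compact plant genome with the
geometry of the pennycress assembly (gene-dense scaffold ends, TE-dense
pericentromeres), multi-tissue replicated sRNA libraries with planted
loci, hairpin candidates engineered to pass or fail individual curation
rules, negative-binomial expression counts with planted tissue
specificity, context-stratified methylation (CG > CHG > CHH, TE
hypermethylation, unmethylated gene bodies), bimodal contig-depth
mixtures, k-mer spectra, and genotypes with exponentially decaying LD.

All randomness flows from a single integer seed through one dedicated
numpy Generator stream per output type (``default_rng([seed, stream])``),
so adding a generator never shifts the draws of another. Identical
(config, seed) pairs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import ContigDepthTable, KmerHistogram
from .atlas import ExpressionMatrix
from .context import ANNOTATION_COLUMNS, TE_PREFIX, GenomeAnnotation
from .methylation import MethylationCalls
from .mirna import HairpinCandidate
from .popgen import GenotypeMatrix
from .srna import READ_COLUMNS, SrnaLibrary

# stream ids: one per output type
STREAMS = {
    "annotation": 1,
    "srna": 2,
    "hairpins": 3,
    "expression": 4,
    "methylation": 5,
    "contigs": 6,
    "kmers": 7,
    "genotypes": 8,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, STREAMS[stream]])


@dataclass
class PlantedLocus:
    """A planted sRNA locus with its expected downstream properties."""

    scaffold: str
    start: int
    end: int
    size_class: str = "23-24"  # or "20-22"
    phased: bool = False
    register: int = 24  # 21 or 24
    tissues_expressed: tuple[str, ...] = ()
    abundance_rpm: float = 20.0
    five_prime_u: float = 0.8  # probability of a 5' U

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.abundance_rpm <= 0:
            raise ValueError("abundance must be positive")
        if self.register not in (21, 24):
            raise ValueError("register must be 21 or 24")


@dataclass
class AnnotationParams:
    window: int = 100_000
    genes_per_mbp: float = 100.0
    edge_contrast: float = 4.0  # gene density lift at scaffold ends
    te_per_mbp: float = 150.0
    te_superfamily_weights: dict[str, float] = field(
        default_factory=lambda: {
            "Gypsy": 0.55,
            "Copia": 0.15,
            "LINE": 0.08,
            "Helitron": 0.06,
            "MuLE": 0.06,
            "other": 0.10,
        }
    )
    gene_len_mean: float = 2000.0
    gene_len_sigma: float = 0.4
    te_len_mean: float = 1500.0
    te_len_sigma: float = 0.7
    max_exons: int = 5
    n_te_embedded_genes: int = 5


@dataclass
class SrnaParams:
    tissues: tuple[str, ...] = ("leaf", "root", "inflorescence", "pollen")
    n_replicates_per_tissue: int = 3
    total_reads_per_library: int = 1_000_000
    n_planted_loci: int = 200
    locus_len_range: tuple[int, int] = (300, 600)
    abundance_rpm: float = 20.0
    fraction_private: float = 0.25  # loci expressed in a single tissue
    n_phased: int = 10
    off_register_fraction: float = 0.1
    noise_reads_per_library: int = 1000


@dataclass
class MethylationParams:
    # per-context mean levels for (TE body, gene body, background)
    te: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.92, "CHG": 0.65, "CHH": 0.30}
    )
    gene: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.04, "CHG": 0.03, "CHH": 0.02}
    )
    background: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.45, "CHG": 0.25, "CHH": 0.10}
    )
    mean_site_spacing: int = 25
    mean_depth: float = 8.0
    context_probs: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.25, "CHG": 0.25, "CHH": 0.50}
    )


@dataclass
class ExpressionParams:
    n_genes: int = 300
    tissues: tuple[str, ...] = (
        "root",
        "leaf",
        "inflorescence",
        "pollen",
        "green_seed",
        "silique",
    )
    n_replicates: int = 3
    n_single_tissue: int = 24  # planted across tissues round-robin
    n_uniform: int = 24
    n_graded: int = 24
    base_mean: float = 400.0
    dispersion: float = 0.05
    library_size: float = 1_000_000.0
    low_coverage_tissues: tuple[str, ...] = ("mature_seed", "old_green_silique")
    low_coverage_factor: float = 0.05


@dataclass
class LdParams:
    decay_scale_bp: float = 2000.0  # r^2 e-folding distance
    n_samples: int = 40
    n_markers: int = 2000
    mean_spacing_bp: float = 400.0
    allele_freq: float = 0.3
    missing_rate: float = 0.02


@dataclass
class ContigParams:
    true_genome_size: int = 20_000_000
    duplicated_fraction: float = 0.3  # extra length relative to true size
    single_depth: float = 30.0
    single_depth_sd: float = 2.0
    duplicated_depth: float = 15.0
    duplicated_depth_sd: float = 1.5
    contig_len_mean: float = 300_000.0
    n_busco: int = 40
    n_protected_low_depth: int = 2  # unique contigs living at half depth


@dataclass
class KmerParams:
    peak_depth: int = 30
    genome_size: int = 5_000_000
    peak_sd: float = 5.0
    error_kmer_mass: float = 0.1  # error observations relative to genomic


@dataclass
class SimulationConfig:
    """All generator parameters; ``seed`` fully determines every output."""

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (
        ("scaffold_1", 2_000_000),
        ("scaffold_2", 2_000_000),
    )
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    srna: SrnaParams = field(default_factory=SrnaParams)
    methylation: MethylationParams = field(default_factory=MethylationParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    ld: LdParams = field(default_factory=LdParams)
    contigs: ContigParams = field(default_factory=ContigParams)
    kmers: KmerParams = field(default_factory=KmerParams)
    planted_srna_loci: list[PlantedLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, length in self.genome:
            if length <= 0:
                raise ValueError(f"zero-length scaffold {name!r}")


# ------------------------------------------------------------- annotation
def _edge_profile(n_windows: int, contrast: float) -> np.ndarray:
    """U-shaped weights: high at both scaffold ends, low in the centre."""
    x = (np.arange(n_windows) + 0.5) / n_windows
    return 1.0 + contrast * (2.0 * np.abs(x - 0.5)) ** 2


def gen_annotation(config: SimulationConfig) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """Generate the genome annotation and the planted-truth table.

    Genes follow a telomere-biased density profile with exon/intron
    substructure; TEs follow the complementary (pericentromeric) profile
    with configured superfamily abundances. ``n_te_embedded_genes`` extra
    genes are placed fully inside dedicated TE bodies; the truth table
    lists their ids (``kind == "te_embedded_gene"``).
    """
    p = config.annotation
    rng = _rng(config.seed, "annotation")
    rows: list[dict] = []
    truth_rows: list[dict] = []
    gene_i = 0
    te_i = 0
    fams = sorted(p.te_superfamily_weights)
    fam_w = np.array([p.te_superfamily_weights[f] for f in fams], dtype=float)
    fam_p = fam_w / fam_w.sum() if fam_w.sum() > 0 else None

    for scaffold, length in config.genome:
        n_win = max(1, length // p.window)
        gene_w = _edge_profile(n_win, p.edge_contrast)
        te_w = gene_w.max() + 1.0 - gene_w  # complementary profile
        n_genes = int(round(p.genes_per_mbp * length / 1e6))
        n_tes = int(round(p.te_per_mbp * length / 1e6))
        gene_counts = rng.multinomial(n_genes, gene_w / gene_w.sum())
        te_counts = (
            rng.multinomial(n_tes, te_w / te_w.sum()) if n_tes > 0 else np.zeros(n_win, int)
        )

        occupied: list[tuple[int, int]] = []  # gene spans, kept sorted
        for w in range(n_win):
            w_lo = w * p.window
            w_hi = min((w + 1) * p.window, length)
            for _ in range(gene_counts[w]):
                glen = int(np.clip(rng.lognormal(np.log(p.gene_len_mean), p.gene_len_sigma), 300, 20_000))
                if w_hi - w_lo <= glen:
                    continue
                start = int(rng.integers(w_lo, w_hi - glen))
                end = start + glen
                if any(s < end and e > start for s, e in occupied):
                    continue  # skip overlapping placements
                occupied.append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                gid = f"gene_{gene_i:05d}"
                gene_i += 1
                rows.append(
                    {"scaffold": scaffold, "start": start, "end": end, "strand": strand, "type": "gene", "id": gid}
                )
                rows.extend(_gene_substructure(rng, scaffold, start, end, strand, gid, p.max_exons))

        occupied.sort()
        for w in range(n_win):
            w_lo = w * p.window
            w_hi = min((w + 1) * p.window, length)
            for _ in range(te_counts[w]):
                tlen = int(np.clip(rng.lognormal(np.log(p.te_len_mean), p.te_len_sigma), 100, 15_000))
                if w_hi - w_lo <= tlen:
                    continue
                start = int(rng.integers(w_lo, w_hi - tlen))
                end = start + tlen
                # never fully contain an existing gene by accident
                if any(start <= s and end >= e for s, e in occupied):
                    continue
                fam = fams[rng.choice(len(fams), p=fam_p)] if fam_p is not None else "other"
                rows.append(
                    {"scaffold": scaffold, "start": start, "end": end, "strand": "+", "type": TE_PREFIX + fam, "id": f"te_{te_i:06d}"}
                )
                te_i += 1

    # planted TE-embedded genes: a fresh TE with a gene strictly inside
    has_tes = fam_p is not None and (p.te_per_mbp > 0 or p.n_te_embedded_genes > 0)
    if p.n_te_embedded_genes > 0 and has_tes:
        all_genes = [(r["scaffold"], r["start"], r["end"]) for r in rows if r["type"] == "gene"]
        for k in range(p.n_te_embedded_genes):
            scaffold, length = config.genome[k % len(config.genome)]
            placed = False
            for _ in range(200):
                glen = int(rng.integers(400, 1200))
                margin = int(rng.integers(200, 500))
                tlen = glen + 2 * margin
                start = int(rng.integers(0, length - tlen))
                te_span = (start, start + tlen)
                if any(
                    s < te_span[1] and e > te_span[0]
                    for (sc, s, e) in all_genes
                    if sc == scaffold
                ):
                    continue
                gid = f"gene_te_{k:03d}"
                g_start = start + margin
                g_end = g_start + glen
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append(
                    {"scaffold": scaffold, "start": start, "end": start + tlen, "strand": "+", "type": TE_PREFIX + "MuLE", "id": f"te_{te_i:06d}"}
                )
                te_i += 1
                rows.append(
                    {"scaffold": scaffold, "start": g_start, "end": g_end, "strand": strand, "type": "gene", "id": gid}
                )
                rows.extend(_gene_substructure(rng, scaffold, g_start, g_end, strand, gid, p.max_exons))
                all_genes.append((scaffold, start, start + tlen))  # block the TE span
                truth_rows.append({"kind": "te_embedded_gene", "id": gid, "scaffold": scaffold, "start": g_start, "end": g_end})
                placed = True
                break
            if not placed:
                raise RuntimeError("could not place a TE-embedded gene; genome too dense")

    intervals = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).sort_values(
        ["scaffold", "start", "end"], kind="mergesort"
    ).reset_index(drop=True)
    annotation = GenomeAnnotation(intervals, dict(config.genome))
    truth = pd.DataFrame(truth_rows, columns=["kind", "id", "scaffold", "start", "end"])
    return annotation, truth


def _gene_substructure(
    rng: np.random.Generator,
    scaffold: str,
    start: int,
    end: int,
    strand: str,
    gid: str,
    max_exons: int,
) -> list[dict]:
    """Alternate exon/intron pieces spanning the gene."""
    n_exons = int(rng.integers(1, max_exons + 1))
    n_parts = 2 * n_exons - 1
    if end - start < n_parts * 30:
        n_exons, n_parts = 1, 1
    cuts = np.sort(rng.choice(np.arange(start + 1, end), size=n_parts - 1, replace=False)) if n_parts > 1 else np.array([], dtype=int)
    bounds = np.concatenate([[start], cuts, [end]])
    out = []
    for i in range(n_parts):
        kind = "exon" if i % 2 == 0 else "intron"
        out.append(
            {"scaffold": scaffold, "start": int(bounds[i]), "end": int(bounds[i + 1]), "strand": strand, "type": kind, "id": f"{gid}.{kind}{i // 2 + 1}"}
        )
    return out


# ------------------------------------------------------------------- sRNA
_SIZE_CLASS_LENGTHS = {"23-24": ([23, 24], [0.25, 0.75]), "20-22": ([20, 21, 22], [0.15, 0.7, 0.15])}


def default_planted_loci(config: SimulationConfig) -> list[PlantedLocus]:
    """Plant ``n_planted_loci`` non-overlapping loci per the sRNA params.

    Roughly 95% heterochromatic 23-24-nt loci, the rest 20-22-nt;
    ``n_phased`` loci are phased (24-nt register except every third,
    which uses 21 and the 20-22 class); ``fraction_private`` are
    tissue-private (round-robin), the rest expressed in all tissues.
    """
    p = config.srna
    rng = _rng(config.seed, "srna")
    loci: list[PlantedLocus] = []
    taken: dict[str, list[tuple[int, int]]] = {s: [] for s, _ in config.genome}
    genome = list(config.genome)
    for i in range(p.n_planted_loci):
        scaffold, length = genome[i % len(genome)]
        for _ in range(500):
            llen = int(rng.integers(p.locus_len_range[0], p.locus_len_range[1] + 1))
            start = int(rng.integers(0, length - llen))
            end = start + llen
            if any(s < end + 200 and e > start - 200 for s, e in taken[scaffold]):
                continue
            taken[scaffold].append((start, end))
            break
        else:
            raise RuntimeError("could not place planted locus; genome too small")
        phased = i < p.n_phased
        register = 21 if (phased and i % 3 == 2) else 24
        size_class = "20-22" if (register == 21 or (not phased and i % 20 == 19)) else "23-24"
        every = max(1, round(1 / p.fraction_private)) if p.fraction_private > 0 else 0
        if every and i % every == 0:
            tissues = (p.tissues[(i // every) % len(p.tissues)],)
        else:
            tissues = tuple(p.tissues)
        loci.append(
            PlantedLocus(
                scaffold=scaffold,
                start=start,
                end=end,
                size_class=size_class,
                phased=phased,
                register=register,
                tissues_expressed=tissues,
                abundance_rpm=p.abundance_rpm,
            )
        )
    return loci


def gen_srna_libraries(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[list[SrnaLibrary], pd.DataFrame]:
    """Simulate multi-tissue replicate sRNA libraries plus a truth table.

    Planted loci emit reads at their configured RPM in their configured
    tissues; background noise reads are scattered at sub-threshold
    abundance. The truth table records each planted locus's span, class,
    phasing and tissues.
    """
    p = config.srna
    if p.n_replicates_per_tissue < 1:
        raise ValueError("need at least one replicate per tissue")
    loci = config.planted_srna_loci or default_planted_loci(config)
    lengths = dict(config.genome)
    for locus in loci:
        if locus.scaffold not in lengths or locus.end > lengths[locus.scaffold]:
            raise ValueError(f"planted locus outside scaffold bounds: {locus}")
    libraries: list[SrnaLibrary] = []
    # sub-stream independent of the locus-placement draws, so explicitly
    # supplied planted loci see identical library noise
    lib_rng = np.random.default_rng([config.seed, STREAMS["srna"], 1])
    for tissue in p.tissues:
        for rep in range(1, p.n_replicates_per_tissue + 1):
            lib_id = f"{tissue}_{rep}"
            rows: list[dict] = []
            total = p.total_reads_per_library
            for locus in loci:
                if tissue not in locus.tissues_expressed:
                    continue
                expected = locus.abundance_rpm * total / 1e6
                n = int(lib_rng.poisson(expected))
                if n == 0:
                    continue
                rows.extend(_locus_reads(lib_rng, locus, n, p.off_register_fraction))
            # background noise: solitary sub-threshold reads
            for _ in range(p.noise_reads_per_library):
                scaffold, length = config.genome[int(lib_rng.integers(len(config.genome)))]
                rlen = int(lib_rng.integers(20, 25))
                start = int(lib_rng.integers(0, length - rlen))
                rows.append(
                    {"scaffold": scaffold, "start": start, "end": start + rlen, "length": rlen, "strand": "+" if lib_rng.random() < 0.5 else "-", "count": 1, "five_prime": "ACGU"[int(lib_rng.integers(4))]}
                )
            reads = pd.DataFrame(rows, columns=READ_COLUMNS).sort_values(
                ["scaffold", "start"], kind="mergesort"
            ).reset_index(drop=True)
            libraries.append(
                SrnaLibrary(
                    library_id=lib_id,
                    tissue=tissue,
                    replicate=rep,
                    reads=reads,
                    total_mapped_reads=total,
                )
            )
    truth = pd.DataFrame(
        [
            {
                "scaffold": l.scaffold,
                "start": l.start,
                "end": l.end,
                "size_class": l.size_class,
                "phased": l.phased,
                "register": l.register,
                "tissues": ",".join(l.tissues_expressed),
                "abundance_rpm": l.abundance_rpm,
                "meets_thresholds": l.abundance_rpm >= 2.0,
            }
            for l in loci
        ]
    )
    return libraries, truth


def _locus_reads(
    rng: np.random.Generator, locus: PlantedLocus, n: int, off_register: float
) -> list[dict]:
    lengths, probs = _SIZE_CLASS_LENGTHS[locus.size_class]
    rows = []
    span = locus.end - locus.start
    for _ in range(n):
        if locus.phased:
            rlen = locus.register
            if rng.random() < off_register:
                start = locus.start + int(rng.integers(0, span - rlen))
            else:
                n_phases = (span - rlen) // locus.register
                start = locus.start + int(rng.integers(0, n_phases + 1)) * locus.register
            strand = "+"
        else:
            rlen = int(rng.choice(lengths, p=probs))
            start = locus.start + int(rng.integers(0, span - rlen))
            strand = "+" if rng.random() < 0.5 else "-"
        five = "U" if rng.random() < locus.five_prime_u else "ACG"[int(rng.integers(3))]
        rows.append(
            {"scaffold": locus.scaffold, "start": start, "end": start + rlen, "length": rlen, "strand": strand, "count": 1, "five_prime": five}
        )
    return rows


# ---------------------------------------------------------------- hairpins
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _build_hairpin(
    rng: np.random.Generator,
    pre_pad: int,
    duplex_ops: list[tuple],
    post_pad: int,
    loop: str = "..........",
    mature_end_bulge: int = 0,
) -> tuple[str, str, tuple[int, int]]:
    """Assemble sequence + dot-bracket from a duplex opposition recipe.

    ``duplex_ops`` describe the mature-arm region 5'->3': ("p", k) paired
    run, ("m",) 1:1 mismatch, ("bm", k) bulge on the mature strand,
    ("bs", k) bulge on the star strand, ("il", a, b) internal loop.
    ``mature_end_bulge`` appends unpaired nts to the mature 3' end
    (inside the mature interval) to distort the overhang.
    """
    left: list[str] = ["("] * pre_pad
    right_rev: list[str] = [")"] * pre_pad  # built outermost-first
    mature_start = pre_pad
    for op in duplex_ops:
        if op[0] == "p":
            left += ["("] * op[1]
            right_rev += [")"] * op[1]
        elif op[0] == "m":
            left += ["."]
            right_rev += ["."]
        elif op[0] == "bm":
            left += ["."] * op[1]
        elif op[0] == "bs":
            right_rev += ["."] * op[1]
        elif op[0] == "il":
            left += ["."] * op[1]
            right_rev += ["."] * op[2]
        else:
            raise ValueError(f"unknown op {op}")
    left += ["."] * mature_end_bulge
    mature_end = len(left)
    left += ["("] * post_pad
    right_rev += [")"] * post_pad
    structure = "".join(left) + loop + "".join(reversed(right_rev))
    seq = _sequence_for(rng, structure)
    return seq, structure, (mature_start, mature_end)


def _sequence_for(rng: np.random.Generator, structure: str) -> str:
    from .mirna import parse_structure

    table = parse_structure(structure)
    seq = [str(b) for b in rng.choice(list("ACGU"), size=len(structure))]
    for i, j in enumerate(table):
        if j > i:
            seq[j] = _COMP[seq[i]]
    return "".join(seq)


def _star_interval(structure: str, mature: tuple[int, int]) -> tuple[int, int]:
    from .mirna import extract_duplex

    dummy = HairpinCandidate("tmp", "A" * len(structure), structure, [], mature)
    return extract_duplex(dummy).star


def gen_hairpin_set(
    config: SimulationConfig,
) -> tuple[list[HairpinCandidate], pd.DataFrame]:
    """Hairpin fixtures engineered to pass all rules or fail exactly one.

    Returns the candidates plus an expected-verdict table with columns
    ``id, expect_pass, failing_criterion``. Includes boundary fixtures
    at 300/301 nt hairpin length and 0.75/0.74 duplex read fraction.
    """
    rng = _rng(config.seed, "hairpins")
    candidates: list[HairpinCandidate] = []
    expected_rows: list[dict] = []

    def mk_reads(structure, mature, frac_num=95, frac_den=100):
        star = _star_interval(structure, mature)
        other_start = max(0, len(structure) // 2 - 10)
        other = (other_start, min(len(structure), other_start + 21))
        n_other = frac_den - frac_num
        reads = [
            (mature[0], mature[1], frac_num - 15),
            (star[0], star[1], 15),
        ]
        if n_other:
            reads.append((other[0], other[1], n_other))
        return reads

    def add(name, seq, structure, mature, reads, expect_pass, failing=None):
        candidates.append(HairpinCandidate(name, seq, structure, reads, mature))
        expected_rows.append(
            {"id": name, "expect_pass": expect_pass, "failing_criterion": failing}
        )

    base_ops = [("p", 8), ("m",), ("p", 12)]  # 21-nt mature, 1 mismatch

    # pass-all: 21-nt mature, one mismatch, clean overhangs, 95% duplex reads
    seq, st, mat = _build_hairpin(rng, 12, base_ops, 20)
    add("pass_all", seq, st, mat, mk_reads(st, mat), True)

    # length boundary: exactly 300 nt passes, 301 fails only hairpin_length
    for total, name, ok in ((300, "pass_len300", True), (301, "fail_length", False)):
        # stem length chosen so 2*(pad+21+post) + loop == total
        loop_len = 10 + (total % 2)
        arm = (total - loop_len) // 2
        post = arm - 12 - 21
        seq, st, mat = _build_hairpin(rng, 12, [("p", 21)], post, loop="." * loop_len)
        add(name, seq, st, mat, mk_reads(st, mat), ok, None if ok else "hairpin_length")

    # duplex-read fraction boundary: 0.75 passes, 0.74 fails
    seq, st, mat = _build_hairpin(rng, 12, base_ops, 20)
    add("pass_duplex75", seq, st, mat, mk_reads(st, mat, 75, 100), True)
    seq, st, mat = _build_hairpin(rng, 12, base_ops, 20)
    add(
        "fail_duplex_fraction",
        seq,
        st,
        mat,
        mk_reads(st, mat, 74, 100),
        False,
        "duplex_read_fraction",
    )

    # mature length out of range (19 nt)
    seq, st, mat = _build_hairpin(rng, 12, [("p", 19)], 20)
    add("fail_mature_length", seq, st, mat, mk_reads(st, mat), False, "mature_length")

    # six 1:1 mismatches
    ops = [("p", 3)] + [("m",), ("p", 2)] * 6
    seq, st, mat = _build_hairpin(rng, 12, ops, 20)
    add("fail_mismatch", seq, st, mat, mk_reads(st, mat), False, "mismatch_count")

    # four asymmetric-bulge nucleotides (two 2-nt bulges on the mature strand)
    ops = [("p", 5), ("bm", 2), ("p", 6), ("bm", 2), ("p", 6)]
    seq, st, mat = _build_hairpin(rng, 12, ops, 20)
    add("fail_bulge", seq, st, mat, mk_reads(st, mat), False, "asymmetric_bulge_count")

    # one internal loop (2:2)
    ops = [("p", 8), ("il", 2, 2), ("p", 11)]
    seq, st, mat = _build_hairpin(rng, 12, ops, 20)
    add("fail_internal_loop", seq, st, mat, mk_reads(st, mat), False, "internal_loops")

    # 3' overhang distorted: mature 3' tail unpaired
    seq, st, mat = _build_hairpin(rng, 12, [("p", 20)], 20, mature_end_bulge=1)
    add("fail_overhang", seq, st, mat, mk_reads(st, mat), False, "three_prime_overhang")

    # two terminal loops in the mature-star span (two side stems turn the
    # main loop into a multiloop with two hairpin loops)
    seq, st, mat = _build_hairpin(
        rng, 12, [("p", 21)], 20, loop=".((....)).((....))."
    )
    add("fail_multi_loop", seq, st, mat, mk_reads(st, mat), False, "single_stem")

    expected = pd.DataFrame(expected_rows)
    return candidates, expected


# -------------------------------------------------------------- expression
def gen_expression_counts(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial counts with planted tissue-specificity labels.

    Plants single-tissue genes (expressed in exactly one tissue),
    uniform genes, and graded intermediates; adds one low-coverage
    sample per configured low-coverage tissue (at ``low_coverage_factor``
    of the normal library size) and pre-lists them for exclusion.
    """
    p = config.expression
    if len(p.tissues) < 2 or p.n_replicates < 2:
        raise ValueError("need >=2 tissues and >=2 replicates")
    rng = _rng(config.seed, "expression")
    genes = [f"gene_{i:05d}" for i in range(p.n_genes)]
    labels = []
    means = np.zeros((p.n_genes, len(p.tissues)))
    for g in range(p.n_genes):
        if g < p.n_single_tissue:
            t = g % len(p.tissues)
            means[g, t] = p.base_mean * float(rng.uniform(2.0, 6.0))
            labels.append(f"single:{p.tissues[t]}")
        elif g < p.n_single_tissue + p.n_uniform:
            means[g, :] = p.base_mean * float(rng.uniform(0.5, 2.0))
            labels.append("uniform")
        elif g < p.n_single_tissue + p.n_uniform + p.n_graded:
            t = g % len(p.tissues)
            base = p.base_mean * float(rng.uniform(0.5, 1.5))
            means[g, :] = base
            means[g, t] = base * float(rng.uniform(4.0, 8.0))
            labels.append(f"graded:{p.tissues[t]}")
        else:
            means[g, :] = p.base_mean * rng.lognormal(0.0, 0.6, size=len(p.tissues))
            labels.append("background")

    samples: list[str] = []
    tissue_map: dict[str, str] = {}
    cols: dict[str, np.ndarray] = {}
    for t_i, tissue in enumerate(p.tissues):
        for rep in range(1, p.n_replicates + 1):
            name = f"{tissue}_{rep}"
            lib_factor = float(rng.uniform(0.7, 1.3))
            mu = means[:, t_i] * lib_factor
            cols[name] = _nb_draw(rng, mu, p.dispersion)
            samples.append(name)
            tissue_map[name] = tissue
    excluded = []
    for tissue in p.low_coverage_tissues:
        name = f"{tissue}_1"
        mu = means.mean(axis=1) * p.low_coverage_factor
        cols[name] = _nb_draw(rng, mu, p.dispersion)
        samples.append(name)
        tissue_map[name] = tissue
        excluded.append(name)

    counts = pd.DataFrame(cols, index=genes)
    truth = pd.DataFrame({"gene": genes, "label": labels}).set_index("gene")
    return (
        ExpressionMatrix(counts=counts, sample_tissues=tissue_map, excluded_samples=excluded),
        truth,
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    out = np.zeros(len(mu), dtype=np.int64)
    pos = mu > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mu[pos])
        return out
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu[pos] / shape)
    out[pos] = rng.poisson(lam)
    return out


# ------------------------------------------------------------- methylation
def gen_methylation_calls(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> MethylationCalls:
    """Binomial per-cytosine calls at feature-dependent context means.

    CG > CHG > CHH holds in every compartment by construction; TE bodies
    are hypermethylated and gene bodies essentially unmethylated (no
    gene-body methylation). Depths are Poisson with some sites below 3x.
    """
    p = config.methylation
    for ctx_means in (p.te, p.gene, p.background):
        for v in ctx_means.values():
            if not 0 <= v <= 1:
                raise ValueError("context means must lie in [0, 1]")
    rng = _rng(config.seed, "methylation")
    contexts = sorted(p.context_probs)
    ctx_p = np.array([p.context_probs[c] for c in contexts])
    ctx_p = ctx_p / ctx_p.sum()
    frames = []
    genes = annotation.genes
    tes = annotation.tes
    for scaffold, length in annotation.scaffold_lengths.items():
        n_sites = int(length / p.mean_site_spacing)
        pos0 = np.sort(rng.choice(length, size=n_sites, replace=False))
        ctx = rng.choice(contexts, size=n_sites, p=ctx_p)
        strand = np.where(rng.random(n_sites) < 0.5, "+", "-")
        in_gene = _in_any(pos0, genes[genes["scaffold"] == scaffold])
        in_te = _in_any(pos0, tes[tes["scaffold"] == scaffold])
        level = np.empty(n_sites)
        for c in contexts:
            m = ctx == c
            level[m] = p.background[c]
            level[m & in_gene] = p.gene[c]
            level[m & in_te] = p.te[c]  # TE status wins over gene
        depth = rng.poisson(p.mean_depth, size=n_sites)
        keep = depth > 0
        meth = rng.binomial(depth[keep], level[keep])
        frames.append(
            pd.DataFrame(
                {
                    "scaffold": scaffold,
                    "position": pos0[keep] + 1,
                    "strand": strand[keep],
                    "context": ctx[keep],
                    "methylated": meth,
                    "total": depth[keep],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return MethylationCalls(records)


def _in_any(pos: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Membership of positions in a union of intervals (vectorized sweep)."""
    if intervals.empty:
        return np.zeros(len(pos), dtype=bool)
    iv = intervals.sort_values("start")
    starts = iv["start"].to_numpy()
    ends = np.maximum.accumulate(iv["end"].to_numpy())
    i = np.searchsorted(starts, pos, side="right")
    ok = i > 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = ends[i[ok] - 1] > pos[ok]
    return out


# ----------------------------------------- contigs, k-mers and genotypes
def gen_contigs_kmers_genotypes(
    config: SimulationConfig,
) -> tuple[ContigDepthTable, KmerHistogram, GenotypeMatrix, pd.DataFrame]:
    """Assembly-QC and population inputs plus the contig truth table.

    Contig depths follow a two-mode mixture (duplicated contigs at ~half
    depth); single-status BUSCOs land mostly on full-depth contigs plus a
    few genuinely unique low-depth contigs that the purge must protect.
    The k-mer spectrum has an error spike at low multiplicity and a
    near-Gaussian main peak. Genotype dosages follow a copy-with-mutation
    process along markers giving exactly exponential r^2 decay at the
    configured scale. Truth table columns: id, duplicated.
    """
    cp = config.contigs
    if not 0 <= cp.duplicated_fraction < 1:
        raise ValueError("duplicated fraction must be in [0, 1)")
    rng = _rng(config.seed, "contigs")
    rows = []
    truth_rows = []
    total_single = 0
    i = 0
    while total_single < cp.true_genome_size:
        length = int(rng.lognormal(np.log(cp.contig_len_mean), 0.5))
        length = min(length, cp.true_genome_size - total_single) if (
            cp.true_genome_size - total_single < length
        ) else length
        depth = max(1.0, rng.normal(cp.single_depth, cp.single_depth_sd))
        rows.append({"id": f"ctg_{i:04d}", "length": length, "depth": round(depth, 2), "n_busco_single": 0, "n_busco_duplicated": 0})
        truth_rows.append({"id": f"ctg_{i:04d}", "duplicated": False})
        total_single += length
        i += 1
    total_dup = 0
    dup_target = int(cp.true_genome_size * cp.duplicated_fraction)
    while total_dup < dup_target:
        length = int(rng.lognormal(np.log(cp.contig_len_mean / 2), 0.5))
        length = min(length, dup_target - total_dup) if (dup_target - total_dup < length) else length
        depth = max(1.0, rng.normal(cp.duplicated_depth, cp.duplicated_depth_sd))
        rows.append({"id": f"ctg_{i:04d}", "length": length, "depth": round(depth, 2), "n_busco_single": 0, "n_busco_duplicated": 1})
        truth_rows.append({"id": f"ctg_{i:04d}", "duplicated": True})
        total_dup += length
        i += 1
    contigs = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    # sprinkle single-status BUSCOs over full-depth contigs
    single_ids = truth.loc[~truth["duplicated"], "id"].to_numpy()
    hosts = rng.choice(single_ids, size=min(cp.n_busco, len(single_ids)), replace=False)
    for h in hosts:
        contigs.loc[contigs["id"] == h, "n_busco_single"] += 1
    # genuinely unique contigs living at duplicated-mode depth: protected
    for k in range(cp.n_protected_low_depth):
        cid = f"ctg_{i:04d}"
        length = int(rng.lognormal(np.log(cp.contig_len_mean / 3), 0.3))
        depth = max(1.0, rng.normal(cp.duplicated_depth, cp.duplicated_depth_sd))
        contigs = pd.concat(
            [contigs, pd.DataFrame([{"id": cid, "length": length, "depth": round(depth, 2), "n_busco_single": 1, "n_busco_duplicated": 0}])],
            ignore_index=True,
        )
        truth = pd.concat(
            [truth, pd.DataFrame([{"id": cid, "duplicated": False}])], ignore_index=True
        )
        i += 1
    table = ContigDepthTable(contigs)

    hist = _gen_kmer_histogram(config)
    geno = _gen_genotypes(config)
    return table, hist, geno, truth


def _gen_kmer_histogram(config: SimulationConfig) -> KmerHistogram:
    kp = config.kmers
    rng = _rng(config.seed, "kmers")
    lam = kp.peak_depth
    m = np.arange(1, int(3 * lam) + 1)
    main = np.exp(-0.5 * ((m - lam) / kp.peak_sd) ** 2)
    main_obs_target = kp.genome_size * lam  # total genomic k-mer observations
    main = main / (m * main).sum() * main_obs_target
    err = np.zeros_like(main)
    err_region = m <= max(3, lam // 6)
    err[err_region] = np.exp(-1.2 * m[err_region])
    err = err / (m * err).sum() * (kp.error_kmer_mass * main_obs_target)
    counts = np.round(main + err).astype(np.int64)
    return KmerHistogram(m, counts, k=101)


def _gen_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    lp = config.ld
    rng = _rng(config.seed, "genotypes")
    gaps = rng.exponential(lp.mean_spacing_bp, size=lp.n_markers).astype(int) + 1
    pos = np.cumsum(gaps)
    # copy-with-mutation haplotypes: corr(h_m, h_{m+1}) = exp(-gap / (2 s)),
    # so r^2 between dosages decays as exp(-d / s) exactly.
    copy_p = np.exp(-gaps[1:] / (2.0 * lp.decay_scale_bp))
    n_hap = 2 * lp.n_samples
    hap = np.zeros((lp.n_markers, n_hap), dtype=np.int8)
    hap[0] = rng.random(n_hap) < lp.allele_freq
    for mI in range(1, lp.n_markers):
        fresh = rng.random(n_hap) >= copy_p[mI - 1]
        hap[mI] = np.where(fresh, rng.random(n_hap) < lp.allele_freq, hap[mI - 1])
    dosage = (hap[:, : lp.n_samples] + hap[:, lp.n_samples :]).astype(float)
    miss = rng.random(dosage.shape) < lp.missing_rate
    dosage[miss] = np.nan
    return GenotypeMatrix(
        positions=pd.DataFrame({"scaffold": "scaffold_1", "position": pos}),
        dosages=dosage,
        samples=[f"acc_{j:02d}" for j in range(lp.n_samples)],
    )
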
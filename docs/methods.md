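# Methods

`cressomics` implements the downstream computational procedures that turn a
field-pennycress (*Thlaspi arvense*) genome resource into annotations and
summaries: consensus small-RNA locus annotation, miRNA hairpin curation,
genomic feature context, whole-genome bisulphite (WGBS) summaries, a Tau
tissue-specificity expression atlas, assembly QC, and population-genetic
summaries. Every stage can be exercised end-to-end on seeded synthetic data
with planted truth; no sequencing data is required.

## Consensus sRNA locus annotation (`srna`)

Coordinates are 0-based half-open (BED native) throughout; GFF3 is converted
on I/O. Per library, aligned 20–24-nt reads whose gaps are at most the island
pad (default 75 nt, the de-novo clustering default of common sRNA tools) are
merged into islands, and islands below 2 RPM are discarded. RPM uses the
library's total mapped 20–24-nt reads as denominator.

The consensus stage works per tissue: an interval survives where clusters
from at least `min_libraries` (default 3) of that tissue's replicate
libraries overlap (a multi-intersection, implemented as an event sweep and
verified against a per-base vote oracle). Survivors separated by gaps of at
most 25 nt are padded together — merge-distance semantics, i.e. a 25-nt gap
merges and a 26-nt gap does not, matching the `-d` behaviour of the merge
utility this emulates. Per-tissue loci whose maximum summed cluster RPM over
all of the tissue's libraries is below 0.5 are removed. Finally per-tissue
loci are unioned across tissues (overlapping or book-ended intervals merge),
retaining the tissue-of-origin set. Whether "at least three libraries" counts
within a tissue or across tissues is ambiguous in the source protocol; this
implementation counts within a tissue, with `min_libraries` configurable.

Locus metrics: the size class is "23-24" (heterochromatic siRNA-like) when at
least 80% of copy-weighted read mass is 23–24 nt, "20-22" at the analogous
threshold, else "mixed" (the 80% dominance cut is this package's choice; the
three-way classification makes the ambiguity explicit). Complexity is
distinct (start, length, strand) positions divided by total read copies.
5' nucleotide frequencies are copy-weighted over A/C/G/U (T normalised to U).

**Phasing.** phasiRNA loci show periodic 5'-end accumulation at a fixed
register (21 or 24 nt). No standard test statistic exists for the source
protocol, so the package uses its own: among reads of exactly the register
length, the score is the largest fraction of 5'-end mass on a single register
offset; the p-value is the binomial tail of that best offset under a uniform
null, Bonferroni-corrected by the register; a locus is phased when p < 0.05
and score ≥ 0.5 (both configurable). This is deliberately conservative: with
50 reads the null maximum offset fraction almost never approaches 0.5, so
the empirical type-I rate is far below the nominal 0.05 while power against
planted phased loci with 10% off-register noise exceeds 95%.

## miRNA curation (`mirna`)

Candidates are screened with hard rules on the precursor and on the
miRNA/miRNA\* duplex: hairpin length ≤ 300 nt; a single stem-loop across the
mature–star span; ≥ 75% of copy-weighted hairpin reads belonging to the
duplex (each read matched to the mature or star interval with ±2 nt end
slack, a common curation convention); mature length 20–24 nt; at most five
mismatched positions of which at most three are nucleotides in asymmetric
bulges; no internal loops; and 2-nt 3' overhangs on both duplex ends.

Opposition accounting: a stretch of `a` unpaired nucleotides on the mature
strand facing `b` unpaired on the star strand contributes — an internal loop
if `a ≥ 2 and b ≥ 2` (disallowed outright); otherwise `min(a, b)` mismatches
plus `|a − b|` asymmetric-bulge nucleotides. The mismatch criterion counts
mismatches *plus* bulge nucleotides, so the three-bulge-nucleotide allowance
is a subset of the five-mismatch allowance; this is the only reading under
which "five mismatched bases, only three of which are in asymmetric bulges"
is internally consistent.

The star interval is the span of positions pairing with the mature, shifted
by the canonical 2-nt Dicer offset; antiparallel pairing makes the shift
`[qmin+2, qmax+3)` regardless of which arm carries the mature. 3' overhangs
are then `2 +` the unpaired mature tail at each duplex end, so a 2/2 overhang
is equivalent to both mature termini being paired. Secondary structure is an
input (any folding engine's dot-bracket); no folding is implemented. When the
hairpin terminus truncates an overhang, the both-ends requirement can be
relaxed via `require_both_overhangs=False`.

## Feature context (`context`)

Density tracks count features per tiling window (1 Mbp default) by interval
midpoint, so a feature straddling a boundary is counted exactly once. The
gene-density partition thresholds windows at the *mean* per-window count
(strictly above → enriched), reporting the median alongside; the mean is the
classifier because the source procedure defines enrichment relative to the
mean even though it quotes both statistics (the quoted mean ≫ median pair is
surprising; the package computes both and takes no stance).

Locus–annotation intersection assigns each locus the first class in a
precedence list (exon > intron > TE > intergenic by default) it overlaps by
≥ 1 bp. Distance-to-nearest reports 0 for overlap, otherwise the minimum gap
on the same scaffold, with a 1.5-kbp proximity fraction. TE-contained genes
are genes whose full span lies within a single TE interval, with a MuLE
(Mutator-like) subset flagged as Pack-MULE candidates.

Ancestral-karyotype block painting takes per-gene ortholog block labels
(A–X) in gene order and finds non-overlapping segments with at least
`min_run` labelled genes whose majority label reaches `1 − max_dissent` of
the labelled genes; unlabelled genes never break a run. Among valid
segmentations the exact dynamic program maximizes labelled-gene coverage
(ties: fewer segments, leftmost). The smoothing parameters are this module's
own; the original assignment was synteny-tool based and partly manual.

## WGBS summaries (`methylation`)

Input is per-cytosine counts (scaffold, 1-based position, strand, context
CG/CHG/CHH, methylated, total), the dialect emitted by common bisulphite
callers. Sites below 3× coverage are removed first. Two genome-wide measures
are always reported because the "percent of cytosines methylated" figure in
survey papers is ambiguous: the coverage-weighted level Σm/Σt, and the
fraction of sites whose per-site level clears a call threshold (default
0.5). Symmetric CG/CHG sites are not collapsed across strands by default;
`merge_strands()` implements the alternative. Window tracks use 200-kbp
tiles; empty windows are missing, never zero.

Metaprofiles cut each 2-kb flank into 80 fixed 25-bp bins and the feature
body into 40 proportional bins (each cytosine assigned by its relative body
position, so short features still contribute); minus-strand features are
reversed so the axis runs 5'→3'. Bin values are weighted levels pooled over
all features.

## Expression atlas (`atlas`)

Between-sample normalization is the trimmed mean of M-values (TMM):
reference = the sample whose upper-quartile count fraction is closest to the
mean upper quartile; gene-wise log2 ratios against the reference are trimmed
by 30% (M) and 5% (A) and averaged with asymptotic binomial precision
weights; factors are rescaled to geometric mean 1. The implementation
reproduces edgeR's `calcNormFactors(method="TMM")` to ~1e-6 (cross-checked
in the test suite via Rscript). Normalized values are TMM-scaled counts per
million rather than counts rescaled to the mean library size: CPM makes Tau
exactly invariant under a global rescaling of all libraries, which the
mean-library-size convention breaks once the log transform is applied.

Tau: per-tissue means of normalized expression are log2(x+1) transformed
(the transform used by the common Tau implementation; switchable), scaled by
the per-gene maximum, and τ = Σ(1 − x̂ᵢ)/(n − 1). Genes with zero maximal
expression are *missing*, not 0. Classes are [0, 0.2) low, [0.2, 0.8)
intermediate, [0.8, 1] high; per tissue the top-k (default 30) most
expressed genes among τ ≥ 0.8 are reported with log2 expression relative to
the per-gene cross-tissue mean. Exclusion of low-coverage samples is
configuration (a sample list), not hard-coded tissue names. The quantile
normalization step of some Tau implementations is deliberately not
replicated.

## Assembly QC (`assembly`)

Genome size = total k-mer observations / peak depth, after discarding the
error region below the spectrum's first local minimum (or an explicit
cutoff). The single-copy fraction is the observation mass within
[peak/2, 3·peak/2] of the retained total — this window is the package's own
operationalization. Depth modes come from a length-weighted Gaussian KDE of
per-contig mean depth, reporting local maxima and the length mass below the
inter-mode valley.

The duplicate purge emulates manual curation of an over-assembled haploid
genome: contigs sorted by ascending depth are removed consecutively until
retained length falls within target × (1 + 2%) — the tolerance band
operationalizes "an approximation of the estimated genome size" — while any
contig carrying a single-status BUSCO is skipped in favour of the next
lowest-depth unprotected contig. Ties break by (depth, length descending,
id). If the protected length alone exceeds the band, everything protected is
kept and the report flags the overflow. Per-contig mean depth is used (the
per-window alternative is out of scope).

## Population summaries (`popgen`)

Variant-class summaries drop records with quality-by-depth (QD) below 2000
(records lacking QD are kept), then report per-class counts and one-decimal
percentages (numpy half-even rounding) plus an exonic effect breakdown of
consumed effect labels (effect classification itself is never computed
here). LD is the squared Pearson correlation of 0/1/2 dosages over
pairwise-complete samples for marker pairs within a 40-marker sliding index
window — composite LD, which for highly selfing inbred accessions is nearly
the haplotype r². Decay is summarized by a LOESS fit (span 0.3) of r² on
distance evaluated on a fixed grid; the crossing distance is the first grid
point (linearly interpolated) where the fit reaches r² ≤ 0.2. A separate
estimator fits a·exp(−d/s)+c to binned means, the floor c absorbing the
finite-sample upward bias of r̂².

## Synthetic data (`simulate`)

All randomness flows from one integer seed through one dedicated numpy
Generator stream per output type, so adding a generator never shifts
another's draws; identical (config, seed) pairs are byte-identical on disk.
The defaults describe the study conditions the tests exercise:

- **Genome/annotation**: 2 scaffolds × 2 Mbp; gene density U-shaped (high at
  scaffold ends), TE density complementary (pericentromeric), superfamily
  weights dominated by Gypsy, then Copia/LINE/Helitron/MuLE; 5 genes planted
  fully inside dedicated MuLE bodies (random TEs are rejected if they would
  fully contain an existing gene, so planted containment is exact truth).
- **sRNA libraries**: 4 tissues × 3 replicates, 1e6 mapped reads per
  library, 200 planted loci of 300–600 bp at 20 RPM (~95% 23–24-nt class,
  1 in 4 tissue-private, 10 phased with 10% off-register reads at exact
  register multiples), plus 1000 single-copy background noise reads per
  library (~1 RPM islands, below every threshold). The noise level is a free
  parameter chosen so solitary reads stay sub-threshold while occasional
  2-read islands still exercise the RPM floor.
- **Hairpins**: one candidate engineered to fail each curation rule
  (including 300/301-nt and 0.75/0.74 duplex-fraction boundary fixtures) and
  passing fixtures; structures are constructed dot-brackets with
  complementary sequences, not folded.
- **Expression**: 6 tissues × 3 replicates, 300 genes (24 single-tissue, 24
  uniform, 24 graded, rest background), gamma-Poisson counts with dispersion
  0.05, plus one 5%-size sample for each of two low-coverage tissues to
  exercise the exclusion rule.
- **Methylation**: per-context means ordered CG > CHG > CHH in every
  compartment, TE ≫ background ≫ gene body (no gene-body methylation);
  binomial draws at Poisson(8) depth so some sites fall below 3×.
- **Contigs/k-mers/genotypes**: contig depths from a two-mode mixture
  (duplicated mode at half depth, 30% extra length), single BUSCOs mostly on
  full-depth contigs plus two genuinely unique half-depth contigs the purge
  must protect; a dense k-mer spectrum with an error spike and a Gaussian
  main peak scaled so retained observations equal size × peak; genotypes
  from a copy-with-mutation haplotype process whose dosage r² decays exactly
  as exp(−d/s) with s = 2 kbp over 2000 markers × 40 samples.

What the generators do *not* emulate: read sequences (no FASTQ), alignment
artefacts, bisulphite conversion errors, multi-mapping, batch effects, or
realistic TE nesting. Passing recovery tests therefore demonstrates the
correctness of the downstream logic under the stated generative model, not
robustness to upstream noise sources of real libraries.

## Numerical choices and edge cases

- Empty inputs raise (classify on zero reads, distance against an empty
  target set, zero-length scaffolds); "too few reads" in phasing returns an
  unphased result with a reason code rather than raising.
- Contexts/windows with no sites are missing values, never zeros.
- Percentages round half-even to one decimal; locus/cluster output is sorted
  and deterministic; purge ties break lexicographically.
- The published exon fraction of variants (661 156 of 13 224 528 quoted as
  2.9%) is arithmetically ~5.0%; the summary reports raw counts so users can
  apply either reading.

## Problem sizes

The bundled tests and the acceptance script run the full synthetic study at
the sizes above (4-Mbp genome, 12 sRNA libraries, 10 000 null loci for the
phasing type-I simulation, 20 000 LD pairs), which completes in a few
minutes on one CPU. All sizes scale through `SimulationConfig`.
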
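"""Plain-text I/O for every table the toolkit consumes or produces.

Dialects:

* annotation — GFF3 (``gene``/``exon``/``intron``/``transposable_element``
  with a ``superfamily`` attribute); coordinates converted to/from the
  package's 0-based half-open convention on the fly.
* sRNA reads — BED-like TSV: scaffold, start, end, length, strand,
  count, five_prime; library metadata in ``#key=value`` header lines.
* methylation — TSV: scaffold, 1-based position, strand, context,
  methylated, total (MethylDackel-adjacent).
* counts — genes x samples TSV; groups as a two-column sample/tissue TSV.
* hairpins — FASTA plus a structure TSV and a read-stack TSV.
* contigs / k-mer histogram — TSV.
* genotypes — minimal VCF (CHROM, POS, REF, ALT, GT per sample).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly import ContigDepthTable, KmerHistogram
from .atlas import ExpressionMatrix
from .context import ANNOTATION_COLUMNS, TE_PREFIX, GenomeAnnotation
from .methylation import CALL_COLUMNS, MethylationCalls
from .mirna import HairpinCandidate
from .popgen import GenotypeMatrix
from .srna import READ_COLUMNS, SrnaLibrary


# ---------------------------------------------------------------- annotation
def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.scaffold_lengths.items():
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for _, r in annotation.intervals.iterrows():
            ftype = r["type"]
            attrs = [f"ID={r['id']}"]
            if ftype.startswith(TE_PREFIX):
                attrs.append(f"superfamily={ftype[len(TE_PREFIX):]}")
                ftype = "transposable_element"
            fh.write(
                f"{r['scaffold']}\tcressomics\t{ftype}\t{r['start'] + 1}\t{r['end']}"
                f"\t.\t{r['strand']}\t.\t{';'.join(attrs)}\n"
            )


def read_gff3(path: str | Path) -> GenomeAnnotation:
    lengths: dict[str, int] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, name, _, length = line.split()
                lengths[name] = int(length)
                continue
            if not line or line.startswith("#"):
                continue
            scaf, _, ftype, start, end, _, strand, _, attr_s = line.split("\t")
            attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv)
            if ftype == "transposable_element":
                ftype = TE_PREFIX + attrs.get("superfamily", "other")
            rows.append(
                {
                    "scaffold": scaf,
                    "start": int(start) - 1,
                    "end": int(end),
                    "strand": strand,
                    "type": ftype,
                    "id": attrs.get("ID", "."),
                }
            )
    return GenomeAnnotation(
        pd.DataFrame(rows, columns=ANNOTATION_COLUMNS), lengths
    )


# --------------------------------------------------------------- sRNA reads
def write_srna_reads(library: SrnaLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#library_id={library.library_id}\n")
        fh.write(f"#tissue={library.tissue}\n")
        fh.write(f"#replicate={library.replicate}\n")
        fh.write(f"#total_mapped_reads={library.total_mapped_reads}\n")
        library.reads.to_csv(fh, sep="\t", index=False)


def read_srna_reads(path: str | Path) -> SrnaLibrary:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, v = line[1:].strip().split("=", 1)
            meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        reads = pd.read_csv(fh, sep="\t")
    return SrnaLibrary(
        library_id=meta["library_id"],
        tissue=meta["tissue"],
        replicate=int(meta["replicate"]),
        reads=reads[READ_COLUMNS],
        total_mapped_reads=int(meta["total_mapped_reads"]),
    )


# -------------------------------------------------------------- methylation
def write_methylation(calls: MethylationCalls, path: str | Path) -> None:
    calls.records[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_methylation(path: str | Path) -> MethylationCalls:
    return MethylationCalls(pd.read_csv(path, sep="\t")[CALL_COLUMNS])


# ------------------------------------------------------------------- counts
def write_counts(matrix: ExpressionMatrix, counts_path: str | Path, groups_path: str | Path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene")
    groups = pd.DataFrame(
        {
            "sample": list(matrix.counts.columns),
            "tissue": [matrix.sample_tissues[c] for c in matrix.counts.columns],
            "excluded": [
                c in set(matrix.excluded_samples) for c in matrix.counts.columns
            ],
        }
    )
    groups.to_csv(groups_path, sep="\t", index=False)


def read_counts(counts_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    counts.index.name = None
    groups = pd.read_csv(groups_path, sep="\t")
    return ExpressionMatrix(
        counts=counts,
        sample_tissues=dict(zip(groups["sample"], groups["tissue"])),
        excluded_samples=list(groups.loc[groups["excluded"], "sample"]),
    )


# ----------------------------------------------------------------- hairpins
def write_hairpins(
    candidates: list[HairpinCandidate],
    fasta_path: str | Path,
    structure_path: str | Path,
    reads_path: str | Path,
) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in candidates
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(structure_path, "w") as fh:
        fh.write("id\tstructure\tmature_start\tmature_end\n")
        for c in candidates:
            m0, m1 = c.mature if c.mature else ("", "")
            fh.write(f"{c.id}\t{c.structure}\t{m0}\t{m1}\n")
    rows = [
        {"id": c.id, "start": s, "end": e, "count": n}
        for c in candidates
        for (s, e, n) in c.reads
    ]
    pd.DataFrame(rows, columns=["id", "start", "end", "count"]).to_csv(
        reads_path, sep="\t", index=False
    )


def read_hairpins(
    fasta_path: str | Path, structure_path: str | Path, reads_path: str | Path
) -> list[HairpinCandidate]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    struct = pd.read_csv(structure_path, sep="\t", dtype={"id": str})
    reads = pd.read_csv(reads_path, sep="\t", dtype={"id": str})
    by_id = {k: g for k, g in reads.groupby("id")}
    out = []
    for _, row in struct.iterrows():
        cid = row["id"]
        stack = [
            (int(s), int(e), int(n))
            for s, e, n in by_id.get(cid, pd.DataFrame(columns=["start", "end", "count"]))[
                ["start", "end", "count"]
            ].itertuples(index=False)
        ]
        mature = None
        if pd.notna(row["mature_start"]) and str(row["mature_start"]) != "":
            mature = (int(row["mature_start"]), int(row["mature_end"]))
        out.append(
            HairpinCandidate(
                id=cid,
                sequence=seqs[cid],
                structure=row["structure"],
                reads=stack,
                mature=mature,
            )
        )
    return out


# --------------------------------------------------------- contigs & k-mers
def write_contigs(table: ContigDepthTable, path: str | Path) -> None:
    table.contigs.to_csv(path, sep="\t", index=False)


def read_contigs(path: str | Path) -> ContigDepthTable:
    return ContigDepthTable(pd.read_csv(path, sep="\t"))


def write_kmer_histogram(hist: KmerHistogram, path: str | Path) -> None:
    pd.DataFrame({"multiplicity": hist.multiplicity, "count": hist.count}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_kmer_histogram(path: str | Path, k: int = 101) -> KmerHistogram:
    df = pd.read_csv(path, sep="\t", header=None, names=["multiplicity", "count"])
    return KmerHistogram(df["multiplicity"].to_numpy(), df["count"].to_numpy(), k=k)


# --------------------------------------------------------------- genotypes
_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i, (_, row) in enumerate(matrix.positions.iterrows()):
            gts = [
                "./." if not np.isfinite(d) else _GT[int(d)]
                for d in matrix.dosages[i]
            ]
            fh.write(
                f"{row['scaffold']}\t{row['position']}\t.\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    samples: list[str] = []
    pos_rows = []
    dosage_rows = []
    inv_gt = {v: k for k, v in _GT.items()}
    inv_gt["1/0"] = 1
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            pos_rows.append({"scaffold": fields[0], "position": int(fields[1])})
            dosage_rows.append(
                [inv_gt.get(g.split(":")[0], np.nan) for g in fields[9:]]
            )
    return GenotypeMatrix(
        positions=pd.DataFrame(pos_rows),
        dosages=np.asarray(dosage_rows, dtype=float),
        samples=samples,
    )
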
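"""Reading and writing of the interchange formats used across the pipeline.

FASTA/FASTQ records go through Biopython; VCF reading goes through pysam.
GFF3 uses 1-based inclusive coordinates throughout; internal pipeline code
converts to 0-based half-open at module boundaries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure, GFF3 convention (1-based inclusive)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start > self.end or self.start < 1:
            raise ValueError(f"bad gene span {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def cds(self, contig_seq: str) -> str:
        """Spliced coding sequence, reverse-complemented on the minus strand."""
        parts = [contig_seq[s - 1 : e] for s, e in self.exons]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (id, sequence) pairs as 4-line FASTQ with constant quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip()
            fh.readline()
            fh.readline()
            out.append((header[1:].rstrip(), seq))
    return out


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tpanforge\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.contig}\tpanforge\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    cols = ["contig", "source", "type", "start", "end", "score", "strand", "frame", "attrs"]
    df = pd.read_csv(str(path), sep="\t", comment="#", names=cols, dtype={"contig": str})
    if df.empty:
        return []

    def attr(s: str, key: str) -> str:
        for part in s.split(";"):
            k, _, v = part.partition("=")
            if k == key:
                return v
        return ""

    genes: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        if row.type == "gene":
            gid = attr(row.attrs, "ID")
            genes[gid] = {
                "contig": row.contig,
                "start": int(row.start),
                "end": int(row.end),
                "strand": row.strand,
                "exons": [],
            }
    for row in df.itertuples(index=False):
        if row.type == "exon":
            parent = attr(row.attrs, "Parent")
            if parent in genes:
                genes[parent]["exons"].append((int(row.start), int(row.end)))
    return [
        GeneModel(
            gene_id=gid,
            contig=info["contig"],
            start=info["start"],
            end=info["end"],
            strand=info["strand"],
            exons=tuple(sorted(info["exons"])) or ((info["start"], info["end"]),),
        )
        for gid, info in genes.items()
    ]


# ---------------------------------------------------------------------------
# VCF (v4.2, homozygous GT plus per-sample DP)

_VCF_HEADER = """##fileformat=VCFv4.2
##source=panforge
##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(
    records: Iterable[tuple],
    samples: list[str],
    path: str | os.PathLike,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write records of (contig, pos1, ref, alt, vtype, genotypes, depths).

    ``genotypes`` holds one code per sample: 0 ref, 1 alt, -1 missing
    (homozygous inbred-line model).  ``depths`` may be None.
    """
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        fh.write(("\t" + "\t".join(samples)) if samples else "")
        fh.write("\n")
        gt_map = {0: "0/0", 1: "1/1", -1: "./."}
        for contig, pos, ref, alt, vtype, gts, depths in records:
            fields = [contig, str(pos), ".", ref, alt, ".", "PASS", f"TYPE={vtype}"]
            if depths is None:
                fields.append("GT")
                fields.extend(gt_map[int(g)] for g in gts)
            else:
                fields.append("GT:DP")
                fields.extend(f"{gt_map[int(g)]}:{int(d)}" for g, d in zip(gts, depths))
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | os.PathLike) -> tuple[list[tuple], list[str]]:
    """Read a VCF back into (contig, pos, ref, alt, vtype, genotypes, depths) rows."""
    records: list[tuple] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf.fetch() if vf.index is not None else vf:
            gts, depths = [], []
            for s in samples:
                call = rec.samples[s]
                allele = call["GT"][0] if call["GT"] else None
                gts.append(-1 if allele is None else int(allele))
                depths.append(call.get("DP") if call.get("DP") is not None else 0)
            vtype = rec.info.get("TYPE", "SNP")
            records.append(
                (rec.contig, rec.pos, rec.ref, rec.alts[0] if rec.alts else ".", vtype, gts, depths)
            )
    return records, samples


# ---------------------------------------------------------------------------
# TSV matrices


def write_matrix_tsv(df: pd.DataFrame, path: str | os.PathLike, index_label: str = "gene") -> None:
    df.to_csv(str(path), sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", index_col=0)
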
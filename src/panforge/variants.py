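"""Pileup SNP calling, site filtering, functional annotation and Ka/Ks.

The caller is a deterministic homozygous-model pileup: per accession and
site, the genotype is alt when depth >= min_depth and the alt base fraction
is >= min_alt_frac, ref when the alt fraction is <= 1 - min_alt_frac, and
missing otherwise.  Duplicate read pairs (identical mate coordinates) are
collapsed before pileup.  Site filters follow the missingness (<= 0.15) and
minor allele count (>= 2) rules; annotation assigns one region class per
site with precedence exon > intron > upstream > downstream > intergenic and
classifies exonic SNPs through the standard codon table.  Ka/Ks uses the
Nei-Gojobori approximate site-counting method without multiple-hit
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .panbuild import AlignmentRecord, PanAssembly, _encode
from .pansim import ReadSet
from .seqio import GeneModel, revcomp

_BASES = "ACGT"
_CODON_FWD = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_FWD[_stop] = "*"


def translate_codon(codon: str) -> str:
    return _CODON_FWD.get(codon.upper(), "X")


@dataclass(frozen=True)
class VariantRecord:
    contig: str
    position: int  # 1-based, VCF convention
    ref: str
    alt: str
    vtype: str  # SNP | insertion | deletion
    genotypes: np.ndarray  # per-accession codes {0, 1, -1}
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.vtype == "SNP" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("SNP alleles must have length 1")


@dataclass
class GenotypeMatrix:
    """Sites x accessions genotype codes {0 ref, 1 alt, -1 missing}."""

    data: np.ndarray
    sites: pd.DataFrame  # contig, position, ref, alt, vtype
    accessions: list[str]

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    def to_records(self) -> list[VariantRecord]:
        return [
            VariantRecord(
                contig=row.contig, position=int(row.position), ref=row.ref, alt=row.alt,
                vtype=row.vtype, genotypes=self.data[i],
            )
            for i, row in enumerate(self.sites.itertuples(index=False))
        ]


# ---------------------------------------------------------------------------
# duplicate collapse + pileup calling


def collapse_duplicates(alignments: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Drop all but one alignment pair per fragment signature.

    Fragment signature: sorted mate (contig, start, strand) coordinates of
    the pair.  Mates whose partner is unmapped are keyed on their own
    coordinates.
    """
    by_pair: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        pid = a.read_id.rsplit("/", 1)[0]
        by_pair.setdefault(pid, []).append(a)
    seen: set[tuple] = set()
    kept: list[AlignmentRecord] = []
    for pid in by_pair:
        mates = by_pair[pid]
        key = tuple(sorted((a.contig, a.start, a.strand) for a in mates))
        if key in seen:
            continue
        seen.add(key)
        kept.extend(mates)
    return kept


def _base_counts(
    alignments: list[AlignmentRecord],
    seqs_by_id: dict[str, str],
    contig_codes: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    counts = {name: np.zeros((4, codes.size), dtype=np.uint16) for name, codes in contig_codes.items()}
    for a in alignments:
        if not a.mapped or a.contig not in counts:
            continue
        seq = seqs_by_id.get(a.read_id)
        if seq is None:
            continue
        codes = _encode(seq)
        if a.strand == "-":
            codes = 3 - codes[::-1]
        L = min(codes.size, contig_codes[a.contig].size - a.start)
        np.add.at(counts[a.contig], (codes[:L], np.arange(a.start, a.start + L)), 1)
    return counts


def call_snps(
    assembly: PanAssembly,
    alignments_by_accession: dict[str, list[AlignmentRecord]],
    reads_by_accession: dict[str, ReadSet],
    min_depth: int = 5,
    min_alt_frac: float = 0.8,
    dedupe: bool = True,
) -> GenotypeMatrix:
    """Homozygous pileup SNP calling across accessions.

    A site is emitted iff at least one accession is called alt there.
    """
    contig_codes = {c.id: _encode(c.sequence) for c in assembly.contigs}
    accs = list(alignments_by_accession)
    counts_by_acc: dict[str, dict[str, np.ndarray]] = {}
    candidates: dict[tuple[str, int], np.ndarray] = {}
    for acc in accs:
        aln = alignments_by_accession[acc]
        if dedupe:
            aln = collapse_duplicates(aln)
        seqs_by_id: dict[str, str] = {}
        for rid, s1, s2 in reads_by_accession[acc].pairs:
            seqs_by_id[f"{rid}/1"] = s1
            seqs_by_id[f"{rid}/2"] = s2
        counts = _base_counts(aln, seqs_by_id, contig_codes)
        counts_by_acc[acc] = counts
        for name, cnt in counts.items():
            depth = cnt.sum(axis=0)
            ref = contig_codes[name]
            refcnt = cnt[ref, np.arange(ref.size)]
            nonref = depth - refcnt
            sites = np.flatnonzero((depth >= min_depth) & (nonref >= min_alt_frac * depth) & (nonref > 0))
            for pos in sites:
                key = (name, int(pos))
                col = cnt[:, pos].astype(np.int64)
                col[ref[pos]] = 0
                candidates[key] = candidates.get(key, np.zeros(4, dtype=np.int64)) + col

    site_keys = sorted(candidates)
    n_sites, n_acc = len(site_keys), len(accs)
    gt = np.full((n_sites, n_acc), -1, dtype=np.int8)
    meta = []
    for si, (name, pos) in enumerate(site_keys):
        ref_code = int(contig_codes[name][pos])
        alt_code = int(np.argmax(candidates[(name, pos)]))
        meta.append((name, pos + 1, _BASES[ref_code], _BASES[alt_code], "SNP"))
        for ai, acc in enumerate(accs):
            cnt = counts_by_acc[acc][name][:, pos]
            depth = int(cnt.sum())
            if depth < min_depth:
                continue
            frac = cnt[alt_code] / depth
            if frac >= min_alt_frac:
                gt[si, ai] = 1
            elif frac <= 1 - min_alt_frac:
                gt[si, ai] = 0
    sites = pd.DataFrame(meta, columns=["contig", "position", "ref", "alt", "vtype"])
    keep = (gt == 1).any(axis=1)
    return GenotypeMatrix(data=gt[keep], sites=sites[keep].reset_index(drop=True), accessions=accs)


def filter_variants(
    matrix: GenotypeMatrix, max_missing: float = 0.15, min_mac: int = 2
) -> GenotypeMatrix:
    """Retain sites with missingness <= max_missing and minor allele count
    >= min_mac (the paper-style site filters); idempotent."""
    gt = matrix.data
    n = gt.shape[1]
    missing_frac = (gt == -1).sum(axis=1) / n
    n_alt = (gt == 1).sum(axis=1)
    n_ref = (gt == 0).sum(axis=1)
    mac = np.minimum(n_alt, n_ref)
    keep = (missing_frac <= max_missing) & (mac >= min_mac)
    return GenotypeMatrix(
        data=gt[keep], sites=matrix.sites[keep].reset_index(drop=True), accessions=list(matrix.accessions)
    )


# ---------------------------------------------------------------------------
# annotation


def _cds_layout(gene: GeneModel) -> tuple[list[tuple[int, int, int]], int]:
    """Per-exon (start, end, cds_offset_at_start) in genomic order."""
    layout = []
    off = 0
    for s, e in gene.exons:
        layout.append((s, e, off))
        off += e - s + 1
    return layout, off


def classify_coding_snp(gene: GeneModel, contig_seq: str, position: int, alt: str) -> str:
    """Effect of a single-base substitution inside an exon of ``gene``.

    Returns synonymous / missense / nonsense, or unknown when the spliced
    CDS is not a whole number of codons.
    """
    layout, total = _cds_layout(gene)
    if total % 3 != 0:
        return "unknown"
    g_off = None
    for s, e, off in layout:
        if s <= position <= e:
            g_off = off + (position - s)
            break
    if g_off is None:
        return "unknown"
    cds = gene.cds(contig_seq)
    if gene.strand == "+":
        cds_off = g_off
        new_base = alt.upper()
    else:
        cds_off = total - 1 - g_off
        new_base = revcomp(alt.upper())
    ci = cds_off // 3
    codon = cds[3 * ci : 3 * ci + 3]
    mutated = codon[: cds_off % 3] + new_base + codon[cds_off % 3 + 1 :]
    aa_ref, aa_alt = translate_codon(codon), translate_codon(mutated)
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def annotate_variants(
    sites: pd.DataFrame,
    gene_models: list[GeneModel],
    assembly: PanAssembly,
    flank: int = 5000,
) -> pd.DataFrame:
    """Region class (precedence exon > intron > upstream > downstream >
    intergenic) and coding effect per site.

    Upstream/downstream windows span ``flank`` bp 5'/3' of a gene respecting
    its strand.  Exonic SNPs get an effect; non-SNPs and frame-less exons
    report "unknown".
    """
    contig_seqs = assembly.as_dict()
    by_contig: dict[str, list[GeneModel]] = {}
    for gm in gene_models:
        by_contig.setdefault(gm.contig, []).append(gm)
    rows = []
    for row in sites.itertuples(index=False):
        pos = int(row.position)
        region, effect, gene_id = "intergenic", "", ""
        genes = by_contig.get(row.contig, [])
        hit_intron = hit_up = hit_down = None
        for gm in genes:
            if gm.start <= pos <= gm.end:
                in_exon = any(s <= pos <= e for s, e in gm.exons)
                if in_exon:
                    region, gene_id = "exon", gm.gene_id
                    if row.vtype == "SNP":
                        effect = classify_coding_snp(gm, contig_seqs[row.contig], pos, row.alt)
                    else:
                        effect = "unknown"
                    break
                hit_intron = hit_intron or gm
            elif (gm.strand == "+" and gm.start - flank <= pos < gm.start) or (
                gm.strand == "-" and gm.end < pos <= gm.end + flank
            ):
                hit_up = hit_up or gm
            elif (gm.strand == "+" and gm.end < pos <= gm.end + flank) or (
                gm.strand == "-" and gm.start - flank <= pos < gm.start
            ):
                hit_down = hit_down or gm
        if region != "exon":
            if hit_intron is not None:
                region, gene_id = "intron", hit_intron.gene_id
            elif hit_up is not None:
                region, gene_id = "upstream", hit_up.gene_id
            elif hit_down is not None:
                region, gene_id = "downstream", hit_down.gene_id
        rows.append((row.contig, pos, region, effect, gene_id))
    return pd.DataFrame(rows, columns=["contig", "position", "region", "effect", "gene"])


# ---------------------------------------------------------------------------
# summary statistics

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def tstv_ratio(sites: pd.DataFrame) -> float:
    """Transition / transversion count ratio over SNP sites."""
    snps = sites[sites["vtype"] == "SNP"] if "vtype" in sites else sites
    if snps.empty:
        raise ValueError("no SNP records")
    ts = sum((r, a) in _TRANSITIONS for r, a in zip(snps["ref"], snps["alt"]))
    tv = len(snps) - ts
    if tv == 0:
        raise ValueError("Ts/Tv undefined: zero transversions")
    return ts / tv


def variant_density(
    sites: pd.DataFrame, contig_lengths: dict[str, int], window: int = 80_000
) -> pd.DataFrame:
    """Non-overlapping windowed variant counts (0-based half-open windows)."""
    rows = []
    for contig, length in contig_lengths.items():
        n_win = max(1, -(-length // window))
        counts = np.zeros(n_win, dtype=int)
        sub = sites[sites["contig"] == contig]
        if not sub.empty:
            idx = (sub["position"].to_numpy() - 1) // window
            np.add.at(counts, idx, 1)
        for w in range(n_win):
            start = w * window
            end = min(length, start + window)
            rows.append((contig, start, end, int(counts[w]), counts[w] / window * 1000))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "count", "per_kb"])


def indel_size_spectrum(sites: pd.DataFrame) -> pd.Series:
    """Counts of indel sizes (insertions positive, deletions negative)."""
    ind = sites[sites["vtype"].isin(["insertion", "deletion"])]
    sizes = ind["alt"].str.len() - ind["ref"].str.len()
    return sizes.value_counts().sort_index()


# ---------------------------------------------------------------------------
# Ka/Ks (Nei-Gojobori approximate method, no multiple-hit correction)


@dataclass(frozen=True)
class KaKsResult:
    gene_id: str
    ka: float
    ks: float
    ratio: float  # nan when Ks == 0
    category: str  # purifying | neutral | positive
    defined: bool


def synonymous_fraction(codon: str, pos: int) -> float:
    """Fraction of the 3 one-step changes at codon position ``pos`` that are
    synonymous."""
    aa = translate_codon(codon)
    syn = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        if translate_codon(codon[:pos] + b + codon[pos + 1 :]) == aa:
            syn += 1
    return syn / 3


def kaks_ratio(
    gene: GeneModel,
    contig_seq: str,
    coding_changes: list[tuple[int, str]],
    neutral_band: float = 0.1,
) -> KaKsResult:
    """Ka/Ks for one gene from observed coding substitutions.

    ``coding_changes`` holds (genomic position, alt base) single-base
    substitutions inside exons; each is scored against the reference codon.
    """
    cds = gene.cds(contig_seq)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS of {gene.gene_id} is not a multiple of 3")
    S = sum(synonymous_fraction(cds[i : i + 3], j) for i in range(0, len(cds), 3) for j in range(3))
    N = len(cds) - S
    sd = nd = 0
    for position, alt in coding_changes:
        effect = classify_coding_snp(gene, contig_seq, position, alt)
        if effect == "synonymous":
            sd += 1
        elif effect in ("missense", "nonsense"):
            nd += 1
    ka = nd / N if N > 0 else 0.0
    ks = sd / S if S > 0 else 0.0
    if ks > 0:
        ratio = ka / ks
        if ratio > 1 + neutral_band:
            category = "positive"
        elif ratio < 1 - neutral_band:
            category = "purifying"
        else:
            category = "neutral"
        return KaKsResult(gene.gene_id, ka, ks, ratio, category, True)
    category = "purifying" if ka == 0 else "positive"
    return KaKsResult(gene.gene_id, ka, ks, math.nan, category, False)
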
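"""Synthetic pan-genome simulator for inbred crop panels.

Generates a structured population of fully homozygous accessions organised
into botanical races plus optional admixed individuals.  All accessions share
a core gene set laid out on reference contigs; variable genes are present in
race-dependent subsets.  Variable genes absent from the designated reference
accession form the novel-sequence pool and exist only in non-reference
genomes, so an iterative map-and-assemble build has real novel sequence to
recover.  SNPs and short indels are planted with race-correlated allele
frequencies; paired-end reads are simulated with uniform base-call errors and
optional organelle-like contaminant pairs.

Ground truth (gene presence/absence, planted variants, race labels) is
retained in a :class:`TruthSet` so downstream callers can be scored.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CapacityError, SimConfig
from .seqio import (
    GeneModel,
    read_fasta,
    read_fastq,
    read_gff3,
    read_matrix_tsv,
    read_vcf,
    revcomp,
    write_fasta,
    write_fastq,
    write_gff3,
    write_matrix_tsv,
    write_vcf,
)

RACE_NAMES = ("durra", "guinea", "caudatum", "kafir", "bicolor")
ADMIXED = "admixed"

def _is_contaminant_id(rid: str) -> bool:
    """Read ids are '<acc>|<tag><n>[|origin...]'; tag 'c' marks decoy pairs."""
    parts = rid.split("|")
    return len(parts) > 1 and parts[1].startswith("c")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class TruthSet:
    """Simulator ground truth for scoring downstream calls.

    ``variant_truth`` rows are (contig, pos [1-based], ref, alt, type,
    genotypes) with one homozygous genotype code per accession
    (0 ref, 1 alt, -1 missing because the locus is deleted there).
    """

    pav_truth: pd.DataFrame
    variant_truth: list[tuple]
    race_of: dict[str, str]
    gene_models: list[GeneModel]

    @property
    def accessions(self) -> list[str]:
        return list(self.pav_truth.columns)


@dataclass
class ReadSet:
    """Paired reads for one accession, in memory and/or on disk."""

    accession: str
    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    fastq1: str | None = None
    fastq2: str | None = None
    n_contaminant: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def provenance(self) -> float:
        return self.n_contaminant / self.n_pairs if self.pairs else 0.0

    def write(self, outdir: str | os.PathLike) -> "ReadSet":
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fastq1 = str(outdir / f"{self.accession}_1.fastq")
        self.fastq2 = str(outdir / f"{self.accession}_2.fastq")
        write_fastq(((rid + "/1", s1) for rid, s1, _ in self.pairs), self.fastq1)
        write_fastq(((rid + "/2", s2) for rid, _, s2 in self.pairs), self.fastq2)
        return self

    @classmethod
    def load(cls, accession: str, fastq1: str, fastq2: str) -> "ReadSet":
        r1, r2 = read_fastq(fastq1), read_fastq(fastq2)
        if len(r1) != len(r2):
            raise ValueError("mate files have unequal record counts")
        pairs = []
        n_cont = 0
        for (id1, s1), (_, s2) in zip(r1, r2):
            rid = id1[:-2] if id1.endswith("/1") else id1
            if _is_contaminant_id(rid):
                n_cont += 1
            pairs.append((rid, s1, s2))
        return cls(accession=accession, pairs=pairs, fastq1=fastq1, fastq2=fastq2, n_contaminant=n_cont)


@dataclass
class PanGenomeSim:
    """Full simulator output: sequences, models, truth and decoys."""

    config: SimConfig
    reference: dict[str, str]
    gene_models: list[GeneModel]
    genomes: dict[str, dict[str, str]]
    truth: TruthSet
    decoys: dict[str, str]

    @property
    def reference_accession(self) -> str:
        return self.truth.accessions[0]

    def write(self, outdir: str | os.PathLike) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.reference, outdir / "reference.fasta")
        write_gff3(
            [g for g in self.gene_models if g.contig in self.reference],
            outdir / "reference.gff3",
        )
        write_fasta(self.decoys, outdir / "decoys.fasta")
        for acc, genome in self.genomes.items():
            write_fasta(genome, outdir / f"{acc}.fasta")
        write_truth(self.truth, outdir)


def _race_labels(config: SimConfig, rng: np.random.Generator) -> tuple[list[str], list[tuple[int, ...]]]:
    """Assign race labels; admixed accessions (taken from the end, never the
    reference accession) mix two distinct races 50:50."""
    names = [RACE_NAMES[i] if i < len(RACE_NAMES) else f"race{i}" for i in range(config.n_races)]
    n_adm = int(round(config.admixture_fraction * config.n_accessions))
    n_adm = min(n_adm, max(0, config.n_accessions - config.n_races))
    labels: list[str] = []
    mixes: list[tuple[int, ...]] = []
    n_pure = config.n_accessions - n_adm
    for i in range(config.n_accessions):
        if i < n_pure:
            r = i % config.n_races
            labels.append(names[r])
            mixes.append((r,))
        else:
            r1, r2 = rng.choice(config.n_races, size=2, replace=False)
            labels.append(ADMIXED)
            mixes.append((int(r1), int(r2)))
    return labels, mixes


def _draw_presence(
    config: SimConfig, mixes: list[tuple[int, ...]], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Presence matrix (variable genes x accessions) and the per-race
    probability table that generated it."""
    n_var, n_acc = config.n_variable_genes, config.n_accessions
    if config.variable_gene_presence_prob is not None:
        ptable = np.asarray(config.variable_gene_presence_prob, dtype=float)
    else:
        a, b = config.presence_beta
        ptable = rng.beta(a, b, size=(n_var, config.n_races))
    pacc = np.empty((n_var, n_acc))
    for j, mix in enumerate(mixes):
        pacc[:, j] = ptable[:, list(mix)].mean(axis=1)
    presence = (rng.random((n_var, n_acc)) < pacc).astype(np.int8)
    # A variable gene needs >=1 carrier to exist anywhere and >=1 absence to
    # be variable; resample degenerate rows where the probabilities allow it.
    for g in range(n_var):
        tries = 0
        while tries < 100 and (presence[g].all() or not presence[g].any()):
            if presence[g].all() and np.all(pacc[g] >= 1.0):
                break  # deterministically ubiquitous: behaves as core
            presence[g] = (rng.random(n_acc) < pacc[g]).astype(np.int8)
            tries += 1
        if not presence[g].any():
            raise ValueError(f"variable gene {g} has no carrier under its presence probabilities")
    return presence, ptable


def _make_gene(gid: str, contig: str, offset: int, length: int, strand: str, rng: np.random.Generator) -> GeneModel:
    """Build a gene model starting at 1-based position offset+1 with 1-3
    exons; total exonic length is a multiple of 3 (valid CDS)."""
    exonic = max(90, (length * 2 // 3) // 3 * 3)
    n_ex = int(rng.integers(1, 4))
    n_ex = min(n_ex, exonic // 60)
    cuts = sorted(rng.choice(np.arange(1, exonic // 3), size=n_ex - 1, replace=False) * 3) if n_ex > 1 else []
    sizes = np.diff([0, *cuts, exonic])
    intron_total = length - exonic
    introns = []
    if n_ex > 1:
        w = rng.dirichlet(np.ones(n_ex - 1))
        introns = np.maximum(20, (w * intron_total).astype(int)).tolist()
    exons = []
    pos = offset + 1
    for i, sz in enumerate(sizes):
        exons.append((pos, pos + int(sz) - 1))
        pos += int(sz)
        if i < len(introns):
            pos += introns[i]
    end = exons[-1][1]
    return GeneModel(
        gene_id=gid,
        contig=contig,
        start=offset + 1,
        end=end,
        strand="+" if rng.random() < 0.5 else "-",
        exons=tuple(exons),
    )


def simulate_pangenome(config: SimConfig) -> PanGenomeSim:
    """Generate reference, accession genomes, gene models and ground truth.

    The first accession is the designated reference: its gene content defines
    the reference contigs and it carries the reference allele at every
    planted variant site.
    """
    rng = np.random.default_rng(config.seed)
    accs = [f"ACC{i:03d}" for i in range(config.n_accessions)]
    labels, mixes = _race_labels(config, rng)
    presence_var, _ = _draw_presence(config, mixes, rng)

    n_total = config.n_core_genes + config.n_variable_genes
    gene_ids = [f"gene{i:04d}" for i in range(n_total)]
    is_core = np.zeros(n_total, dtype=bool)
    is_core[: config.n_core_genes] = True
    order = rng.permutation(n_total)

    # Gene lengths drawn up front so layout is reproducible.
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n_total)

    # Partition: genes on reference contigs vs the novel pool.  Variable gene
    # v is novel iff absent from the reference accession (column 0).
    var_index = {}  # gene index -> row in presence_var
    vi = 0
    for i in range(n_total):
        if not is_core[i]:
            var_index[i] = vi
            vi += 1

    ref_gene_idx = [i for i in order if is_core[i] or presence_var[var_index[i], 0] == 1]
    novel_gene_idx = [i for i in order if not is_core[i] and presence_var[var_index[i], 0] == 0]

    # ---- lay reference genes onto contigs -------------------------------
    contig_names = [f"chr{c + 1}" for c in range(config.n_contigs)]
    contig_arrays = {name: rng.integers(0, 4, size=config.contig_length).astype(np.uint8) for name in contig_names}
    gene_models: dict[str, GeneModel] = {}
    cidx, cursor = 0, config.intergenic_length
    for i in ref_gene_idx:
        length = int(lengths[i])
        while cursor + length + config.intergenic_length > config.contig_length:
            cidx += 1
            cursor = config.intergenic_length
            if cidx >= config.n_contigs:
                raise CapacityError(
                    f"{n_total} genes do not fit on {config.n_contigs} contigs of "
                    f"{config.contig_length} bp"
                )
        gm = _make_gene(gene_ids[i], contig_names[cidx], cursor, length, "+", rng)
        gene_models[gene_ids[i]] = gm
        cursor = gm.end + config.intergenic_length

    # ---- novel pool: one donor contig per non-reference gene ------------
    novel_donors: dict[str, np.ndarray] = {}
    for i in novel_gene_idx:
        gid = gene_ids[i]
        length = int(lengths[i])
        seg_len = length + 2 * config.novel_flank
        seg = rng.integers(0, 4, size=seg_len).astype(np.uint8)
        donor_name = f"novel_{gid}"
        gm = _make_gene(gid, donor_name, config.novel_flank, length, "+", rng)
        gene_models[gid] = gm
        novel_donors[donor_name] = seg

    # ---- PAV truth over all genes ---------------------------------------
    pav = np.ones((n_total, config.n_accessions), dtype=np.int8)
    for i in range(n_total):
        if not is_core[i]:
            pav[i] = presence_var[var_index[i]]
    pav_truth = pd.DataFrame(pav, index=gene_ids, columns=accs)

    # ---- planted SNPs with race-correlated allele frequencies -----------
    variant_truth: list[tuple] = []
    snp_edits: dict[str, list[tuple[int, np.ndarray, int]]] = {n: [] for n in contig_names}
    for name in contig_names:
        arr = contig_arrays[name]
        sites = np.flatnonzero(rng.random(arr.size) < config.snp_rate)
        for pos in sites:
            ref_code = int(arr[pos])
            alt_code = (ref_code + int(rng.integers(1, 4))) % 4
            freq = rng.beta(0.5, 0.5, size=config.n_races)
            gts = np.zeros(config.n_accessions, dtype=np.int8)
            for j, mix in enumerate(mixes):
                f = float(np.mean(freq[list(mix)]))
                gts[j] = 1 if rng.random() < f else 0
            gts[0] = 0  # reference accession carries the reference allele
            if gts.max() == 0:
                continue
            variant_truth.append(
                (name, int(pos) + 1, _decode(np.array([ref_code])), _decode(np.array([alt_code])), "SNP", gts)
            )
            snp_edits[name].append((int(pos), gts, alt_code))

    # ---- deletion intervals for absent reference-variable genes ---------
    # flanks are clamped so a deletion never intrudes into a neighbouring
    # gene's span (keeps the coverage signal of present genes clean)
    spans_by_contig: dict[str, list[tuple[int, int]]] = {n: [] for n in contig_names}
    for gm in gene_models.values():
        if gm.contig in spans_by_contig:
            spans_by_contig[gm.contig].append((gm.start, gm.end))
    for n in spans_by_contig:
        spans_by_contig[n].sort()
    del_intervals: dict[str, list[tuple[int, int, np.ndarray]]] = {n: [] for n in contig_names}
    for i in ref_gene_idx:
        if is_core[i]:
            continue
        gm = gene_models[gene_ids[i]]
        row = presence_var[var_index[i]]
        spans = spans_by_contig[gm.contig]
        prev_end = max((e for s, e in spans if e < gm.start), default=0)
        next_start = min((s for s, e in spans if s > gm.end), default=config.contig_length + 1)
        s = max(prev_end, gm.start - 1 - config.deletion_flank)
        e = min(next_start - 1, gm.end + config.deletion_flank, config.contig_length)
        del_intervals[gm.contig].append((s, e, row))

    # ---- planted indels in intergenic space ------------------------------
    genic = {n: np.zeros(config.contig_length, dtype=bool) for n in contig_names}
    pad = config.deletion_flank + config.max_indel_len + 1
    for gm in gene_models.values():
        if gm.contig in genic:
            genic[gm.contig][max(0, gm.start - 1 - pad) : gm.end + pad] = True
    indel_events: dict[str, list[tuple[int, int, np.ndarray, np.ndarray]]] = {n: [] for n in contig_names}
    for name in contig_names:
        arr = contig_arrays[name]
        cand = np.flatnonzero((rng.random(arr.size) < config.indel_rate) & ~genic[name])
        cand = cand[(cand > 0) & (cand < arr.size - config.max_indel_len - 1)]
        for pos in cand:
            ilen = int(rng.integers(1, config.max_indel_len + 1))
            is_ins = rng.random() < 0.5
            freq = rng.beta(0.5, 0.5, size=config.n_races)
            gts = np.zeros(config.n_accessions, dtype=np.int8)
            for j, mix in enumerate(mixes):
                f = float(np.mean(freq[list(mix)]))
                gts[j] = 1 if rng.random() < f else 0
            gts[0] = 0
            if gts.max() == 0:
                continue
            anchor = _decode(arr[pos : pos + 1])
            if is_ins:
                ins_seq = rng.integers(0, 4, size=ilen).astype(np.uint8)
                ref_a, alt_a = anchor, anchor + _decode(ins_seq)
                indel_events[name].append((int(pos), ilen, gts, ins_seq))
                vtype = "insertion"
            else:
                ref_a = _decode(arr[pos : pos + 1 + ilen])
                alt_a = anchor
                indel_events[name].append((int(pos), -ilen, gts, np.empty(0, dtype=np.uint8)))
                vtype = "deletion"
            variant_truth.append((name, int(pos) + 1, ref_a, alt_a, vtype, gts))

    variant_truth.sort(key=lambda r: (r[0], r[1]))

    # mark genotypes missing where the surrounding locus is deleted
    final_truth = []
    for contig, pos1, ref_a, alt_a, vtype, gts in variant_truth:
        gts = gts.copy()
        for s, e, row in del_intervals.get(contig, []):
            if s <= pos1 - 1 < e:
                gts[row == 0] = -1
        if (gts == 1).any():
            final_truth.append((contig, pos1, ref_a, alt_a, vtype, gts))
    variant_truth = final_truth

    # ---- per-accession genomes ------------------------------------------
    genomes: dict[str, dict[str, str]] = {}
    for j, acc in enumerate(accs):
        genome: dict[str, str] = {}
        for name in contig_names:
            arr = contig_arrays[name].copy()
            for pos, gts, alt_code in snp_edits[name]:
                if gts[j] == 1:
                    arr[pos] = alt_code
            cuts: list[tuple[int, int, np.ndarray | None]] = []
            for s, e, row in del_intervals[name]:
                if row[j] == 0:
                    cuts.append((s, e, None))
            for pos, ilen, gts, ins_seq in indel_events[name]:
                if gts[j] != 1:
                    continue
                if ilen > 0:
                    cuts.append((pos + 1, pos + 1, ins_seq))
                else:
                    cuts.append((pos + 1, pos + 1 - ilen, None))
            cuts.sort(key=lambda c: (c[0], c[1]))
            pieces, prev = [], 0
            for s, e, ins in cuts:
                pieces.append(arr[prev:s])
                if ins is not None:
                    pieces.append(ins)
                prev = e
            pieces.append(arr[prev:])
            genome[name] = _decode(np.concatenate(pieces))
        for i in novel_gene_idx:
            gid = gene_ids[i]
            if presence_var[var_index[i], j] == 1:
                donor = f"novel_{gid}"
                genome[donor] = _decode(novel_donors[donor])
        genomes[acc] = genome

    # ---- organelle-like decoys ------------------------------------------
    decoys = {
        "mito_like": _decode(rng.integers(0, 4, size=15_000).astype(np.uint8)),
        "chloro_like": _decode(rng.integers(0, 4, size=12_000).astype(np.uint8)),
    }

    truth = TruthSet(
        pav_truth=pav_truth,
        variant_truth=variant_truth,
        race_of=dict(zip(accs, labels)),
        gene_models=list(gene_models.values()),
    )
    reference = {name: _decode(contig_arrays[name]) for name in contig_names}
    return PanGenomeSim(
        config=config,
        reference=reference,
        gene_models=list(gene_models.values()),
        genomes=genomes,
        truth=truth,
        decoys=decoys,
    )


# ---------------------------------------------------------------------------
# Read simulation


def _pairs_from_contig(
    name: str,
    codes: np.ndarray,
    n_pairs: int,
    config: SimConfig,
    rng: np.random.Generator,
    acc: str,
    tag: str,
    start_index: int,
) -> list[tuple[str, str, str]]:
    L, rl = codes.size, config.read_length
    ilo = max(config.insert_range[0], rl)
    ihi = min(config.insert_range[1], L)
    inserts = np.clip(
        np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)).astype(int), ilo, ihi
    )
    starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(int)
    idx = np.arange(rl)
    r1 = codes[starts[:, None] + idx]
    ends = starts + inserts
    r2 = codes[ends[:, None] - rl + idx]
    r2 = 3 - r2[:, ::-1]  # reverse complement
    if config.error_rate > 0:
        for mat in (r1, r2):
            mask = rng.random(mat.shape) < config.error_rate
            shift = rng.integers(1, 4, size=mat.shape)
            mat[mask] = (mat[mask] + shift[mask]) % 4
    out = []
    for i in range(n_pairs):
        if config.tag_read_origin:
            rid = f"{acc}|{tag}{start_index + i}|{name}|{starts[i]}|{inserts[i]}"
        else:
            rid = f"{acc}|{tag}{start_index + i}"
        out.append((rid, _decode(r1[i]), _decode(r2[i])))
    return out


def simulate_reads(
    genome: dict[str, str],
    config: SimConfig,
    accession: str = "ACC",
    rng: np.random.Generator | None = None,
    decoys: dict[str, str] | None = None,
) -> ReadSet:
    """Simulate paired-end reads at the configured fold coverage.

    Pair counts per contig satisfy depth = 2 * read_length * n_pairs /
    contig_length.  When ``contaminant_fraction`` > 0 a binomial share of
    pairs is drawn from the organelle-like decoys instead and flagged in the
    read ids (tag ``c``).
    """
    if not genome:
        raise ValueError("genome is empty")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    for name, seq in genome.items():
        if config.read_length > len(seq):
            raise ValueError(f"read_length {config.read_length} exceeds contig {name} ({len(seq)} bp)")
    pairs: list[tuple[str, str, str]] = []
    counter = 0
    for name, seq in genome.items():
        codes = _encode(seq)
        n = int(round(len(seq) * config.coverage / (2 * config.read_length)))
        if n == 0:
            continue
        n_cont = int(rng.binomial(n, config.contaminant_fraction)) if config.contaminant_fraction else 0
        pairs.extend(_pairs_from_contig(name, codes, n - n_cont, config, rng, accession, "p", counter))
        counter += n - n_cont
        if n_cont:
            if not decoys:
                raise ValueError("contaminant_fraction > 0 requires a decoy FASTA")
            dnames = sorted(decoys)
            picks = rng.integers(0, len(dnames), size=n_cont)
            for d in range(len(dnames)):
                k = int((picks == d).sum())
                if k == 0:
                    continue
                dcodes = _encode(decoys[dnames[d]])
                if dcodes.size < config.read_length:
                    raise ValueError(f"decoy {dnames[d]} shorter than read_length")
                pairs.extend(
                    _pairs_from_contig(dnames[d], dcodes, k, config, rng, accession, "c", counter)
                )
                counter += k
    n_cont_total = sum(1 for rid, _, _ in pairs if _is_contaminant_id(rid))
    return ReadSet(accession=accession, pairs=pairs, n_contaminant=n_cont_total)


def spike_contaminants(
    reads: ReadSet, decoys: dict[str, str], fraction: float, config: SimConfig, rng: np.random.Generator | None = None
) -> ReadSet:
    """Add decoy-derived pairs on top of an existing read set.

    The number added is binomial(n_pairs, fraction); added pairs carry the
    contaminant tag ``c`` in their ids.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if fraction == 0.0:
        return reads
    if not decoys:
        raise ValueError("cannot spike contaminants from an empty decoy set")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    for name, seq in decoys.items():
        if len(seq) < config.read_length:
            raise ValueError(f"decoy {name} shorter than read_length")
    n_add = int(rng.binomial(reads.n_pairs, fraction))
    new_pairs = list(reads.pairs)
    counter = reads.n_pairs
    dnames = sorted(decoys)
    picks = rng.integers(0, len(dnames), size=n_add)
    for d in range(len(dnames)):
        k = int((picks == d).sum())
        if k == 0:
            continue
        dcodes = _encode(decoys[dnames[d]])
        new_pairs.extend(
            _pairs_from_contig(dnames[d], dcodes, k, config, rng, reads.accession, "c", counter)
        )
        counter += k
    return ReadSet(
        accession=reads.accession,
        pairs=new_pairs,
        n_contaminant=reads.n_contaminant + n_add,
    )


def simulate_readsets(sim: PanGenomeSim) -> dict[str, ReadSet]:
    """Reads for every accession, each from an independent child stream of
    the master seed (whole-simulation determinism)."""
    seeds = np.random.SeedSequence(sim.config.seed).spawn(len(sim.genomes))
    out = {}
    for ss, (acc, genome) in zip(seeds, sim.genomes.items()):
        out[acc] = simulate_reads(
            genome, sim.config, accession=acc, rng=np.random.default_rng(ss), decoys=sim.decoys
        )
    return out


# ---------------------------------------------------------------------------
# Truth round-trip


def write_truth(truth: TruthSet, outdir: str | os.PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(truth.pav_truth, outdir / "pav_truth.tsv")
    records = [
        (contig, pos, ref, alt, vtype, gts, None)
        for contig, pos, ref, alt, vtype, gts in truth.variant_truth
    ]
    write_vcf(records, truth.accessions, outdir / "variant_truth.vcf")
    pd.Series(truth.race_of, name="race").rename_axis("accession").to_frame().to_csv(
        outdir / "races.tsv", sep="\t"
    )
    write_gff3(truth.gene_models, outdir / "gene_models.gff3")


def read_truth(outdir: str | os.PathLike) -> TruthSet:
    outdir = Path(outdir)
    pav = read_matrix_tsv(outdir / "pav_truth.tsv").astype(np.int8)
    records, samples = read_vcf(outdir / "variant_truth.vcf")
    variant_truth = [
        (contig, pos, ref, alt, vtype, np.asarray(gts, dtype=np.int8))
        for contig, pos, ref, alt, vtype, gts, _ in records
    ]
    races = pd.read_csv(outdir / "races.tsv", sep="\t", index_col=0)["race"].to_dict()
    models = read_gff3(outdir / "gene_models.gff3")
    return TruthSet(pav_truth=pav, variant_truth=variant_truth, race_of=races, gene_models=models)
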
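"""Coverage-based gene presence/absence calling and pan-genome analytics.

A gene is scored per accession from the breadth of its exonic bases covered
at a minimum read depth; presence requires breadth above a small threshold
(defaults: >=5% of exonic bases at depth >=2, both configurable).  Genes on
assembly contigs shorter than 1 kbp are excluded from the matrix.  Core
genes are present in every accession; variable genes are missing from at
least one.  Pan/core accumulation curves over accession subsets and a
Heaps-type power-law fit to new-gene discovery classify the pan-genome as
open or closed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panbuild import AlignmentRecord, PanAssembly
from .seqio import GeneModel, revcomp


# ---------------------------------------------------------------------------
# gene model lifting (novel genes onto assembled contigs)


def lift_gene_models(
    gene_models: list[GeneModel],
    source_seqs: dict[str, str],
    assembly: PanAssembly,
) -> list[GeneModel]:
    """Re-place gene models onto assembly contigs.

    Models already on an assembly contig are kept.  A model on a donor
    contig (novel gene) is located by exact search of its locus sequence in
    the assembly's novel contigs, on either strand; models that cannot be
    located are dropped with a warning.
    """
    names = {c.id for c in assembly.contigs}
    # search novel contigs when provenance is tracked; otherwise (e.g. an
    # assembly re-read from FASTA) search everything
    novels = [c for c in assembly.contigs if c.provenance != "reference"] or assembly.contigs
    out: list[GeneModel] = []
    for gm in gene_models:
        if gm.contig in names:
            out.append(gm)
            continue
        src = source_seqs.get(gm.contig)
        if src is None:
            warnings.warn(f"no source sequence for donor contig {gm.contig}; dropping {gm.gene_id}")
            continue
        locus = src[gm.start - 1 : gm.end]
        placed = None
        for c in novels:
            p = c.sequence.find(locus)
            if p >= 0:
                exons = tuple((p + s - gm.start + 1, p + e - gm.start + 1) for s, e in gm.exons)
                placed = GeneModel(gm.gene_id, c.id, p + 1, p + len(locus), gm.strand, exons)
                break
            rc = revcomp(locus)
            p = c.sequence.find(rc)
            if p >= 0:
                M = len(locus)
                exons = tuple(
                    sorted(
                        (p + M - (e - gm.start + 1) + 1, p + M - (s - gm.start + 1) + 1)
                        for s, e in gm.exons
                    )
                )
                strand = "-" if gm.strand == "+" else "+"
                placed = GeneModel(gm.gene_id, c.id, p + 1, p + M, strand, exons)
                break
        if placed is None:
            warnings.warn(f"gene {gm.gene_id} not located in assembly; dropped")
        else:
            out.append(placed)
    return out


# ---------------------------------------------------------------------------
# coverage


def depth_arrays(alignments: list[AlignmentRecord], contig_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base read depth per contig from ungapped alignment intervals."""
    depth = {name: np.zeros(length + 1, dtype=np.int32) for name, length in contig_lengths.items()}
    for a in alignments:
        if not a.mapped or a.contig not in depth:
            continue
        d = depth[a.contig]
        end = min(a.start + a.length, d.size - 1)
        d[a.start] += 1
        d[end] -= 1
    return {name: np.cumsum(d[:-1]).astype(np.int32) for name, d in depth.items()}


def gene_coverage(
    alignments: list[AlignmentRecord],
    gene_models: list[GeneModel],
    contig_lengths: dict[str, int],
    accession: str,
    min_depth: int = 2,
) -> pd.DataFrame:
    """Breadth (fraction of exonic bases at >= min_depth) and mean exonic
    depth for every gene, for one accession."""
    for gm in gene_models:
        if gm.contig not in contig_lengths:
            raise ValueError(f"gene {gm.gene_id} lies on unknown contig {gm.contig}")
    depth = depth_arrays(alignments, contig_lengths)
    rows = []
    for gm in gene_models:
        d = depth[gm.contig]
        ex = np.concatenate([d[s - 1 : e] for s, e in gm.exons])
        breadth = float(np.mean(ex >= min_depth)) if ex.size else 0.0
        rows.append((gm.gene_id, accession, breadth, float(ex.mean()) if ex.size else 0.0))
    return pd.DataFrame(rows, columns=["gene", "accession", "breadth", "mean_depth"])


def coverage_table(
    alignments_by_accession: dict[str, list[AlignmentRecord]],
    gene_models: list[GeneModel],
    contig_lengths: dict[str, int],
    min_depth: int = 2,
) -> pd.DataFrame:
    return pd.concat(
        [
            gene_coverage(aln, gene_models, contig_lengths, acc, min_depth=min_depth)
            for acc, aln in alignments_by_accession.items()
        ],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# PAV matrix


@dataclass
class PavMatrix:
    """Binary genes x accessions presence/absence matrix."""

    data: pd.DataFrame  # int8, genes rows, accessions columns
    gene_contig: dict[str, str]
    contig_lengths: dict[str, int]

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.data.columns)


def call_pav(
    coverage: pd.DataFrame,
    gene_models: list[GeneModel],
    contig_lengths: dict[str, int],
    present_breadth: float = 0.05,
    min_contig_len: int = 1000,
) -> PavMatrix:
    """Presence iff breadth >= present_breadth.

    Genes on contigs shorter than ``min_contig_len`` are excluded before the
    matrix is built, and genes absent from every accession are dropped (an
    all-absent gene does not belong to the observed pan-genome).
    """
    gene_contig = {gm.gene_id: gm.contig for gm in gene_models}
    keep = {g for g, c in gene_contig.items() if contig_lengths.get(c, 0) >= min_contig_len}
    table = coverage[coverage["gene"].isin(keep)]
    mat = (
        table.pivot(index="gene", columns="accession", values="breadth")
        .ge(present_breadth)
        .astype(np.int8)
    )
    if mat.isna().any().any():
        raise ValueError("coverage table is missing (gene, accession) pairs")
    mat = mat.loc[mat.sum(axis=1) > 0]
    mat = mat.sort_index()
    return PavMatrix(
        data=mat,
        gene_contig={g: gene_contig[g] for g in mat.index},
        contig_lengths=dict(contig_lengths),
    )


@dataclass
class GeneClassification:
    labels: pd.Series  # "core" | "variable" per gene
    uniquely_present: set[str]
    uniquely_absent: set[str]
    per_accession_counts: pd.Series

    @property
    def core(self) -> set[str]:
        return set(self.labels.index[self.labels == "core"])

    @property
    def variable(self) -> set[str]:
        return set(self.labels.index[self.labels == "variable"])


def classify_genes(matrix: PavMatrix) -> GeneClassification:
    """Core iff present in all accessions; uniquely present/absent iff the
    row sum is 1 or n-1."""
    df = matrix.data
    n = df.shape[1]
    if n < 2:
        raise ValueError("classification requires >= 2 accessions")
    sums = df.sum(axis=1)
    if (sums == 0).any():
        bad = list(df.index[sums == 0])
        raise ValueError(f"matrix contains genes absent everywhere: {bad[:5]}")
    labels = pd.Series(np.where(sums == n, "core", "variable"), index=df.index, name="label")
    return GeneClassification(
        labels=labels,
        uniquely_present=set(df.index[sums == 1]),
        uniquely_absent=set(df.index[sums == n - 1]),
        per_accession_counts=df.sum(axis=0),
    )


def content_summary(classification: GeneClassification, matrix: PavMatrix) -> dict[str, float]:
    """Headline pan-genome content ratios.

    The core fraction is reported against both natural denominators: the
    total pan-gene count and the mean per-accession gene count.
    """
    n_total = matrix.data.shape[0]
    n_core = len(classification.core)
    mean_per_acc = float(classification.per_accession_counts.mean())
    return {
        "n_genes": n_total,
        "n_core": n_core,
        "n_variable": n_total - n_core,
        "core_fraction_of_total": n_core / n_total,
        "core_fraction_of_mean_accession": n_core / mean_per_acc if mean_per_acc else math.nan,
        "variable_fraction_of_total": (n_total - n_core) / n_total,
        "n_uniquely_present": len(classification.uniquely_present),
        "n_uniquely_absent": len(classification.uniquely_absent),
        "uniquely_absent_fraction": len(classification.uniquely_absent) / n_total,
        "mean_genes_per_accession": mean_per_acc,
    }


# ---------------------------------------------------------------------------
# accumulation curves & openness


def accumulation_curves(matrix: PavMatrix, draws_per_N: int = 100, seed: int = 0) -> pd.DataFrame:
    """Mean/s.d. core and pan gene counts across accession subsets of every
    size; exhaustive enumeration whenever C(n, N) <= draws_per_N."""
    arr = matrix.data.to_numpy(dtype=bool)
    n = arr.shape[1]
    if n < 2:
        raise ValueError("accumulation requires >= 2 accessions")
    rng = np.random.default_rng(seed)
    rows = []
    for N in range(1, n + 1):
        if math.comb(n, N) <= draws_per_N:
            subsets = list(itertools.combinations(range(n), N))
        else:
            subsets = [rng.choice(n, size=N, replace=False) for _ in range(draws_per_N)]
        cores, pans = [], []
        for idx in subsets:
            sub = arr[:, list(idx)]
            cores.append(int(sub.all(axis=1).sum()))
            pans.append(int(sub.any(axis=1).sum()))
        rows.append(
            (N, float(np.mean(cores)), float(np.std(cores)), float(np.mean(pans)), float(np.std(pans)), len(subsets))
        )
    return pd.DataFrame(rows, columns=["N", "core_mean", "core_sd", "pan_mean", "pan_sd", "n_draws"])


@dataclass
class OpennessFit:
    kappa: float
    alpha: float
    label: str  # "open" | "closed"
    residual: float


def fit_openness(curve: pd.DataFrame) -> OpennessFit:
    """Fit new-gene discovery dPan(N) = kappa * N^(-alpha) by least squares
    on log-transformed positive increments; closed iff alpha > 1
    (Heaps'-law convention)."""
    if len(curve) < 4:
        raise ValueError("openness fit needs >= 4 sample sizes")
    pan = curve["pan_mean"].to_numpy()
    N = curve["N"].to_numpy()
    inc = np.diff(pan)
    xs, ys = N[1:], inc
    pos = ys > 0
    if pos.sum() < 2:
        return OpennessFit(kappa=float("inf"), alpha=float("inf"), label="closed", residual=0.0)
    lx, ly = np.log(xs[pos]), np.log(ys[pos])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = float(np.mean((ly - (slope * lx + intercept)) ** 2))
    alpha = -float(slope)
    kappa = float(np.exp(intercept))
    return OpennessFit(kappa=kappa, alpha=alpha, label="closed" if alpha > 1 else "open", residual=resid)


# ---------------------------------------------------------------------------
# race-specific genes


def race_specific_genes(
    matrix: PavMatrix,
    race_of: dict[str, str],
    exclude: tuple[str, ...] = ("admixed",),
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Per-race specific gene sets and the shared-gene table.

    A gene is specific to race r iff it is present in at least one accession
    of r and absent from every accession of every other race.  Accessions
    with no label, or whose label is in ``exclude`` (admixed individuals),
    are left out with a warning.  The shared table counts genes by the exact
    set of races in which they occur.
    """
    labelled = {}
    skipped = []
    for acc in matrix.accessions:
        r = race_of.get(acc)
        if r is None or r in exclude:
            skipped.append(acc)
        else:
            labelled[acc] = r
    if skipped:
        warnings.warn(f"excluding {len(skipped)} unlabelled/admixed accessions: {skipped[:5]}")
    races = sorted(set(labelled.values()))
    if len(races) < 2:
        raise ValueError("race specificity requires >= 2 races")
    df = matrix.data[list(labelled)]
    present_races: list[frozenset] = []
    for _, row in df.iterrows():
        rs = frozenset(labelled[a] for a in df.columns[row.to_numpy(dtype=bool)])
        present_races.append(rs)
    specific = {r: set() for r in races}
    combo_counts: dict[frozenset, int] = {}
    for gene, rs in zip(df.index, present_races):
        if len(rs) == 1:
            specific[next(iter(rs))].add(gene)
        if rs:
            combo_counts[rs] = combo_counts.get(rs, 0) + 1
    shared = pd.DataFrame(
        sorted(
            ((len(k), "+".join(sorted(k)), v) for k, v in combo_counts.items()),
            key=lambda t: (t[0], t[1]),
        ),
        columns=["n_races", "races", "n_genes"],
    )
    return specific, shared
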
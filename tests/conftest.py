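"""Shared fixtures: small simulated panels and one full pipeline run.

The expensive end-to-end run (20 accessions, 300 genes, 10x error-free
reads) is session-scoped and shared between the recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from panforge import (
    SimConfig,
    build_pangenome,
    call_pav,
    classify_genes,
    coverage_table,
    lift_gene_models,
    map_reads,
    simulate_pangenome,
    simulate_readsets,
)
from panforge.panbuild import KmerIndex


@dataclass
class PipelineRun:
    cfg: SimConfig
    sim: object
    readsets: dict
    assembly: object
    models: list
    contig_lengths: dict
    alignments: dict
    matrix: object
    classification: object


def run_pipeline(cfg: SimConfig) -> PipelineRun:
    sim = simulate_pangenome(cfg)
    readsets = simulate_readsets(sim)
    assembly = build_pangenome(sim.reference, list(readsets.values()), decoys=sim.decoys)
    source_seqs = {c: sim.genomes[a][c] for a in sim.genomes for c in sim.genomes[a]}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models = lift_gene_models(sim.gene_models, source_seqs, assembly)
    lengths = {c.id: c.length for c in assembly.contigs}
    index = KmerIndex(assembly)
    alignments = {
        acc: map_reads(rs, assembly, index=index)[0] for acc, rs in readsets.items()
    }
    cov = coverage_table(alignments, models, lengths)
    matrix = call_pav(cov, models, lengths)
    return PipelineRun(
        cfg=cfg,
        sim=sim,
        readsets=readsets,
        assembly=assembly,
        models=models,
        contig_lengths=lengths,
        alignments=alignments,
        matrix=matrix,
        classification=classify_genes(matrix),
    )


@pytest.fixture(scope="session")
def small_run() -> PipelineRun:
    """A quick 6-accession panel for unit-level pipeline checks."""
    cfg = SimConfig(
        seed=11, n_accessions=6, n_core_genes=30, n_variable_genes=15,
        n_contigs=2, contig_length=20_000, admixture_fraction=0.0,
        snp_rate=0.001, indel_rate=0.0, coverage=10, error_rate=0.0,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def full_run() -> PipelineRun:
    """The full recovery panel: 20 accessions, 200 core + 100 variable
    genes in 4 races, 10x error-free reads."""
    cfg = SimConfig(
        seed=7, n_accessions=20, n_core_genes=200, n_variable_genes=100,
        n_contigs=4, contig_length=60_000, admixture_fraction=0.0,
        snp_rate=0.001, indel_rate=0.0, coverage=10, error_rate=0.0,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def variant_run() -> PipelineRun:
    """Panel tuned for variant-recovery checks: 20x coverage, base error
    1e-3, ~100+ planted SNPs, no gene PAV interference."""
    cfg = SimConfig(
        seed=5, n_accessions=12, n_core_genes=80, n_variable_genes=0,
        n_contigs=2, contig_length=30_000, admixture_fraction=0.0,
        snp_rate=0.002, indel_rate=0.0, coverage=20, error_rate=0.001,
    )
    return run_pipeline(cfg)
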
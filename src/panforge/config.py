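"""Simulation configuration.

A :class:`SimConfig` fixes every knob of the synthetic pan-genome generator:
population structure (races, admixture), gene content (core vs variable),
sequence composition, planted variation, and sequencing (coverage, read
length, insert distribution, error rate, organelle-like contamination).
Identical configs with identical seeds produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class CapacityError(ValueError):
    """Requested gene content does not fit on the configured contigs."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic inbred-line pan-genome.

    Accessions are fully homozygous inbred lines structured into ``n_races``
    botanical races plus a fraction of admixed individuals.  All accessions
    share ``n_core_genes``; each of ``n_variable_genes`` is present in a
    race-dependent subset.  Sequencing defaults follow the mapping contract
    of the analysis: >=10x coverage, paired 100 bp reads with inserts
    confined to [0, 1000] bp.
    """

    seed: int = 0
    n_accessions: int = 20
    n_races: int = 4
    admixture_fraction: float = 0.1
    n_core_genes: int = 200
    n_variable_genes: int = 100
    gene_length_range: tuple[int, int] = (300, 600)
    intergenic_length: int = 150
    contig_length: int = 60_000
    n_contigs: int = 4
    # Per-(gene, race) presence probabilities; drawn from a U-shaped Beta
    # when None so variable genes discriminate between races.
    variable_gene_presence_prob: tuple[tuple[float, ...], ...] | None = None
    presence_beta: tuple[float, float] = (0.3, 0.3)
    snp_rate: float = 0.001
    indel_rate: float = 1e-4
    max_indel_len: int = 10
    read_length: int = 100
    insert_mean: int = 300
    insert_sd: int = 60
    insert_range: tuple[int, int] = (0, 1000)
    coverage: float = 10.0
    error_rate: float = 0.0
    contaminant_fraction: float = 0.0
    # Whole-locus deletion flank for absent variable genes (clean PAV signal).
    deletion_flank: int = 200
    # Flank around novel (non-reference) gene donor segments; sized so
    # assembled novel contigs clear the 1 kbp gene-model contig filter even
    # after edge losses inherent to single-accession assembly.
    novel_flank: int = 600
    # Read ids carry origin coordinates unless disabled (production mode).
    tag_read_origin: bool = True

    def __post_init__(self) -> None:
        counts = {
            "n_accessions": self.n_accessions,
            "n_races": self.n_races,
            "n_core_genes": self.n_core_genes,
            "n_variable_genes": self.n_variable_genes,
            "intergenic_length": self.intergenic_length,
            "contig_length": self.contig_length,
            "n_contigs": self.n_contigs,
            "read_length": self.read_length,
            "deletion_flank": self.deletion_flank,
            "novel_flank": self.novel_flank,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        for name in ("admixture_fraction", "error_rate", "contaminant_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.coverage <= 0:
            raise ValueError(f"coverage must be > 0, got {self.coverage}")
        if not 0.0 <= self.snp_rate <= 1.0 or not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("snp_rate and indel_rate must be in [0, 1]")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid gene_length_range {self.gene_length_range}")
        ilo, ihi = self.insert_range
        if ilo < 0 or ihi < ilo:
            raise ValueError(f"invalid insert_range {self.insert_range}")
        if self.variable_gene_presence_prob is not None:
            table = self.variable_gene_presence_prob
            if len(table) != self.n_variable_genes:
                raise ValueError("presence table must have one row per variable gene")
            for row in table:
                if len(row) != self.n_races:
                    raise ValueError("presence table rows must have one entry per race")
                if any(not 0.0 <= p <= 1.0 for p in row):
                    raise ValueError("presence probabilities must be in [0, 1]")
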
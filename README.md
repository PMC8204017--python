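# panforge

Desk-scale pan-genome construction and analysis for panels of inbred crop
accessions, modelled on the iterative-assembly pan-genomics used for
selfing cereals such as sorghum.

A single reference genome misses sequence that is present only in other
accessions of the species.  The iterative map-and-assemble strategy
recovers it: reads from each accession are mapped to the current assembly,
the unmapped reads are assembled, and contigs above a length cut-off are
appended, then contaminant- and redundancy-filtered.  Reads are then
remapped to the finished pan-genome and each gene is scored
present/absent per accession from read-coverage breadth, yielding the
gene presence/absence variation (gPAV) matrix **P** ∈ {0,1}^(genes ×
accessions).  From **P** the package derives:

- **core genes** (rows of all ones) vs **variable genes** (absent
  somewhere), uniquely present/absent genes, and per-accession counts;
- pan/core **accumulation curves** over accession subsets, with the
  openness fit ΔPan(N) = κ·N^(−α) — α > 1 marks a *closed* pan-genome
  (Heaps'-law convention);
- neighbour-joining trees (Saitou–Nei) with character-bootstrap supports,
  and classical PCoA of PAV or SNP distances;
- pileup **SNP calls** under a homozygous inbred-line model, the
  missingness ≤ 0.15 / minor-allele-count ≥ 2 site filters, region and
  codon-effect annotation, Ts/Tv, 80 kb windowed density, and
  Nei–Gojobori Ka/Ks;
- a single-marker **association scan** (OLS with optional PCoA
  covariates, Benjamini–Hochberg FDR) with the three-part significance
  rule −log10(p) > 2.5 ∧ p < 0.05 ∧ q < 0.05, genic/intergenic hit
  annotation, Fisher-exact GO enrichment with the **elim** procedure, and
  the DEG threshold rule (q < 0.05, |log2FC| > 2).

Everything runs on one core against synthetic data from the built-in
simulator, which generates race-structured populations of homozygous
accessions with planted PAV, SNPs, indels and organelle-like contaminant
reads — with full ground truth for scoring.  See `docs/methods.md` for
the models, defaults and their rationale.

## Worked example

```python
from panforge import (SimConfig, simulate_pangenome, simulate_readsets,
                      build_pangenome, lift_gene_models, map_reads,
                      coverage_table, call_pav, classify_genes,
                      content_summary, accumulation_curves, fit_openness,
                      bootstrap_support)
from panforge.panbuild import KmerIndex

cfg = SimConfig(seed=1, n_accessions=8, n_core_genes=60, n_variable_genes=30,
                n_contigs=2, contig_length=30_000, admixture_fraction=0.0,
                coverage=10)
sim = simulate_pangenome(cfg)
reads = simulate_readsets(sim)

assembly = build_pangenome(sim.reference, list(reads.values()),
                           decoys=sim.decoys)

source = {c: g[c] for g in sim.genomes.values() for c in g}
models = lift_gene_models(sim.gene_models, source, assembly)
lengths = {c.id: c.length for c in assembly.contigs}
index = KmerIndex(assembly)
aln = {acc: map_reads(rs, assembly, index=index)[0]
       for acc, rs in reads.items()}
matrix = call_pav(coverage_table(aln, models, lengths), models, lengths)

cls = classify_genes(matrix)
summary = content_summary(cls, matrix)
fit = fit_openness(accumulation_curves(matrix, seed=1))
tree = bootstrap_support(matrix.data.T, B=1000, seed=1)
```

Output of the session above:

```
pan-assembly: 19 contigs, 84,627 bp (17 novel)
core 60 / 89 genes (67.4%), 29 variable, 1 uniquely present, 2 uniquely absent
openness: alpha = 2.62 -> closed pan-genome
NJ tree: 5 internal splits, bootstrap support 60-100
PAV calls match simulated truth at 100.0% of cells
```

Reading it: the build recovered 17 novel contigs carrying the variable
genes absent from the reference accession; coverage-based calling then
classified 60 of 89 matrix genes as core (one variable gene was present in
a single accession only, two were absent from a single accession); the
quickly-exhausted variable pool makes discovery fall off faster than 1/N
(α ≈ 2.6), i.e. a closed pan-genome; and the PAV matrix reproduces the
simulator's truth exactly.

A thin CLI wraps the same functions:

```bash
panforge simulate --config cfg.json --seed 1 --outdir sim/
panforge build --ref sim/reference.fasta --reads manifest.tsv \
               --decoys sim/decoys.fasta --out pan.fasta
panforge pav --assembly pan.fasta --reads manifest.tsv \
             --gff sim/gene_models.gff3 --out pav.tsv
panforge tree --input pav.tsv --bootstrap 1000 --seed 42 --out pav.nwk
panforge deg --expression expr.tsv --out deg.tsv
```

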
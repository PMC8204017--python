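# Methods

`panforge` re-creates, at desk scale, the computational skeleton of an
iterative-assembly crop pan-genome study: build a pan-genome from short
reads of many inbred accessions, call gene presence/absence variation (PAV)
from read coverage, characterise core and variable gene content, estimate
relationships among accessions, call and annotate SNPs, and run downstream
trait association, GO enrichment and differential-expression
classification.  Every stage is exercised against synthetic data whose
ground truth the package itself generates.

## The synthetic population

The simulator emulates a panel of fully homozygous inbred lines — the
natural model for a selfing crop such as sorghum, where sequenced
accessions behave as lines and planted variants have unambiguous truth
genotypes.  Accessions are organised into `n_races` botanical races
(labelled with sorghum race names) plus an optional fraction of admixed
individuals that mix two races' parameters 50:50.

Gene content.  All accessions share `n_core_genes`.  Each of
`n_variable_genes` carries a per-race presence probability; unless supplied
explicitly, probabilities are drawn from a U-shaped Beta(0.3, 0.3), so most
variable genes are near-fixed present in some races and near-fixed absent
in others — the race-discriminating structure that makes PAV phylogenies
and ordination informative.  Rows that come out all-present or all-absent
are redrawn (a variable gene must be present somewhere and absent
somewhere); a gene whose probabilities make that impossible raises an
error.

The first accession is the designated reference.  Its gene content defines
the reference contigs; variable genes absent from it form the novel pool
and exist only in non-reference genomes, each on its own donor segment with
600 bp flanks.  The flank size is chosen so that a novel segment (gene ≥
300 bp + 1200 bp flanks) still exceeds the 1 kbp contig threshold of the
PAV stage after the edge losses inherent to assembling one accession's
reads at 10x.  Absent genes are simulated as deletion of the full locus
plus 200 bp flanks, clamped so a deletion never intrudes into a
neighbouring gene's span — without the clamp, two absent neighbours can
clip a present gene and corrupt its coverage signal.

Variants.  SNPs are planted on reference contigs at `snp_rate` per bp with
race-correlated allele frequencies (per-site race frequencies from
Beta(0.5, 0.5)); short indels (1–10 bp) are confined to intergenic space so
they never disturb coding frames or PAV signals.  The reference accession
carries the reference allele everywhere, so the reference FASTA is exactly
its backbone.  Truth genotypes inside a deleted locus are recorded as
missing.

Reads.  Paired 100 bp reads at a target fold coverage (default 10x, the
study's stated minimum), inserts Normal(300, 60) clipped to [0, 1000] (the
mapping contract's insert window), uniform substitution errors at
`error_rate`, constant quality characters, and an optional binomial share
of pairs drawn from two organelle-like decoy contigs to exercise the
contamination filter.  Read ids encode origin coordinates for truth-aware
tests; production mode can disable the tagging.  Identical config + seed
reproduces byte-identical output; per-accession read streams are spawned
from the master seed.

What the simulator does not model: base-quality profiles, heterozygosity,
transposons, structural variation beyond whole-gene PAV, GC bias, or
homology between genes (gene sequences are i.i.d. random).  Passing tests
therefore demonstrate the pipeline's correctness on clean, repeat-free
signal, not its robustness to paralogy or repetitive DNA.

## Pan-genome construction

Iterative map-and-assemble, one accession at a time, in input order
(logged):

1. **Mapping** — an internal k-mer seed-and-extend mapper: 31-mer seeds at
   three read offsets, candidate loci verified by substitution counting
   (max 4 mismatches per 100 bp read by default).  Pairs are evaluated
   per-mate with pair rescue: when one mate maps, the partner is scanned
   for within the ±1000 bp insert window by brute force.  The three-seed
   scheme is a heuristic: a read whose every seed is mutated can be missed
   even with ≤4 total mismatches, which is immaterial at the error rates
   simulated here.  Every mate lands in exactly one of mapped/unmapped.
2. **Assembly** — unmapped reads are assembled by greedy
   maximal-exact-overlap extension (minimum 31 bp exact overlap, both
   strands, deterministic tie-breaks).  Only contigs strictly longer than
   500 bp are kept.
3. **Append** — passing contigs join the assembly with provenance
   (accession, iteration); per-iteration added bp are logged.

After the loop, two homology filters run.  Pairwise coverage/identity is
computed with Biopython's `PairwiseAligner` (local mode, match +1, mismatch
−2, gaps −4/−2) on k-mer-prescreened candidate pairs; the scoring keeps
≥85 %-identity alignments extending while random-sequence extension is
unprofitable, so the 90 % thresholds discriminate cleanly.  The
contamination filter removes novel contigs ≥90 % covered at ≥90 % identity
by an organelle-like decoy (taxonomy screening is reduced to decoy-FASTA
screening; no remote databases).  The redundancy filter removes novel
contigs >90 % covered at >90 % identity by another retained sequence,
processing by descending length so the longer copy survives; it is
idempotent.  Whether novel contigs are compared only among themselves
(`self`, the default, matching a self-comparison reading of the protocol)
or also against the reference (`all`) is a mode switch.

Known limitation: at 10x a novel segment occasionally fragments into
pieces on either side of the 500 bp cut-off during the first carrier's
iteration and is then unrecoverable (later carriers' reads map to the
retained piece).  In the 20-accession recovery panel this costs about one
gene in 300 — visible as PAV cell accuracy ≈99.7 % rather than 100 %.

## PAV calling and content analytics

Gene models are lifted onto the assembly by exact locus search (novel genes
onto assembled contigs, either strand).  Per accession, exonic per-base
depth is accumulated from alignment intervals; breadth is the fraction of
exonic bases covered at depth ≥2, and a gene is present when breadth ≥5 %.
Both cutoffs are deliberate package defaults in the spirit of the
coverage-based PAV literature (the protocol this mirrors does not print
its numbers) and are config keys.  Exonic rather than full-locus breadth
makes the call invariant to intron length.  Genes on contigs shorter than
1 kbp are excluded before matrix construction, and a gene absent from every
accession is dropped (it is not part of the observed pan-genome).

Classification is by row sums: core = present in all; variable = missing
somewhere; uniquely present / uniquely absent = row sum 1 / n−1.  The
content summary reports the core fraction against both natural
denominators (total pan-genes and mean per-accession genes), since the
headline "47 %" admits either reading.

Accumulation curves draw `draws_per_N` accession subsets per sample size
(exhaustive when C(n, N) is smaller), reporting means and s.d. of core and
pan counts.  Openness fits the new-gene discovery increments ΔPan(N) =
κ·N^(−α) by least squares on log-transformed positive increments —
Heaps'-law convention: α > 1 ⇒ closed, α ≤ 1 ⇒ open; a curve with no
positive increments is closed with α = ∞.

Race-specific genes: present in ≥1 accession of one race and absent from
every accession of all other races; admixed or unlabelled accessions are
excluded with a warning.  A shared-gene table counts genes by the exact
race set in which they occur.

## Variants

The caller is a deterministic homozygous pileup, appropriate for inbred
lines: after collapsing duplicate fragments (identical mate coordinates),
per accession and site the genotype is alt when depth ≥5 and the alt base
fraction ≥0.8, ref when the fraction ≤0.2, missing otherwise; a site is
emitted when at least one accession is alt.  Site filters retain
missingness ≤0.15 and minor allele count ≥2.  Indels are carried by the
simulator's truth (VCF) rather than called — gapped realignment is out of
scope, and the mapper is substitution-only.

Annotation assigns one region class per site with precedence exon > intron
> upstream > downstream > intergenic; upstream/downstream windows are 5 kb
respecting strand (a common annotation default; config key).  Exonic SNP
effects come from the standard codon table on the spliced, strand-aware
frame (stop-gain = nonsense; stop-loss is reported as missense).  Ts/Tv
counts transitions (A↔G, C↔T) over transversions and refuses a zero
denominator.  Windowed density uses non-overlapping 80 kb windows, 1-based
positions, window w covering [80000·w+1, 80000·(w+1)].

Ka/Ks is the Nei–Gojobori approximate method without multiple-hit
correction: synonymous site counts weight each codon position by the
fraction of its three one-step changes that are synonymous; observed
substitutions are scored against the reference codon (multiple hits in one
codon are scored independently, adequate at the planted densities).  A
gene with Ks = 0 reports an undefined ratio with a flag, categorised from
Ka alone.

## Trees and ordination

Distances over the binary PAV matrix default to simple matching (mismatch
fraction; robust default for binary data), with Jaccard over present-gene
sets as the alternative; SNP character distances ignore missing codes
pairwise.  Neighbour joining follows the Saitou–Nei Q-criterion with
deterministic tie-breaking (lexicographically smallest label pair);
negative branch lengths are clamped to zero and flagged.  For additive
inputs the tree's path metric reproduces the input to numerical precision
(tested to 1e−9 against 100 random trees and cross-checked against
scikit-bio).  Bootstrap resamples characters with replacement (default
B = 1000), rebuilds the tree per replicate, and scores each original
bipartition by the percentage of replicates containing it.  PCoA is
classical metric scaling: eigendecomposition of the double-centred squared
distance matrix; negative eigenvalues are reported but never yield
coordinates.

## Association, enrichment, DEGs

The association scan is ordinary least squares per site — slope t-test
with per-site mean imputation of missing genotypes and optional covariates
(e.g. leading PCoA axes) partialled out of phenotype and genotypes — with
Benjamini–Hochberg q-values across all tested sites.  This replaces a
kinship mixed model deliberately: at desk scale the OLS scan has testable
type-I and power behaviour (null ≈5 % raw p < 0.05; a planted QTL
explaining half the variance at n = 150 passes the full filter in ≈100 %
of replicates).  The significance rule is applied literally as printed in
the protocol this mirrors: −log10(p) > 2.5 AND p < 0.05 AND q < 0.05, with
the 2.5 as a fixed constant (it is labelled a Bonferroni cut-off upstream,
but it is a constant, not a function of the number of tests).  Hits are
genic iff inside a gene span, 1-based inclusive.

GO enrichment is a one-sided Fisher exact (hypergeometric upper tail) per
term, with annotations propagated to ancestors, plus the elim
decorrelation: terms are processed from the deepest level (longest-path
depth from the roots, ties in term-id order) upward, and once a term is
significant at alpha its annotated study genes are removed from all its
ancestors before those are tested.  With alpha = 0, or when nothing is
significant, elim equals classical Fisher.  DEG classification is the
threshold rule: up iff q < 0.05 and log2FC > 2, down iff q < 0.05 and
log2FC < −2, otherwise not differentially expressed; rows lacking q are
flagged.

## Problem sizes and numerics

The recovery panel is 20 accessions × (200 core + 100 variable) genes on
four 60 kb contigs at 10x — large enough for race structure, novel-pool
assembly and bootstrap supports to be meaningful, small enough to run on
one core in about a minute.  The variant panel uses 12 accessions at 20x
with base error 1e−3 and ~150 planted SNPs.  Statistical checks use 100
replicates each.  All randomness flows from explicit seeds
(`numpy.random.Generator`; per-accession streams via `SeedSequence.spawn`),
and every stage is deterministic given its inputs.  Coordinates are
0-based half-open internally and 1-based inclusive at the GFF3/VCF
boundaries, with converters exercised in both directions by the round-trip
tests.
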
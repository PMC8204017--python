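"""Mapper, assembler, iterative build and homology filters."""

import numpy as np
import pytest

from panforge import (
    SimConfig,
    assemble_unmapped,
    filter_contaminants,
    iterate_build,
    map_reads,
    remove_redundant,
    simulate_reads,
)
from panforge.panbuild import Contig, PanAssembly, homology
from panforge.pansim import ReadSet
from panforge.seqio import revcomp


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _assembly(**contigs):
    out = PanAssembly()
    for name, seq in contigs.items():
        prov = "reference" if name.startswith("ref") else "acc/iteration1"
        out.contigs.append(Contig(name, seq, prov))
    return out


def _pairs(reads):
    """Wrap single-end test reads as pairs of identical mates."""
    return ReadSet(accession="T", pairs=[(f"T|p{i}", r, r) for i, r in enumerate(reads)])


def brute_force_best_mismatches(read, contig):
    """Oracle: minimum substitution count over all offsets and strands."""
    best = len(read) + 1
    for seq in (read, revcomp(read)):
        for s in range(len(contig) - len(read) + 1):
            mm = sum(a != b for a, b in zip(seq, contig[s : s + len(read)]))
            best = min(best, mm)
    return best


class TestMapper:
    def test_exact_substring_maps_with_zero_mismatches(self):
        ref = _random_seq(2000, 1)
        read = ref[500:600]
        aln, un = map_reads(_pairs([read]), _assembly(ref1=ref), pair_rescue=False)
        assert not un
        assert all(a.mismatches == 0 and a.start == 500 and a.strand == "+" for a in aln)

    def test_reverse_complement_read_maps(self):
        ref = _random_seq(2000, 2)
        read = revcomp(ref[700:800])
        aln, _ = map_reads(_pairs([read]), _assembly(ref1=ref), pair_rescue=False)
        assert aln and aln[0].start == 700 and aln[0].strand == "-"

    def test_read_from_absent_region_is_unmapped(self):
        ref = _random_seq(2000, 3)
        novel = _random_seq(100, 99)
        aln, un = map_reads(_pairs([novel]), _assembly(ref1=ref), pair_rescue=False)
        assert not aln and len(un) == 2

    @pytest.mark.parametrize("n_subs,expect_mapped", [(4, True), (5, False)])
    def test_mismatch_budget_boundary(self, n_subs, expect_mapped):
        """A read with exactly max_mismatch+1 substitutions vs its best locus
        is unmapped (verified against a brute-force scan oracle)."""
        ref = _random_seq(3000, 4)
        read = list(ref[1000:1100])
        rng = np.random.default_rng(0)
        # substitutions confined to the first seed window so the mapper's
        # other seeds stay intact; the oracle checks the true best count
        for pos in rng.choice(np.arange(0, 31), size=n_subs, replace=False):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        read = "".join(read)
        assert brute_force_best_mismatches(read, ref) == n_subs
        aln, un = map_reads(_pairs([read]), _assembly(ref1=ref), max_mismatch=4, pair_rescue=False)
        assert bool(aln) == expect_mapped

    def test_partition_mapped_plus_unmapped_equals_reads(self):
        cfg = SimConfig(seed=20, coverage=5, error_rate=0.01, n_accessions=1)
        ref = {"ref1": _random_seq(12_000, 5)}
        rs = simulate_reads(ref, cfg, accession="A")
        aln, un = map_reads(rs, _assembly(ref1=ref["ref1"]))
        assert len(aln) + len(un) == 2 * rs.n_pairs
        ids = {a.read_id for a in aln} | {u[0] for u in un}
        assert len(ids) == 2 * rs.n_pairs

    def test_pair_rescue_recovers_mate_near_partner(self):
        ref = _random_seq(5000, 6)
        r1 = ref[1000:1100]
        r2 = revcomp(ref[1200:1300])
        # heavily mutated mate: unmapped alone, rescued via partner window
        noisy = list(r2)
        rng = np.random.default_rng(1)
        # leave no intact 31-mer so seeding fails but <=4 mismatches remain
        for pos in (10, 45, 75):
            noisy[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[pos]]
        noisy = "".join(noisy)
        reads = ReadSet(accession="T", pairs=[("T|p0", r1, noisy)])
        aln_no, _ = map_reads(reads, _assembly(ref1=ref), pair_rescue=False)
        aln_yes, _ = map_reads(reads, _assembly(ref1=ref), pair_rescue=True)
        assert len(aln_yes) >= len(aln_no)
        assert {a.read_id for a in aln_yes} == {"T|p0/1", "T|p0/2"}


class TestAssembler:
    def _tiling_reads(self, segment, step=10, rl=100):
        return [segment[i : i + rl] for i in range(0, len(segment) - rl + 1, step)]

    def test_reads_tiling_600bp_segment_assemble_to_one_contig(self):
        seg = _random_seq(600, 7)
        contigs = assemble_unmapped(self._tiling_reads(seg))
        assert len(contigs) == 1
        assert seg in contigs[0] or revcomp(seg) in contigs[0]

    def test_400bp_segment_filtered_by_length(self):
        seg = _random_seq(400, 8)
        assert assemble_unmapped(self._tiling_reads(seg)) == []

    def test_empty_input_empty_output(self):
        assert assemble_unmapped([]) == []

    def test_mixed_strand_reads_assemble(self):
        seg = _random_seq(700, 9)
        reads = self._tiling_reads(seg)
        reads = [r if i % 2 == 0 else revcomp(r) for i, r in enumerate(reads)]
        contigs = assemble_unmapped(reads)
        assert len(contigs) == 1
        assert seg in contigs[0] or revcomp(seg) in contigs[0]


class TestIterativeBuild:
    def test_accessions_identical_to_reference_add_nothing(self):
        cfg = SimConfig(seed=21, coverage=10, n_accessions=2)
        ref = {"ref1": _random_seq(12_000, 10)}
        readsets = [simulate_reads(ref, cfg, accession=f"A{i}") for i in range(2)]
        asm = iterate_build(ref, readsets)
        assert asm.added_bp == [0, 0]
        assert len(asm.contigs) == 1

    def test_shared_novel_segment_assembled_in_first_iteration_only(self):
        cfg = SimConfig(seed=22, coverage=10, n_accessions=2)
        ref = {"ref1": _random_seq(10_000, 11)}
        novel = _random_seq(1000, 12)
        genome = {"ref1": ref["ref1"][:5000] + novel + ref["ref1"][5000:]}
        readsets = [simulate_reads(genome, cfg, accession=f"A{i}",
                                   rng=np.random.default_rng(i)) for i in range(2)]
        asm = iterate_build(ref, readsets)
        assert asm.added_bp[0] > 800
        assert asm.added_bp[1] < 200
        # order reversal leaves the novel total unchanged within edge effects
        asm_rev = iterate_build(ref, readsets[::-1])
        assert abs(sum(asm.added_bp) - sum(asm_rev.added_bp)) < 250

    def test_monotone_assembly_growth(self):
        cfg = SimConfig(seed=23, coverage=10, n_accessions=3)
        ref = {"ref1": _random_seq(8_000, 13)}
        genomes = [
            {"ref1": ref["ref1"] + _random_seq(800, 50 + i)} for i in range(3)
        ]
        readsets = [simulate_reads(g, cfg, accession=f"A{i}",
                                   rng=np.random.default_rng(i)) for i, g in enumerate(genomes)]
        asm = iterate_build(ref, readsets)
        assert all(b >= 0 for b in asm.added_bp)

    def test_novel_region_recovered_exactly_once(self):
        """A 2 kb region private to 3 of 6 accessions ends up covered >=95%
        by exactly one pan-assembly contig."""
        cfg = SimConfig(seed=24, coverage=10, n_accessions=6)
        ref = {"ref1": _random_seq(10_000, 14)}
        novel = _random_seq(2000, 15)
        carrier = {"ref1": ref["ref1"][:4000] + novel + ref["ref1"][4000:]}
        readsets = []
        for i in range(6):
            g = carrier if i < 3 else ref
            readsets.append(simulate_reads(g, cfg, accession=f"A{i}",
                                           rng=np.random.default_rng(100 + i)))
        asm = remove_redundant(iterate_build(ref, readsets))
        covering = [c for c in asm.novel_contigs if homology(novel, c.sequence)[0] >= 0.95]
        assert len(covering) == 1


class TestHomologyFilters:
    def test_exact_decoy_copy_removed(self):
        decoy = _random_seq(1200, 16)
        asm = _assembly(ref1=_random_seq(2000, 17), novel1=decoy)
        out = filter_contaminants(asm, {"mito": decoy})
        assert [c.id for c in out.contigs] == ["ref1"]
        assert out.filter_log[0]["reason"] == "contaminant"

    def test_contig_without_shared_kmer_retained(self):
        asm = _assembly(ref1=_random_seq(2000, 18), novel1=_random_seq(1000, 19))
        out = filter_contaminants(asm, {"mito": _random_seq(1500, 20)})
        assert len(out.contigs) == 2

    def test_half_covered_contig_retained_at_09_threshold(self):
        decoy = _random_seq(1500, 21)
        novel = decoy[:500] + _random_seq(500, 22)  # 50% decoy-derived
        cov, ident = homology(novel, decoy)
        assert 0.4 <= cov <= 0.6
        asm = _assembly(ref1=_random_seq(2000, 23), novel1=novel)
        out = filter_contaminants(asm, {"mito": decoy}, min_cov=0.9, min_id=0.9)
        assert len(out.contigs) == 2

    def test_reference_contigs_never_removed(self):
        seq = _random_seq(1500, 24)
        asm = _assembly(ref1=seq)
        out = filter_contaminants(asm, {"mito": seq})
        assert [c.id for c in out.contigs] == ["ref1"]

    def test_duplicate_novel_contig_removed_once(self):
        seq = _random_seq(1200, 25)
        asm = _assembly(ref1=_random_seq(2000, 26), novel1=seq, novel2=seq)
        out = remove_redundant(asm)
        assert sum(c.sequence == seq for c in out.contigs) == 1

    def test_redundant_with_reference_removed_only_in_all_mode(self):
        """A contig 95% covered at ~95% identity by the reference crosses
        both thresholds and is removed when reference comparison is on."""
        ref = _random_seq(4000, 27)
        piece = list(ref[1000:2000])
        rng = np.random.default_rng(3)
        for pos in rng.choice(len(piece), size=50, replace=False):  # ~95% identity
            piece[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[piece[pos]]
        novel = "".join(piece) + _random_seq(50, 28)  # ~95% covered
        asm = _assembly(ref1=ref, novel1=novel)
        assert len(remove_redundant(asm, mode="self").novel_contigs) == 1
        assert len(remove_redundant(asm, mode="all").novel_contigs) == 0

    def test_low_identity_contig_retained(self):
        """95% covered but only ~85% identity stays below the identity bar."""
        ref = _random_seq(4000, 29)
        piece = list(ref[1000:2000])
        rng = np.random.default_rng(4)
        for pos in rng.choice(len(piece), size=150, replace=False):  # ~85% identity
            piece[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[piece[pos]]
        novel = "".join(piece) + _random_seq(50, 30)
        cov, ident = homology(novel, ref)
        assert ident < 0.9
        asm = _assembly(ref1=ref, novel1=novel)
        assert len(remove_redundant(asm, mode="all").novel_contigs) == 1

    def test_remove_redundant_idempotent(self):
        seq = _random_seq(1200, 31)
        asm = _assembly(ref1=_random_seq(2000, 32), novel1=seq, novel2=seq,
                        novel3=_random_seq(900, 33))
        once = remove_redundant(asm)
        twice = remove_redundant(once)
        assert [c.id for c in once.contigs] == [c.id for c in twice.contigs]
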
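"""Variant calling, site filters, annotation, Ts/Tv, density and Ka/Ks."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from panforge import (
    annotate_variants,
    filter_variants,
    indel_size_spectrum,
    kaks_ratio,
    tstv_ratio,
    variant_density,
)
from panforge.panbuild import Contig, PanAssembly
from panforge.seqio import GeneModel, revcomp
from panforge.variants import (
    GenotypeMatrix,
    VariantRecord,
    classify_coding_snp,
    collapse_duplicates,
    synonymous_fraction,
    translate_codon,
)

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]


def _gm_matrix(rows, contig="c1"):
    gt = np.asarray(rows, dtype=np.int8)
    sites = pd.DataFrame({"contig": contig, "position": np.arange(1, len(rows) + 1),
                          "ref": "A", "alt": "G", "vtype": "SNP"})
    return GenotypeMatrix(gt, sites, [f"S{j}" for j in range(gt.shape[1])])


class TestVariantRecord:
    def test_snp_allele_lengths_enforced(self):
        with pytest.raises(ValueError):
            VariantRecord("c", 1, "AT", "A", "SNP", np.array([1]))
        with pytest.raises(ValueError):
            VariantRecord("c", 1, "", "A", "SNP", np.array([1]))


class TestSiteFilters:
    def test_excess_missingness_removed(self):
        rows = [[1] * 8 + [-1, -1]]  # 0.20 missing > 0.15
        assert filter_variants(_gm_matrix(rows)).n_sites == 0

    def test_singleton_removed(self):
        rows = [[1] + [0] * 9]  # MAC = 1
        assert filter_variants(_gm_matrix(rows)).n_sites == 0

    def test_passing_site_retained(self):
        rows = [[1, 1] + [0] * 7 + [-1]]  # missing 0.1, MAC 2
        assert filter_variants(_gm_matrix(rows)).n_sites == 1

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(0)
        rows = rng.choice([-1, 0, 1], size=(50, 10), p=[0.1, 0.5, 0.4])
        m = _gm_matrix(rows.tolist())
        once = filter_variants(m)
        twice = filter_variants(once)
        assert np.array_equal(once.data, twice.data)
        perm = rng.permutation(50)
        m_perm = GenotypeMatrix(m.data[perm], m.sites.iloc[perm].reset_index(drop=True), m.accessions)
        filt_perm = filter_variants(m_perm)
        assert {tuple(r) for r in filt_perm.data.tolist()} == {tuple(r) for r in once.data.tolist()}


class TestDuplicateCollapse:
    def test_identical_fragment_coordinates_collapsed(self):
        from panforge.panbuild import AlignmentRecord

        def pair(pid, s1, s2):
            return [
                AlignmentRecord(f"{pid}/1", "c1", s1, "+", 0, True, 100),
                AlignmentRecord(f"{pid}/2", "c1", s2, "-", 0, True, 100),
            ]

        alns = pair("p1", 100, 300) + pair("p2", 100, 300) + pair("p3", 150, 350)
        kept = collapse_duplicates(alns)
        assert len(kept) == 4
        assert {a.read_id.split("/")[0] for a in kept} == {"p1", "p3"}


class TestAnnotation:
    def _setup(self):
        rng = np.random.default_rng(1)
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=30_000))
        # plus-strand gene with two exons; codon-clean CDS
        gene = GeneModel("g1", "c1", 2001, 2600, "+", ((2001, 2300), (2401, 2600)))
        asm = PanAssembly(contigs=[Contig("c1", seq, "reference")])
        return seq, gene, asm

    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["contig", "position", "ref", "alt", "vtype"])

    def test_region_precedence_and_flanks(self):
        seq, gene, asm = self._setup()
        sites = self._sites([
            ("c1", 2100, seq[2099], "A" if seq[2099] != "A" else "C", "SNP"),   # exon
            ("c1", 2350, seq[2349], "A" if seq[2349] != "A" else "C", "SNP"),   # intron
            ("c1", 1500, seq[1499], "A" if seq[1499] != "A" else "C", "SNP"),   # upstream (+)
            ("c1", 3000, seq[2999], "A" if seq[2999] != "A" else "C", "SNP"),   # downstream (+)
            ("c1", 20_000, seq[19_999], "A" if seq[19_999] != "A" else "C", "SNP"),  # >5 kb away
        ])
        ann = annotate_variants(sites, [gene], asm)
        assert ann.region.tolist() == ["exon", "intron", "upstream", "downstream", "intergenic"]
        assert (ann.region != "intergenic").sum() == 4

    def test_every_site_gets_exactly_one_region(self):
        seq, gene, asm = self._setup()
        rng = np.random.default_rng(2)
        pos = rng.integers(1, 30_000, size=200)
        sites = self._sites([("c1", int(p), seq[p - 1], "A" if seq[p - 1] != "A" else "C", "SNP")
                             for p in pos])
        ann = annotate_variants(sites, [gene], asm)
        assert set(ann.region) <= {"exon", "intron", "upstream", "downstream", "intergenic"}
        # brute-force interval oracle
        for row in ann.itertuples(index=False):
            p = row.position
            in_exon = any(s <= p <= e for s, e in gene.exons)
            in_gene = gene.start <= p <= gene.end
            if in_exon:
                assert row.region == "exon"
            elif in_gene:
                assert row.region == "intron"
            elif gene.start - 5000 <= p < gene.start:
                assert row.region == "upstream"
            elif gene.end < p <= gene.end + 5000:
                assert row.region == "downstream"
            else:
                assert row.region == "intergenic"

    def test_codon_table_examples(self):
        """AAA->AAG stays Lys (synonymous); AAA->GAA becomes Glu (missense)."""
        seq = "AAA" * 100
        gene = GeneModel("g", "c1", 1, 300, "+", ((1, 300),))
        assert classify_coding_snp(gene, seq, 3, "G") == "synonymous"
        assert classify_coding_snp(gene, seq, 1, "G") == "missense"

    def test_minus_strand_effect(self):
        # gene on '-': genomic TTT codon reads AAA; genomic T->C at the
        # codon's genomic 3rd base is CTT -> reverse-complement AAG (Lys, syn)
        seq = "TTT" * 100
        gene = GeneModel("g", "c1", 1, 300, "-", ((1, 300),))
        assert classify_coding_snp(gene, seq, 1, "C") == "synonymous"
        assert classify_coding_snp(gene, seq, 3, "C") == "missense"

    def test_effect_agrees_with_exhaustive_codon_enumeration(self):
        """All 576 one-step mutations of all 64 codons match the codon-table
        oracle (stop-gain = nonsense, same amino acid = synonymous)."""
        for codon in ALL_CODONS:
            gene = GeneModel("g", "c1", 1, 3, "+", ((1, 3),))
            for pos in range(3):
                for nb in BASES:
                    if nb == codon[pos]:
                        continue
                    mutated = codon[:pos] + nb + codon[pos + 1 :]
                    aa0, aa1 = translate_codon(codon), translate_codon(mutated)
                    expected = (
                        "synonymous" if aa0 == aa1
                        else "nonsense" if aa1 == "*"
                        else "missense"
                    )
                    assert classify_coding_snp(gene, codon, pos + 1, nb) == expected


class TestTsTv:
    def _sites(self, pairs):
        return pd.DataFrame([("c", i + 1, r, a, "SNP") for i, (r, a) in enumerate(pairs)],
                            columns=["contig", "position", "ref", "alt", "vtype"])

    def test_counted_by_definition(self):
        assert tstv_ratio(self._sites([("A", "G"), ("C", "T"), ("A", "C")])) == 2.0

    def test_zero_transversions_errors(self):
        with pytest.raises(ValueError, match="transversions"):
            tstv_ratio(self._sites([("A", "G"), ("G", "A")]))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            tstv_ratio(self._sites([]))


class TestDensity:
    def _sites(self, positions, contig="c1"):
        return pd.DataFrame([(contig, p, "A", "G", "SNP") for p in positions],
                            columns=["contig", "position", "ref", "alt", "vtype"])

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(3)
        pos = rng.integers(1, 200_000, size=500)
        d = variant_density(self._sites(pos), {"c1": 200_000})
        assert d["count"].sum() == 500

    def test_window_boundary_convention(self):
        """Position 80,000 falls in window 1; 80,001 opens window 2."""
        d = variant_density(self._sites([80_000, 80_001]), {"c1": 160_000})
        assert d["count"].tolist() == [1, 1]

    def test_empty_input_zero_track(self):
        d = variant_density(self._sites([]), {"c1": 160_000})
        assert (d["count"] == 0).all() and len(d) == 2


class TestKaKs:
    def brute_syn_fraction(self, codon, pos):
        aa = translate_codon(codon)
        syn = sum(
            translate_codon(codon[:pos] + b + codon[pos + 1 :]) == aa
            for b in BASES if b != codon[pos]
        )
        return syn / 3

    def test_site_weights_match_nine_neighbour_enumeration(self):
        for codon in ALL_CODONS:
            for pos in range(3):
                assert synonymous_fraction(codon, pos) == pytest.approx(
                    self.brute_syn_fraction(codon, pos)
                )

    def test_phe_to_leu_counts_nonsynonymous(self):
        """TTT->TTA (Phe->Leu) contributes Nd = 1."""
        gene = GeneModel("g", "c1", 1, 9, "+", ((1, 9),))
        seq = "TTTAAAGGG"
        res = kaks_ratio(gene, seq, [(3, "A")])
        assert res.ka > 0 and res.ks == 0 and not res.defined

    def test_only_synonymous_changes_purifying(self):
        gene = GeneModel("g", "c1", 1, 9, "+", ((1, 9),))
        seq = "TTTAAAGGG"  # TTT->TTC is synonymous (Phe)
        res = kaks_ratio(gene, seq, [(3, "C")])
        assert res.ka == 0 and res.ks > 0 and res.defined
        assert res.category == "purifying" and res.ratio == 0

    def test_no_variants_undefined_ratio(self):
        gene = GeneModel("g", "c1", 1, 9, "+", ((1, 9),))
        res = kaks_ratio(gene, "TTTAAAGGG", [])
        assert res.ka == 0 and res.ks == 0 and math.isnan(res.ratio) and not res.defined

    def test_cds_not_multiple_of_three_errors(self):
        gene = GeneModel("g", "c1", 1, 10, "+", ((1, 10),))
        with pytest.raises(ValueError):
            kaks_ratio(gene, "A" * 10, [])


def test_indel_size_spectrum():
    sites = pd.DataFrame(
        [("c", 1, "A", "ATT", "insertion"), ("c", 5, "ACGT", "A", "deletion"),
         ("c", 9, "A", "G", "SNP"), ("c", 12, "A", "AT", "insertion")],
        columns=["contig", "position", "ref", "alt", "vtype"])
    spec = indel_size_spectrum(sites)
    assert spec.to_dict() == {-3: 1, 1: 1, 2: 1}
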
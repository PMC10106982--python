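"""Variant filtering, ancestor subtraction and effect classification."""

import pytest
from hypothesis import given, strategies as st

from cinpipe.genome import Gene, GenomeModel, revcomp
from cinpipe.variants import (
    FilterParams,
    VariantRecord,
    annotate_variants,
    classify_effect,
    filter_variants,
    read_vcf,
    select_nonsynonymous,
    subtract_ancestor,
    write_vcf,
)
from oracles import classify_by_full_translation


def rec(pos=1, qual=100.0, depth=150, chrom="c1", ref="A", alt="G"):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, depth=depth)


class TestFilter:
    def test_quality_boundary_is_strict(self):
        kept = filter_variants([rec(qual=96.0), rec(pos=2, qual=95.0)])
        assert [r.qual for r in kept] == [96.0]

    @pytest.mark.parametrize(
        "mode,depth,expected",
        [
            ("max", 150, True),
            ("max", 300, True),
            ("max", 301, False),
            ("min", 301, True),
            ("min", 300, True),
            ("min", 299, False),
        ],
    )
    def test_depth_cutoff_direction(self, mode, depth, expected):
        params = FilterParams(depth_mode=mode)
        kept = filter_variants([rec(qual=99.0, depth=depth)], params)
        assert bool(kept) is expected

    def test_order_preserved(self):
        records = [rec(pos=p, qual=200.0) for p in (5, 1, 9)]
        assert filter_variants(records) == records

    @given(
        quals=st.lists(st.floats(0, 255), min_size=0, max_size=30),
        q1=st.floats(50, 150),
        q2=st.floats(50, 150),
    )
    def test_raising_min_quality_never_adds_records(self, quals, q1, q2):
        records = [rec(pos=i + 1, qual=q) for i, q in enumerate(quals)]
        lo, hi = sorted((q1, q2))
        loose = set(r.pos for r in filter_variants(records, FilterParams(min_qual=lo)))
        tight = set(r.pos for r in filter_variants(records, FilterParams(min_qual=hi)))
        assert tight <= loose


class TestSubtractAncestor:
    def test_set_difference_keeps_order(self):
        a, b, c = rec(pos=1), rec(pos=2), rec(pos=3)
        assert subtract_ancestor([a, b, c], [b]) == [a, c]

    def test_empty_ancestor_is_identity(self):
        evolved = [rec(pos=i) for i in (1, 2)]
        assert subtract_ancestor(evolved, []) == evolved

    def test_subset_of_ancestor_is_empty(self):
        evolved = [rec(pos=1), rec(pos=2)]
        assert subtract_ancestor(evolved, evolved + [rec(pos=9)]) == []

    def test_identity_is_chrom_pos_alt_not_qual(self):
        evolved = [rec(pos=1, qual=200.0, depth=10)]
        ancestor = [rec(pos=1, qual=50.0, depth=999)]
        assert subtract_ancestor(evolved, ancestor) == []

    @given(
        ev=st.sets(st.integers(1, 40), max_size=20),
        an=st.sets(st.integers(1, 40), max_size=20),
    )
    def test_subtraction_algebra(self, ev, an):
        evolved = [rec(pos=p) for p in sorted(ev)]
        ancestor = [rec(pos=p) for p in sorted(an)]
        out = subtract_ancestor(evolved, ancestor)
        assert set(r.pos for r in out) == ev - an
        assert all(r in evolved for r in out)


def toy_genome():
    """c1: +strand gene ATG AAA TAA at 11-19; c2: same CDS on the - strand."""
    pad5, pad3 = "CCCCCCCCCC", "GGGGGGGGGG"
    cds = "ATGAAATAA"
    plus = pad5 + cds + pad3
    minus = pad5 + revcomp(cds) + pad3
    return GenomeModel(
        chromosomes={"c1": plus, "c2": minus},
        genes=[Gene("gp", "c1", 11, 19, "+"), Gene("gm", "c2", 11, 19, "-")],
    )


class TestClassifyEffect:
    def test_intergenic_is_noncoding(self):
        g = toy_genome()
        v = VariantRecord("c1", 2, "C", "T", 100.0, 100)
        ann = classify_effect(v, g)
        assert ann.effect == "noncoding" and ann.gene_id is None

    @pytest.mark.parametrize(
        "pos,ref,alt,effect,aa",
        [
            (14, "A", "G", "missense", "K2E"),  # AAA->GAA, Lys->Glu
            (14, "A", "T", "nonsense", "K2X"),  # AAA->TAA stop gained
            (16, "A", "G", "silent", "K2K"),  # AAA->AAG
        ],
    )
    def test_plus_strand_codon2_cases(self, pos, ref, alt, effect, aa):
        g = toy_genome()
        ann = classify_effect(VariantRecord("c1", pos, ref, alt, 100.0, 100), g)
        assert (ann.effect, ann.aa_change, ann.gene_id) == (effect, aa, "gp")
        assert ann.codon_index == 1

    def test_minus_strand_mirrors_plus_strand(self):
        # corresponding substitutions on the reverse-complement gene
        g = toy_genome()
        # c2 pos 11..19 holds revcomp("ATGAAATAA") = "TTATTTCAT"; CDS offset 3
        # (first base of codon 2) maps to genomic pos 19-3 = 16, base T
        ann = classify_effect(VariantRecord("c2", 16, "T", "C", 100.0, 100), g)
        assert ann.effect == "missense" and ann.aa_change == "K2E"
        ann = classify_effect(VariantRecord("c2", 16, "T", "A", 100.0, 100), g)
        assert ann.effect == "nonsense"

    def test_ref_mismatch_raises(self):
        g = toy_genome()
        with pytest.raises(ValueError, match="ref mismatch"):
            classify_effect(VariantRecord("c1", 11, "C", "T", 100.0, 100), g)

    def test_stop_loss_is_missense(self):
        g = toy_genome()
        # TAA -> CAA at codon 3 (pos 17 on +) removes the stop
        ann = classify_effect(VariantRecord("c1", 17, "T", "C", 100.0, 100), g)
        assert ann.effect == "missense"

    def test_agrees_with_full_translation_oracle_spot_checks(self, small_genome):
        import numpy as np

        rng = np.random.default_rng(0)
        chrom = small_genome.chrom_names[0]
        L = small_genome.chrom_length(chrom)
        for pos in rng.integers(1, L + 1, size=300):
            pos = int(pos)
            ref = small_genome.base_at(chrom, pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                v = VariantRecord(chrom, pos, ref, alt, 100.0, 100)
                assert (
                    classify_effect(v, small_genome).effect
                    == classify_by_full_translation(small_genome, chrom, pos, alt)
                )

    def test_strand_symmetry_exhaustive_on_toy_gene(self):
        # every substitution in the +strand gene classifies identically to
        # its mirrored substitution in the -strand copy
        g = toy_genome()
        for offset in range(9):
            pos_p = 11 + offset
            pos_m = 19 - offset  # mirrored genomic position on c2
            ref_p = g.base_at("c1", pos_p)
            ref_m = g.base_at("c2", pos_m)
            assert ref_m == revcomp(ref_p)
            for alt in "ACGT":
                if alt == ref_p:
                    continue
                e1 = classify_effect(VariantRecord("c1", pos_p, ref_p, alt, 99.0, 1), g).effect
                e2 = classify_effect(
                    VariantRecord("c2", pos_m, ref_m, revcomp(alt), 99.0, 1), g
                ).effect
                assert e1 == e2


class TestSelectNonsynonymous:
    def test_keeps_missense_and_nonsense(self):
        g = toy_genome()
        records = [
            VariantRecord("c1", 2, "C", "T", 99.0, 9),  # noncoding
            VariantRecord("c1", 16, "A", "G", 99.0, 9),  # silent
            VariantRecord("c1", 14, "A", "G", 99.0, 9),  # missense
            VariantRecord("c1", 14, "A", "T", 99.0, 9),  # nonsense
        ]
        annotated = annotate_variants(records, g)
        kept = select_nonsynonymous(annotated)
        assert [a.effect for a in kept] == ["missense", "nonsense"]
        assert select_nonsynonymous(kept) == kept  # idempotent

    def test_all_silent_gives_empty(self):
        g = toy_genome()
        annotated = annotate_variants([VariantRecord("c1", 16, "A", "G", 99.0, 9)], g)
        assert select_nonsynonymous(annotated) == []


class TestVcfIO:
    def test_round_trip(self, tmp_path):
        records = [
            VariantRecord("c1", 5, "A", "G", 120.5, 250),
            VariantRecord("c2", 9, "T", "C", 80.0, 310),
        ]
        path = tmp_path / "x.vcf"
        write_vcf(records, path)
        assert read_vcf(path) == records

    def test_snv_only_parsing_skips_indels(self, tmp_path):
        path = tmp_path / "mixed.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "c1\t5\t.\tA\tG\t100\t.\tDP=200\n"
            "c1\t8\t.\tAT\tA\t100\t.\tDP=200\n"  # deletion: skipped
            "c1\t12\t.\tC\tCTT\t100\t.\tDP=200\n"  # insertion: skipped
        )
        records = read_vcf(path)
        assert [r.pos for r in records] == [5]

    def test_missing_depth_fails_closed_by_default(self, tmp_path):
        path = tmp_path / "nodp.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "c1\t5\t.\tA\tG\t100\t.\t.\n"
        )
        assert read_vcf(path) == []
        assert [r.depth for r in read_vcf(path, missing_depth="pass")] == [0]
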
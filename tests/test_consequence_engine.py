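"""Genetic-code arithmetic, term classification and the internal annotator."""

import pytest
from Bio.Seq import Seq

from mybpc_landscape.consequence_engine import (
    AnnotationRangeError,
    CodonChange,
    ConsequenceCategory,
    GENETIC_CODE,
    annotate_variant,
    classify_terms,
    codon_position_of_change,
    enumerate_single_substitutions,
    stop_accessibility,
    translate_codon,
    vep_codon_markup,
)
from mybpc_landscape.variant_io import VariantRecord

from conftest import (
    geometric_noncoding_oracle,
    random_models,
    random_snvs,
    retranslate_oracle,
)


class TestGeneticCode:
    def test_matches_biopython_for_all_codons(self):
        for codon in GENETIC_CODE:
            expected = str(Seq(codon).translate())
            assert translate_codon(codon) == expected

    @pytest.mark.parametrize("codon,aa", [("ATG", "M"), ("TGG", "W"), ("TAA", "*")])
    def test_known_codons(self, codon, aa):
        assert translate_codon(codon) == aa

    @pytest.mark.parametrize("bad", ["ATN", "AT", "AUGG", "XYZ"])
    def test_invalid_codon_raises(self, bad):
        with pytest.raises(ValueError):
            translate_codon(bad)


class TestClassifyTerms:
    @pytest.mark.parametrize(
        "terms,expected",
        [
            (["stop_gained"], ConsequenceCategory.TRUNCATION),
            (["missense_variant", "splice_region_variant"], ConsequenceCategory.MISSENSE),
            (["intron_variant"], ConsequenceCategory.NONCODING),
            (["synonymous_variant"], ConsequenceCategory.SYNONYMOUS),
            (["inframe_deletion"], ConsequenceCategory.INFRAME_INDEL),
            (["inframe_insertion"], ConsequenceCategory.INFRAME_INDEL),
            (["splice_donor_variant", "intron_variant"], ConsequenceCategory.SPLICE),
            (["splice_acceptor_variant"], ConsequenceCategory.SPLICE),
            (["start_lost"], ConsequenceCategory.START_LOSS),
            (["stop_lost"], ConsequenceCategory.STOP_LOSS),
            (["frameshift_variant"], ConsequenceCategory.FRAMESHIFT),
            (["5_prime_UTR_variant"], ConsequenceCategory.NONCODING),
            (["upstream_gene_variant"], ConsequenceCategory.NONCODING),
            # splice_region alone is positional, not a donor/acceptor hit
            (["splice_region_variant", "intron_variant"], ConsequenceCategory.NONCODING),
            # ... and must not mask a coding synonymous call
            (["splice_region_variant", "synonymous_variant"], ConsequenceCategory.SYNONYMOUS),
            (["stop_gained", "splice_region_variant"], ConsequenceCategory.TRUNCATION),
        ],
    )
    def test_priority_mapping(self, terms, expected):
        assert classify_terms(terms) is expected

    def test_unknown_terms_fall_back(self, caplog):
        assert classify_terms(["weird_new_term"]) is ConsequenceCategory.PROTEIN_ALTERING_OTHER

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            classify_terms([])


class TestCodonChange:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("gGg", "gAg", {2}), ("GAA", "AAA", {1}), ("TAT", "TAA", {3})],
    )
    def test_changed_positions(self, ref, alt, expected):
        change = CodonChange.from_vep_markup(ref, alt)
        assert codon_position_of_change(change) == frozenset(expected)

    def test_markup_inconsistent_with_bases_raises(self):
        with pytest.raises(ValueError):
            CodonChange.from_vep_markup("Ggg", "gAg")  # uppercase at 1, diff at 2

    def test_identical_codons_raise(self):
        with pytest.raises(ValueError):
            CodonChange.from_codons("AAA", "AAA")

    def test_markup_round_trip(self):
        assert vep_codon_markup("GGG", "GAG") == ("gGg", "gAg")


class TestStopAccessibility:
    """Brute-force nulls for the Trp/Tyr premature-stop dominance."""

    def test_known_counts(self):
        acc = stop_accessibility()
        assert acc["W"] == (2, 9)   # TGG -> TAG, TGA
        assert acc["Y"] == (4, 18)  # TAT/TAC -> TAA/TAG each
        assert acc["M"] == (0, 9)   # ATG cannot reach a stop in one step

    def test_total_substitutions_conserved(self):
        acc = stop_accessibility()
        # 61 sense codons x 9 single-base substitutions
        assert sum(total for _n, total in acc.values()) == 61 * 9

    def test_full_enumeration_partitions_576(self):
        subs = list(enumerate_single_substitutions())
        assert len(subs) == 64 * 9
        syn = sum(1 for *_x, r, a in subs if r == a)
        nonsense = sum(1 for *_x, r, a in subs if r != "*" and a == "*")
        stop_loss = sum(1 for *_x, r, a in subs if r == "*" and a != "*")
        missense = sum(1 for *_x, r, a in subs if "*" not in (r, a) and r != a)
        assert syn + nonsense + stop_loss + missense == 576

    def test_trp_tyr_have_maximal_per_codon_nonsense_rate(self):
        acc = stop_accessibility()
        rates = {aa: n / total for aa, (n, total) in acc.items()}
        top = max(rates.values())
        assert rates["W"] == rates["Y"] == top == pytest.approx(2 / 9)
        others = {aa: r for aa, r in rates.items() if aa not in "WY"}
        assert max(others.values()) < 2 / 9

    def test_synonymous_changes_concentrate_at_third_position(self):
        by_pos = {1: 0, 2: 0, 3: 0}
        for _codon, _alt, pos, ref_aa, alt_aa in enumerate_single_substitutions():
            if ref_aa == alt_aa:
                by_pos[pos] += 1
        assert by_pos[3] > by_pos[1] + by_pos[2]


class TestAnnotateToyModel:
    """Hand-derived expectations on the 4-codon toy gene ATG GAA TGG TAA."""

    def test_missense_codon2(self, toy_model):
        # GAA -> AAA at the first base of codon 2 (genomic position 8)
        ann = annotate_variant(toy_model, VariantRecord("chrT", 8, "G", "A"))
        assert ann.consequence_terms == ["missense_variant"]
        assert ann.aa_change == ("E", "K")
        assert ann.protein_pos == 2
        change = CodonChange.from_vep_markup(*ann.codon_change)
        assert change.changed_positions == frozenset({1})

    def test_stop_gained_codon3(self, toy_model):
        # TGG -> TGA at the third base of codon 3 (genomic position 13)
        ann = annotate_variant(toy_model, VariantRecord("chrT", 13, "G", "A"))
        assert ann.consequence_terms == ["stop_gained"]
        assert ann.aa_change == ("W", "*")
        assert ann.protein_pos == 3

    def test_synonymous_codon2(self, toy_model):
        # GAA -> GAG, still Glu
        ann = annotate_variant(toy_model, VariantRecord("chrT", 10, "A", "G"))
        assert ann.consequence_terms == ["synonymous_variant"]
        assert ann.aa_change == ("E", "E")

    def test_start_lost(self, toy_model):
        ann = annotate_variant(toy_model, VariantRecord("chrT", 5, "A", "G"))
        assert ann.consequence_terms == ["start_lost"]

    def test_stop_lost(self, toy_model):
        # TAA -> CAA (Q)
        ann = annotate_variant(toy_model, VariantRecord("chrT", 14, "T", "C"))
        assert ann.consequence_terms == ["stop_lost"]

    def test_utr_terms(self, toy_model):
        five = annotate_variant(toy_model, VariantRecord("chrT", 2, "A", "G"))
        three = annotate_variant(toy_model, VariantRecord("chrT", 18, "T", "C"))
        assert five.consequence_terms == ["5_prime_UTR_variant"]
        assert three.consequence_terms == ["3_prime_UTR_variant"]

    def test_frameshift_and_inframe_deletions(self, toy_model):
        fs = annotate_variant(toy_model, VariantRecord("chrT", 7, "GGA", "G"))
        assert fs.consequence_terms == ["frameshift_variant"]
        assert fs.protein_pos == 2  # first deleted base sits in codon 2 (ref aa E)
        assert fs.aa_change == ("E", "X")
        inframe = annotate_variant(toy_model, VariantRecord("chrT", 7, "GGAA", "G"))
        assert inframe.consequence_terms == ["inframe_deletion"]

    def test_insertion_frameshift(self, toy_model):
        ins = annotate_variant(toy_model, VariantRecord("chrT", 8, "G", "GT"))
        assert ins.consequence_terms == ["frameshift_variant"]
        ins3 = annotate_variant(toy_model, VariantRecord("chrT", 8, "G", "GTTT"))
        assert ins3.consequence_terms == ["inframe_insertion"]

    def test_out_of_range_raises(self, toy_model):
        with pytest.raises(AnnotationRangeError):
            annotate_variant(toy_model, VariantRecord("chrT", 99, "A", "G"))

    def test_ref_mismatch_raises(self, toy_model):
        with pytest.raises(ValueError, match="REF mismatch"):
            annotate_variant(toy_model, VariantRecord("chrT", 5, "C", "G"))

    def test_minus_strand_gives_same_protein_results(self, toy_model, toy_model_minus):
        # mirror of position 8 (G->A missense) on the reverse-complement locus
        L = len(toy_model.sequence)
        pos_minus = L - 8 + 1
        ann = annotate_variant(toy_model_minus, VariantRecord("chrT", pos_minus, "C", "T"))
        assert ann.consequence_terms == ["missense_variant"]
        assert ann.aa_change == ("E", "K")
        assert ann.protein_pos == 2


class TestSpliceSites:
    def test_donor_acceptor_positions_both_strands(self):
        for model in random_models(4, seed=99):
            for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
                for pos in (e1 + 1, e1 + 2, s2 - 2, s2 - 1):
                    ref = model.base(pos)
                    alt = "A" if ref != "A" else "G"
                    ann = annotate_variant(model, VariantRecord(model.chrom, pos, ref, alt))
                    assert ann.consequence_terms[0] == geometric_noncoding_oracle(model, pos)


class TestOracleEquivalence:
    """The annotator must agree with the whole-protein retranslation oracle."""

    def test_random_snvs_across_random_models(self):
        n_checked = 0
        for model in random_models(6, seed=7):
            for v in random_snvs(model, 60, seed=model.exons[0][0]):
                ann = annotate_variant(model, v)
                oracle = retranslate_oracle(model, v)
                if oracle is None:
                    expected = geometric_noncoding_oracle(model, v.pos)
                    assert ann.consequence_terms[0] == expected, (model.strand, v)
                else:
                    category, protein_pos, aa_change = oracle
                    got = classify_terms(ann.consequence_terms).value
                    assert got == category, (model.strand, v, ann)
                    assert ann.protein_pos == protein_pos
                    assert ann.aa_change == aa_change
                n_checked += 1
        assert n_checked >= 300

    def test_strand_mirror_invariance(self):
        import numpy as np

        from mybpc_landscape.synthetic_data import make_gene_model

        rng = np.random.default_rng(5)
        for seed in (11, 23, 31):
            plus = make_gene_model(4, 60, "+", seed=seed, flank=100, intron_min=30, intron_max=80)
            minus = make_gene_model(4, 60, "-", seed=seed, flank=100, intron_min=30, intron_max=80)
            assert plus.cds_sequence == minus.cds_sequence
            L = len(plus.sequence)
            off = plus.seq_offset
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            coding = [p for p in range(*plus.span) if plus.is_coding(p)]
            for pos in rng.choice(coding, size=40, replace=False):
                pos = int(pos)
                ref = plus.base(pos)
                alt = "ACGT"[int(rng.integers(0, 4))]
                while alt == ref:
                    alt = "ACGT"[int(rng.integers(0, 4))]
                a_plus = annotate_variant(plus, VariantRecord(plus.chrom, pos, ref, alt))
                mpos = off + (L - 1) - (pos - off)
                a_minus = annotate_variant(
                    minus, VariantRecord(minus.chrom, mpos, comp[ref], comp[alt])
                )
                assert a_plus.consequence_terms == a_minus.consequence_terms
                assert a_plus.protein_pos == a_minus.protein_pos
                assert a_plus.aa_change == a_minus.aa_change
                assert a_plus.codon_change == a_minus.codon_change
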
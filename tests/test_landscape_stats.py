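"""Category tallies, spectra, domain/exon mapping and pathogenicity rules."""

import dataclasses

import pytest

from mybpc_landscape.landscape_stats import (
    DomainArchitecture,
    PathogenicityRule,
    Region,
    domain_distribution,
    exon_distribution,
    filter_likely_pathogenic,
    frameshift_aa_tally,
    is_likely_pathogenic,
    map_to_domain,
    pathogenic_distribution,
    stop_gain_sources,
    substitution_spectrum,
    tally_categories,
    tally_nucleotide_changes,
)
from mybpc_landscape.variant_io import TranscriptAnnotation, VariantRecord


def ann(terms=("missense_variant",), **kw):
    return TranscriptAnnotation(
        transcript_id="ENST1", gene_symbol="G", consequence_terms=list(terms), **kw
    )


def rec(pos, ref="G", alt="A", annotations=None):
    return VariantRecord("1", pos, ref, alt, annotations=annotations or [ann()])


@pytest.fixture
def two_domain_arch():
    return DomainArchitecture(
        "toy", 250, [Region("C1", "Ig", 1, 100), Region("C2", "Ig", 101, 200)]
    )


class TestTallyCategories:
    def test_proportions_over_coding(self):
        records = (
            [rec(i, annotations=[ann(("missense_variant",))]) for i in range(1, 64)]
            + [rec(i, annotations=[ann(("synonymous_variant",))]) for i in range(100, 130)]
            + [rec(i, annotations=[ann(("stop_gained",))]) for i in range(200, 207)]
        )
        tally = tally_categories(records)
        assert tally.counts["missense"] == 63
        assert tally.coding_proportions["missense"] == pytest.approx(0.63)
        assert sum(tally.coding_proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_noncoding_reported_separately(self):
        records = [
            rec(1, annotations=[ann(("intron_variant",))]),
            rec(2, annotations=[ann(("missense_variant",))]),
        ]
        tally = tally_categories(records)
        assert tally.n_noncoding == 1
        assert tally.noncoding_fraction == pytest.approx(0.5)

    def test_empty_input(self):
        tally = tally_categories([])
        assert tally.counts == {}
        assert tally.coding_proportions == {}
        assert tally.noncoding_fraction is None


class TestNucleotideChanges:
    def test_single_snv(self):
        assert tally_nucleotide_changes([rec(1, "G", "A")]) == {"G>A": 1}

    def test_indels_do_not_contribute(self):
        assert tally_nucleotide_changes([rec(1, "GA", "G")]) == {}

    def test_per_category_nesting(self):
        records = [
            rec(1, "G", "A", annotations=[ann(("missense_variant",))]),
            rec(2, "C", "T", annotations=[ann(("synonymous_variant",))]),
        ]
        nested = tally_nucleotide_changes(records, per_category=True)
        assert nested == {"missense": {"G>A": 1}, "synonymous": {"C>T": 1}}


class TestSubstitutionSpectrum:
    def test_top_k_and_tie_break(self):
        records = [
            rec(1, annotations=[ann(protein_pos=1, aa_change=("E", "K"))]),
            rec(2, annotations=[ann(protein_pos=2, aa_change=("E", "K"))]),
            rec(3, annotations=[ann(protein_pos=3, aa_change=("A", "T"))]),
            rec(4, annotations=[ann(protein_pos=4, aa_change=("A", "S"))]),
        ]
        spectrum = substitution_spectrum(records)
        assert spectrum.top_k(1) == [(("E", "K"), 2)]
        # ties resolve lexicographically on (ref, alt)
        assert spectrum.top_k(3)[1] == (("A", "S"), 1)
        assert spectrum.total == 4

    def test_marginals_sum_to_total(self):
        records = [
            rec(1, annotations=[ann(protein_pos=1, aa_change=("R", "C"))]),
            rec(2, annotations=[ann(protein_pos=2, aa_change=("R", "H"))]),
            rec(3, annotations=[ann(protein_pos=3, aa_change=("E", "K"))]),
        ]
        spectrum = substitution_spectrum(records)
        assert spectrum.marginal_ref()["R"] == 2
        assert sum(spectrum.marginal_ref().values()) == spectrum.total
        assert sum(spectrum.marginal_alt().values()) == spectrum.total

    def test_category_filter_excludes_other_classes(self):
        records = [
            rec(1, annotations=[ann(("stop_gained",), protein_pos=1, aa_change=("W", "*"))]),
            rec(2, annotations=[ann(protein_pos=2, aa_change=("E", "K"))]),
        ]
        assert substitution_spectrum(records, ("missense",)).total == 1
        assert substitution_spectrum(records, ("truncation",)).total == 1


class TestPerAaTallies:
    def test_frameshift_first_codon_residue(self):
        records = [
            rec(1, "GA", "G", annotations=[ann(("frameshift_variant",), protein_pos=5, aa_change=("T", "X"))]),
        ]
        assert frameshift_aa_tally(records) == {"T": 1}

    def test_frameshift_without_position_counts_unknown(self):
        records = [rec(1, "GA", "G", annotations=[ann(("frameshift_variant",))])]
        assert frameshift_aa_tally(records) == {"unknown": 1}

    def test_stop_gain_sources(self):
        records = [
            rec(1, annotations=[ann(("stop_gained",), protein_pos=3, aa_change=("W", "*"))]),
            rec(2, annotations=[ann(("stop_gained",), protein_pos=9, aa_change=("Y", "*"))]),
            rec(3, annotations=[ann(("stop_gained",), protein_pos=4, aa_change=("W", "*"))]),
        ]
        assert stop_gain_sources(records) == {"W": 2, "Y": 1}

    def test_no_truncations_empty(self):
        assert stop_gain_sources([rec(1)]) == {}


class TestDomainMapping:
    def test_inclusive_boundaries(self, two_domain_arch):
        assert map_to_domain(100, two_domain_arch) == "C1"
        assert map_to_domain(101, two_domain_arch) == "C2"
        assert map_to_domain(1, two_domain_arch) == "C1"

    def test_gap_is_linker(self, two_domain_arch):
        assert map_to_domain(201, two_domain_arch) == "linker"

    def test_out_of_range_raises(self, two_domain_arch):
        with pytest.raises(ValueError):
            map_to_domain(251, two_domain_arch)
        with pytest.raises(ValueError):
            map_to_domain(0, two_domain_arch)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            DomainArchitecture(
                "bad", 100, [Region("C1", "Ig", 1, 50), Region("C2", "Ig", 50, 90)]
            )

    def test_tsv_round_trip(self, two_domain_arch, tmp_path):
        path = tmp_path / "arch.tsv"
        two_domain_arch.to_tsv(path)
        back = DomainArchitecture.from_tsv(path)
        assert back.protein_name == "toy"
        assert back.length_aa == 250
        assert back.regions == two_domain_arch.regions


class TestDistributions:
    def test_domain_counts_partition(self, two_domain_arch):
        records = [
            rec(1, annotations=[ann(protein_pos=10, aa_change=("A", "T"))]),
            rec(2, annotations=[ann(protein_pos=150, aa_change=("A", "T"))]),
            rec(3, annotations=[ann(protein_pos=150, aa_change=("A", "S"))]),
            rec(4, annotations=[ann(protein_pos=240, aa_change=("A", "S"))]),
        ]
        counts = domain_distribution(records, two_domain_arch)
        assert counts == {"C1": 1, "C2": 2, "linker": 1}
        assert sum(counts.values()) == 4

    def test_normalized_rates(self, two_domain_arch):
        records = [rec(1, annotations=[ann(protein_pos=10, aa_change=("A", "T"))])]
        out = domain_distribution(records, two_domain_arch, normalize=True)
        count, rate = out["C1"]
        assert count == 1
        assert rate == pytest.approx(1.0)  # 1 variant per 100 aa in a 100-aa domain

    def test_exon_distribution_uses_annotation_then_model(self, toy_model):
        records = [
            rec(1, annotations=[ann(exon_index=2)]),
            VariantRecord("chrT", 8, "G", "A", annotations=[ann()]),  # model says exon 1
            rec(999, annotations=[ann(("intron_variant",))]),  # outside every exon
        ]
        counts, n_excluded = exon_distribution(records, toy_model)
        assert counts == {2: 1, 1: 1}
        assert n_excluded == 1


class TestPathogenicityRule:
    d = ("deleterious", 0.01)
    t = ("tolerated", 0.6)
    pd_ = ("probably_damaging", 0.97)
    b = ("benign", 0.1)

    @pytest.mark.parametrize(
        "sift,polyphen,mode,expected",
        [
            (d, pd_, "both", True),
            (t, b, "both", False),
            (t, b, "either", False),
            (t, b, "sift_only", False),
            (d, None, "both", False),
            (d, None, "either", True),
            (d, None, "sift_only", True),
            (None, pd_, "polyphen_only", True),
            (None, None, "either", False),
            (None, None, "sift_only", False),
            (d, b, "both", False),
            (d, b, "either", True),
        ],
    )
    def test_rule_semantics(self, sift, polyphen, mode, expected):
        a = ann(sift=sift, polyphen=polyphen)
        assert is_likely_pathogenic(a, PathogenicityRule(mode=mode)) is expected

    def test_both_subset_of_either(self):
        import numpy as np

        rng = np.random.default_rng(0)
        records = []
        for i in range(200):
            sift = self.d if rng.random() < 0.5 else self.t
            polyphen = self.pd_ if rng.random() < 0.5 else self.b
            if rng.random() < 0.2:
                sift = None
            if rng.random() < 0.2:
                polyphen = None
            records.append(rec(i + 1, annotations=[ann(sift=sift, polyphen=polyphen)]))
        both = {r.key for r in filter_likely_pathogenic(records, PathogenicityRule(mode="both"))}
        either = {r.key for r in filter_likely_pathogenic(records, PathogenicityRule(mode="either"))}
        assert both <= either

    def test_strengthening_labels_shrinks_set(self):
        records = [
            rec(1, annotations=[ann(sift=("deleterious_low_confidence", 0.04))]),
            rec(2, annotations=[ann(sift=self.d)]),
        ]
        loose = PathogenicityRule(
            mode="sift_only",
            sift_damaging_labels=frozenset({"deleterious", "deleterious_low_confidence"}),
        )
        strict = PathogenicityRule(mode="sift_only")
        assert len(filter_likely_pathogenic(records, loose)) == 2
        assert len(filter_likely_pathogenic(records, strict)) == 1

    def test_filter_idempotent(self):
        records = [
            rec(1, annotations=[ann(sift=self.d, polyphen=self.pd_)]),
            rec(2, annotations=[ann(sift=self.t, polyphen=self.b)]),
        ]
        rule = PathogenicityRule(mode="both")
        once = filter_likely_pathogenic(records, rule)
        twice = filter_likely_pathogenic(once, rule)
        assert [r.key for r in once] == [r.key for r in twice]

    def test_pathogenic_distribution_counts_damaging_only(self, two_domain_arch):
        damaging = [
            rec(i, annotations=[ann(sift=self.d, polyphen=self.pd_, protein_pos=10,
                                    aa_change=("A", "T"), exon_index=1)])
            for i in range(1, 6)
        ]
        benign = [
            rec(i, annotations=[ann(sift=self.t, polyphen=self.b, protein_pos=150,
                                    aa_change=("A", "T"), exon_index=2)])
            for i in range(10, 15)
        ]
        exon_counts, region_counts = pathogenic_distribution(
            damaging + benign, PathogenicityRule(mode="both"), two_domain_arch
        )
        assert exon_counts == {1: 5}
        assert region_counts == {"C1": 5}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            PathogenicityRule(mode="sometimes")

    def test_mode_replace_keeps_labels(self):
        rule = PathogenicityRule(mode="both")
        either = dataclasses.replace(rule, mode="either")
        assert either.sift_damaging_labels == rule.sift_damaging_labels
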
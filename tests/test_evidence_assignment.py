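"""Annotation-to-evidence-code assignment tests."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bradyvar.acmg import Tier
from bradyvar.assignment import (AnnotationBundle, GeneRuleConfig, Thresholds,
                                 VocabularyError, assign_codes,
                                 classify_variant,
                                 consequence_for_splice_hgvs)


def codes_of(bundle, config=None, thresholds=None):
    return set(assign_codes(bundle, config, thresholds).codes)


class TestFrequencyRules:
    def test_rare_missense_gets_pm2_only(self):
        bundle = AnnotationBundle(allele_frequency=0.0005, consequence="missense")
        assert codes_of(bundle) == {"PM2"}

    def test_common_variant_gets_ba1_not_pm2(self):
        bundle = AnnotationBundle(allele_frequency=0.02)
        assert codes_of(bundle) == {"BA1"}

    def test_absent_frequency_counts_as_absent_from_databases(self):
        assert "PM2" in codes_of(AnnotationBundle())

    @pytest.mark.parametrize("af, pm2, ba1", [
        (0.000999, True, False),   # strictly below the rarity cut-off
        (0.001, False, False),     # exactly at it: "under 0.001" excludes it
        (0.005, False, False),     # exactly 0.5%: ">0.5%" excludes it
        (0.0051, False, True),     # strictly above
    ])
    def test_threshold_boundaries_are_strict(self, af, pm2, ba1):
        codes = codes_of(AnnotationBundle(allele_frequency=af))
        assert ("PM2" in codes) is pm2
        assert ("BA1" in codes) is ba1

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="pm2_max_af"):
            Thresholds(pm2_max_af=0.01, ba1_min_af=0.005)

    def test_custom_thresholds_respected(self):
        th = Thresholds(pm2_max_af=0.0001, ba1_min_af=0.05)
        assert "PM2" not in codes_of(
            AnnotationBundle(allele_frequency=0.0005), thresholds=th)
        assert "BA1" not in codes_of(
            AnnotationBundle(allele_frequency=0.02), thresholds=th)


class TestConsequenceRules:
    def test_null_variant_needs_lof_mechanism(self):
        bundle = AnnotationBundle(consequence="frameshift")
        assert "PVS1" not in codes_of(bundle)
        lof = GeneRuleConfig(gene="SCN5A", lof_mechanism=True)
        assert "PVS1" in codes_of(bundle, lof)

    @pytest.mark.parametrize("consequence", [
        "nonsense", "frameshift", "canonical_splice", "large_deletion"])
    def test_all_null_classes_trigger_pvs1(self, consequence):
        lof = GeneRuleConfig(gene="G", lof_mechanism=True)
        assert "PVS1" in codes_of(
            AnnotationBundle(consequence=consequence), lof)

    @pytest.mark.parametrize("consequence", ["inframe_indel", "stoploss"])
    def test_protein_length_changes_trigger_pm4(self, consequence):
        assert "PM4" in codes_of(AnnotationBundle(consequence=consequence))

    def test_pp2_requires_missense_constrained_gene(self):
        bundle = AnnotationBundle(consequence="missense")
        assert "PP2" not in codes_of(bundle)
        cfg = GeneRuleConfig(gene="G", missense_constrained=True)
        assert "PP2" in codes_of(bundle, cfg)

    def test_unknown_consequence_label_rejected(self):
        with pytest.raises(VocabularyError):
            AnnotationBundle(consequence="gained_stop")

    @pytest.mark.parametrize("hgvs, expected", [
        ("c.1737+1G>T", "canonical_splice"),
        ("c.357-2A>G", "canonical_splice"),
        ("c.3963+2T>C", "canonical_splice"),
        ("IVS9-3C>G", "other_splice_region"),
        ("c.-225-820T>C", "other_splice_region"),
    ])
    def test_splice_hgvs_maps_by_intronic_offset(self, hgvs, expected):
        assert consequence_for_splice_hgvs(hgvs) == expected


class TestObservationRules:
    def test_confirmed_de_novo_is_strong_unconfirmed_moderate(self):
        assert "PS2" in codes_of(AnnotationBundle(de_novo="confirmed"))
        assert "PM6" in codes_of(AnnotationBundle(de_novo="unconfirmed"))

    def test_functional_study_direction(self):
        assert "PS3" in codes_of(
            AnnotationBundle(functional_study="supports_pathogenic"))
        assert "BS3" in codes_of(
            AnnotationBundle(functional_study="supports_benign"))

    def test_segregation_direction(self):
        assert "PP1" in codes_of(AnnotationBundle(segregates_in_family="yes"))
        assert "BS4" in codes_of(AnnotationBundle(segregates_in_family="no"))

    def test_in_silico_direction(self):
        assert "PP3" in codes_of(AnnotationBundle(in_silico_verdict="deleterious"))
        assert "BP4" in codes_of(AnnotationBundle(in_silico_verdict="benign_pred"))

    def test_hotspot_and_healthy_recessive_flags(self):
        assert "PM1" in codes_of(AnnotationBundle(hotspot_or_domain=True))
        assert "BS2" in codes_of(
            AnnotationBundle(observed_healthy_recessive=True))

    def test_manual_codes_pass_through_without_double_count(self):
        bundle = AnnotationBundle(
            allele_frequency=None, manual_codes=frozenset({"PS1", "PP5", "PM2"}))
        profile = assign_codes(bundle)
        assert {"PS1", "PP5", "PM2"} <= set(profile.codes)
        assert profile.counts.PM == 1  # PM2 asserted manually and by rule


class TestComposition:
    def test_null_variant_with_functional_support_is_pathogenic(self):
        bundle = AnnotationBundle(
            consequence="frameshift",
            functional_study="supports_pathogenic")
        cfg = GeneRuleConfig(gene="G", lof_mechanism=True)
        result = classify_variant(bundle, cfg)
        assert result.tier is Tier.PATHOGENIC  # PVS1 + PS3 (+ PM2)

    def test_common_synonymous_is_benign(self):
        bundle = AnnotationBundle(allele_frequency=0.3, consequence="synonymous")
        assert classify_variant(bundle).tier is Tier.BENIGN

    def test_rare_missense_without_other_evidence_is_vus(self):
        bundle = AnnotationBundle(allele_frequency=0.0001, consequence="missense")
        assert classify_variant(bundle).tier is Tier.UNCERTAIN

    def test_confirmed_de_novo_null_profile_superset(self):
        bundle = AnnotationBundle(consequence="frameshift", de_novo="confirmed")
        cfg = GeneRuleConfig(gene="G", lof_mechanism=True)
        assert {"PVS1", "PS2", "PM2"} <= codes_of(bundle, cfg)

    def test_common_af_with_unknowns_yields_ba1_alone(self):
        bundle = AnnotationBundle(allele_frequency=0.5)
        assert codes_of(bundle) == {"BA1"}


@st.composite
def bundles(draw):
    af = draw(st.one_of(st.none(), st.floats(min_value=0, max_value=1,
                                             allow_nan=False)))
    return AnnotationBundle(
        allele_frequency=af,
        consequence=draw(st.sampled_from(
            ("missense", "nonsense", "frameshift", "inframe_indel",
             "stoploss", "canonical_splice", "other_splice_region",
             "synonymous", "large_deletion", "other"))),
        de_novo=draw(st.sampled_from(("confirmed", "unconfirmed", "no",
                                      "unknown"))),
        segregates_in_family=draw(st.sampled_from(("yes", "no", "unknown"))),
        functional_study=draw(st.sampled_from(
            ("supports_pathogenic", "supports_benign", "none"))),
        in_silico_verdict=draw(st.sampled_from(
            ("deleterious", "benign_pred", "conflicting", "none"))),
        hotspot_or_domain=draw(st.booleans()),
        observed_healthy_recessive=draw(st.booleans()),
    )


class TestAssignmentProperties:
    @given(bundles(), st.booleans(), st.booleans())
    @settings(max_examples=300, deadline=None)
    def test_profiles_valid_and_free_of_paired_contradictions(
            self, bundle, lof, constrained):
        cfg = GeneRuleConfig(gene="G", lof_mechanism=lof,
                             missense_constrained=constrained)
        profile = assign_codes(bundle, cfg)
        profile.counts.validate()
        codes = set(profile.codes)
        assert not {"PS2", "PM6"} <= codes
        assert not {"PP1", "BS4"} <= codes
        assert not {"PS3", "BS3"} <= codes
        assert not {"PP3", "BP4"} <= codes
        assert not {"PM2", "BA1"} <= codes

    @given(bundles())
    @settings(max_examples=100, deadline=None)
    def test_assignment_is_deterministic(self, bundle):
        assert assign_codes(bundle) == assign_codes(bundle)
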
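"""Combination-engine unit and property tests."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bradyvar import acmg
from bradyvar.acmg import (ALL_CODES, CATEGORY_SIZES, Counts, EvidenceProfile,
                           ProfileError, Strength, Tier, TIER_RANK,
                           classify_counts, classify_profile,
                           enumerate_count_vectors, explain, get_dialect)

from oracle import oracle_tier

DIALECTS = ("paper_verbatim", "acmg2015")


class TestTaxonomy:
    def test_28_codes_with_expected_category_sizes(self):
        assert len(ALL_CODES) == 28
        per_cat = {}
        for cid in ALL_CODES:
            per_cat[acmg.category_of(cid)] = per_cat.get(acmg.category_of(cid), 0) + 1
        assert per_cat == {"PVS": 1, "PS": 4, "PM": 6, "PP": 5,
                           "BA": 1, "BS": 4, "BP": 7}

    @pytest.mark.parametrize("cid, strength", [
        ("PVS1", Strength.VERY_STRONG_PATHOGENIC),
        ("PS4", Strength.STRONG_PATHOGENIC),
        ("PM6", Strength.MODERATE_PATHOGENIC),
        ("PP5", Strength.SUPPORTING_PATHOGENIC),
        ("BA1", Strength.STAND_ALONE_BENIGN),
        ("BS2", Strength.STRONG_BENIGN),
        ("BP7", Strength.SUPPORTING_BENIGN),
    ])
    def test_strength_is_function_of_prefix(self, cid, strength):
        assert ALL_CODES[cid].strength_class is strength

    def test_every_code_has_a_description(self):
        assert all(c.description for c in ALL_CODES.values())


class TestProfile:
    def test_counts_recomputed_from_codes(self):
        p = EvidenceProfile.from_codes(["PVS1", "PS2", "PM2", "BP4"])
        assert p.counts == Counts(1, 1, 1, 0, 0, 0, 1)

    def test_duplicate_codes_rejected(self):
        with pytest.raises(ProfileError, match="duplicate"):
            EvidenceProfile.from_codes(["PM2", "PM2"])

    def test_unknown_code_rejected(self):
        with pytest.raises(ProfileError, match="unknown"):
            EvidenceProfile.from_codes(["PX9"])

    def test_count_bounds_enforced_by_classifier(self):
        with pytest.raises(ProfileError, match="admissible"):
            classify_counts((2, 0, 0, 0, 0, 0, 0))
        with pytest.raises(ProfileError):
            classify_counts((0, 0, 0, 0, 0, 0, -1))


class TestClassifyExamples:
    """Tier outcomes frozen from the printed combination table."""

    @pytest.mark.parametrize("codes, tier", [
        ({"PVS1", "PS3"}, Tier.PATHOGENIC),             # PVS1 + >=1 PS
        (set(), Tier.UNCERTAIN),                        # nothing met
        ({"BA1"}, Tier.BENIGN),                         # stand-alone
        ({"PM1", "PM2", "PP1", "PP3"}, Tier.LIKELY_PATHOGENIC),
        ({"BS1", "BP4"}, Tier.LIKELY_BENIGN),
        ({"PVS1", "PM2"}, Tier.LIKELY_PATHOGENIC),      # PVS1 + 1 PM
        ({"PM2"}, Tier.UNCERTAIN),
    ])
    def test_printed_line_examples(self, codes, tier):
        for dialect in DIALECTS:
            assert classify_profile(codes, dialect).tier is tier

    def test_empty_profile_is_uncertain_without_contradiction(self):
        result = classify_profile(set())
        assert result.tier is Tier.UNCERTAIN
        assert not result.via_contradiction
        assert result.matched_rules == ()

    def test_both_sides_satisfied_is_contradiction(self):
        result = classify_profile({"PVS1", "PS1", "BA1"})
        assert result.tier is Tier.UNCERTAIN
        assert result.via_contradiction

    def test_lone_strong_code_with_ba1_resolves_benign(self):
        # a single PS satisfies no pathogenic combination line, so the
        # stand-alone BA1 line decides and no contradiction is flagged
        result = classify_profile({"PS1", "BA1"})
        assert result.tier is Tier.BENIGN
        assert not result.via_contradiction

    def test_non_uncertain_tiers_carry_matched_rules(self):
        assert classify_profile({"BA1"}).matched_rules == ("1 BA1",)
        assert "1 PVS1 + >=1 PS" in classify_profile({"PVS1", "PS3"}).matched_rules


class TestEnumeration:
    def test_exactly_33600_admissible_vectors(self):
        vectors = enumerate_count_vectors()
        assert len(vectors) == 33_600
        assert len(set(vectors)) == 33_600
        assert Counts(0, 0, 0, 0, 0, 0, 0) in vectors
        assert all(v.PVS <= 1 for v in vectors)
        for cat, size in CATEGORY_SIZES.items():
            assert max(getattr(v, cat) for v in vectors) == size

    @pytest.mark.parametrize("dialect", DIALECTS)
    def test_totality_and_oracle_agreement(self, dialect):
        """Engine agrees with the literal line-by-line oracle everywhere."""
        for counts in enumerate_count_vectors():
            result = classify_counts(counts, dialect)
            tier, contradiction = oracle_tier(counts, dialect)
            assert result.tier.value == tier, counts
            assert result.via_contradiction == contradiction, counts

    @pytest.mark.parametrize("dialect", DIALECTS)
    def test_minimal_profile_of_each_line_hits_its_tier(self, dialect):
        d = get_dialect(dialect)
        for line in d.lines:
            counts = dict.fromkeys(CATEGORY_SIZES, 0)
            counts.update(dict(line.min_counts))
            assert classify_counts(Counts(**counts), d).tier is line.tier, line.name

    def test_order_invariance_over_code_identity(self):
        # same count vector via different codes / orders -> same tier
        a = classify_profile(["PS1", "PM2", "PP3", "PP1"])
        b = classify_profile(["PP5", "PP4", "PS4", "PM6"])
        assert a.tier is b.tier is Tier.LIKELY_PATHOGENIC

    def test_pathogenic_monotonicity_on_benign_free_vectors(self):
        rank = {t.value: k for t, k in TIER_RANK.items()}
        for counts in enumerate_count_vectors():
            if counts.BA or counts.BS or counts.BP:
                continue
            base = rank[classify_counts(counts).tier.value]
            for i, cat in enumerate(("PVS", "PS", "PM", "PP")):
                if counts[i] >= CATEGORY_SIZES[cat]:
                    continue
                bumped = counts._replace(**{cat: counts[i] + 1})
                assert rank[classify_counts(bumped).tier.value] >= base, counts

    def test_dialect_delta_is_nonempty_and_localized(self):
        """The dialects disagree, and only on vectors touched by the two
        changed lines (>=3 supporting vs >=3 moderate; the extra PVS1 line)."""
        delta = []
        for counts in enumerate_count_vectors():
            a = classify_counts(counts, "paper_verbatim")
            b = classify_counts(counts, "acmg2015")
            if (a.tier, a.via_contradiction) != (b.tier, b.via_contradiction):
                delta.append(counts)
        assert delta
        for counts in delta:
            touched = (counts.PP >= 3 or counts.PM >= 3
                       or (counts.PVS >= 1 and counts.PM >= 1 and counts.PP >= 1))
            assert touched, counts


class TestExplain:
    def test_report_names_matched_line_and_tier(self):
        report = explain({"PVS1", "PM2"})
        assert "1 PVS1 + 1 PM" in report
        assert "MATCH" in report
        assert "likely_pathogenic" in report

    def test_report_for_empty_profile_has_no_matches(self):
        report = explain(set())
        assert "MATCH" not in report
        assert "matched lines: 0" in report
        assert "uncertain_significance" in report

    def test_report_flags_contradiction(self):
        report = explain({"BA1", "PVS1", "PS1"})
        assert "contradictory" in report
        assert "uncertain_significance" in report

    def test_report_is_deterministic(self):
        assert explain({"PM2", "PP3"}) == explain({"PP3", "PM2"})


@st.composite
def profiles(draw):
    codes = draw(st.sets(st.sampled_from(sorted(ALL_CODES))))
    return EvidenceProfile(frozenset(codes))


class TestProperties:
    @given(profiles())
    @settings(max_examples=300, deadline=None)
    def test_classifier_total_and_consistent_with_oracle(self, profile):
        for dialect in DIALECTS:
            result = classify_profile(profile, dialect)
            tier, contradiction = oracle_tier(profile.counts, dialect)
            assert result.tier.value == tier
            assert result.via_contradiction == contradiction

    @given(profiles())
    @settings(max_examples=200, deadline=None)
    def test_contradiction_implies_uncertain(self, profile):
        result = classify_profile(profile)
        if result.via_contradiction:
            assert result.tier is Tier.UNCERTAIN

    @given(profiles())
    @settings(max_examples=200, deadline=None)
    def test_counts_within_bounds_for_any_code_set(self, profile):
        profile.counts.validate()
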
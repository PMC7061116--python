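"""ACMG/AMP evidence codes and the five-tier combination engine.

The 2015 ACMG/AMP framework scores variant-level evidence with 28 labelled
criteria — pathogenic codes in four strength classes (PVS1; PS1–PS4; PM1–PM6;
PP1–PP5) and benign codes in three (BA1; BS1–BS4; BP1–BP7) — and combines the
asserted codes into one of five tiers: pathogenic, likely pathogenic,
uncertain significance, likely benign, benign.  Contradictory evidence
(a pathogenic-side combination and a benign-side combination both satisfied)
resolves to uncertain significance.

Two rule dialects are provided:

``paper_verbatim``
    The combination table exactly as printed in the systematic review this
    package reproduces, including its ``>=3 supporting`` likely-pathogenic
    line and its omission of the ``PVS1 + 1 moderate + 1 supporting``
    pathogenic line.
``acmg2015``
    The standard 2015 guideline table (``>=3 moderate`` likely-pathogenic
    line; the extra PVS1 pathogenic line restored).

Combination lines are count-threshold predicates over the per-strength code
counts; classification depends only on those counts, never on code identity
within a strength class.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Sequence

import yaml

__all__ = [
    "CATEGORIES",
    "CATEGORY_SIZES",
    "Strength",
    "Tier",
    "EvidenceCode",
    "ALL_CODES",
    "EvidenceProfile",
    "Classification",
    "CombinationLine",
    "RuleDialect",
    "get_dialect",
    "classify_profile",
    "classify_counts",
    "enumerate_count_vectors",
    "explain",
    "ProfileError",
]

# Strength categories in display order; sizes give the number of codes per
# category and therefore the admissible count range (0..size).
CATEGORIES: tuple[str, ...] = ("PVS", "PS", "PM", "PP", "BA", "BS", "BP")
CATEGORY_SIZES: dict[str, int] = {
    "PVS": 1, "PS": 4, "PM": 6, "PP": 5, "BA": 1, "BS": 4, "BP": 7,
}


class ProfileError(ValueError):
    """Raised for malformed evidence profiles (duplicates, unknown codes,
    count-bound violations)."""


class Strength(str, enum.Enum):
    VERY_STRONG_PATHOGENIC = "very_strong_pathogenic"
    STRONG_PATHOGENIC = "strong_pathogenic"
    MODERATE_PATHOGENIC = "moderate_pathogenic"
    SUPPORTING_PATHOGENIC = "supporting_pathogenic"
    STAND_ALONE_BENIGN = "stand_alone_benign"
    STRONG_BENIGN = "strong_benign"
    SUPPORTING_BENIGN = "supporting_benign"


_PREFIX_STRENGTH = {
    "PVS": Strength.VERY_STRONG_PATHOGENIC,
    "PS": Strength.STRONG_PATHOGENIC,
    "PM": Strength.MODERATE_PATHOGENIC,
    "PP": Strength.SUPPORTING_PATHOGENIC,
    "BA": Strength.STAND_ALONE_BENIGN,
    "BS": Strength.STRONG_BENIGN,
    "BP": Strength.SUPPORTING_BENIGN,
}


class Tier(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain_significance"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


# Pathogenicity ordering used for monotonicity checks and per-gene "best"
# aggregation: benign < likely_benign < uncertain < likely_pathogenic <
# pathogenic.
TIER_RANK: dict[Tier, int] = {
    Tier.BENIGN: 0,
    Tier.LIKELY_BENIGN: 1,
    Tier.UNCERTAIN: 2,
    Tier.LIKELY_PATHOGENIC: 3,
    Tier.PATHOGENIC: 4,
}


def category_of(code_id: str) -> str:
    """Strength category (``PVS`` .. ``BP``) of a code identifier."""
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code_id.startswith(prefix):
            return prefix
    raise ProfileError(f"unknown evidence code {code_id!r}")


@dataclass(frozen=True)
class EvidenceCode:
    """One of the 28 ACMG/AMP criteria.

    ``strength_class`` is a pure function of the identifier prefix.
    """

    code_id: str
    description: str

    @property
    def strength_class(self) -> Strength:
        return _PREFIX_STRENGTH[category_of(self.code_id)]


_DESCRIPTIONS: dict[str, str] = {
    "PVS1": "Null variant (nonsense, frameshift, canonical splice site, "
            "exon-level deletion) in a gene where loss of function is a "
            "known disease mechanism",
    "PS1": "Same amino-acid change as an established pathogenic variant, "
           "via a different nucleotide change",
    "PS2": "De novo, with maternity and paternity confirmed, in a patient "
           "with the disease and no family history",
    "PS3": "Well-established functional studies show a damaging effect",
    "PS4": "Prevalence in affected individuals significantly exceeds that "
           "in controls",
    "PM1": "Located in a mutational hot spot or well-studied functional "
           "domain",
    "PM2": "Absent from (or at extremely low frequency in) large "
           "population databases",
    "PM3": "For recessive disease, detected in trans with a pathogenic "
           "variant",
    "PM4": "Protein length change from an in-frame indel in a non-repeat "
           "region or a stop-loss variant",
    "PM5": "Novel missense change at a residue where a different missense "
           "change is established as pathogenic",
    "PM6": "Assumed de novo, without confirmation of maternity and "
           "paternity",
    "PP1": "Cosegregation with disease in multiple affected family "
           "members",
    "PP2": "Missense variant in a gene with a low rate of benign missense "
           "variation in which missense is a common disease mechanism",
    "PP3": "Multiple lines of computational evidence support a "
           "deleterious effect",
    "PP4": "Phenotype highly specific for a disease with a single genetic "
           "etiology",
    "PP5": "Reputable source reports the variant as pathogenic",
    "BA1": "Allele frequency above 0.5% in a population database "
           "(stand-alone)",
    "BS1": "Allele frequency greater than expected for the disorder",
    "BS2": "Observed in a healthy adult for a recessive "
           "(homozygous) condition",
    "BS3": "Well-established functional studies show no damaging effect",
    "BS4": "Lack of segregation in affected family members",
    "BP1": "Missense variant in a gene where only loss of function causes "
           "disease",
    "BP2": "Observed in trans with a pathogenic variant for a dominant "
           "disorder, or in cis with a pathogenic variant",
    "BP3": "In-frame indel in a repetitive region without known function",
    "BP4": "Multiple lines of computational evidence suggest no impact",
    "BP5": "Found in a case with an alternate molecular basis for "
           "disease",
    "BP6": "Reputable source reports the variant as benign",
    "BP7": "Synonymous/splice-region variant predicted to have no impact "
           "on the splice consensus",
}

#: The full taxonomy: 1 PVS, 4 PS, 6 PM, 5 PP, 1 BA, 4 BS, 7 BP.
ALL_CODES: dict[str, EvidenceCode] = {
    cid: EvidenceCode(cid, desc) for cid, desc in _DESCRIPTIONS.items()
}


class Counts(NamedTuple):
    """Per-strength-category code counts for one profile."""

    PVS: int
    PS: int
    PM: int
    PP: int
    BA: int
    BS: int
    BP: int

    def validate(self) -> None:
        for cat, n in zip(CATEGORIES, self):
            if not (0 <= int(n) <= CATEGORY_SIZES[cat]):
                raise ProfileError(
                    f"count {cat}={n} outside admissible range "
                    f"0..{CATEGORY_SIZES[cat]}"
                )


@dataclass(frozen=True)
class EvidenceProfile:
    """The set of evidence codes asserted for one variant.

    Duplicate code identifiers are rejected: each criterion is asserted at
    most once per variant.
    """

    codes: frozenset[str] = frozenset()

    @classmethod
    def from_codes(cls, codes: Iterable[str | EvidenceCode]) -> "EvidenceProfile":
        ids = [c.code_id if isinstance(c, EvidenceCode) else str(c) for c in codes]
        for cid in ids:
            if cid not in ALL_CODES:
                raise ProfileError(f"unknown evidence code {cid!r}")
        if len(ids) != len(set(ids)):
            dupes = sorted({c for c in ids if ids.count(c) > 1})
            raise ProfileError(f"duplicate evidence codes: {dupes}")
        return cls(frozenset(ids))

    @property
    def counts(self) -> Counts:
        tally = dict.fromkeys(CATEGORIES, 0)
        for cid in self.codes:
            tally[category_of(cid)] += 1
        return Counts(**tally)

    def sorted_codes(self) -> list[str]:
        order = list(_DESCRIPTIONS)
        return sorted(self.codes, key=order.index)


@dataclass(frozen=True)
class Classification:
    """Outcome of the combination engine for one profile."""

    tier: Tier
    via_contradiction: bool = False
    matched_rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.via_contradiction and self.tier is not Tier.UNCERTAIN:
            raise ValueError("contradiction implies uncertain significance")


@dataclass(frozen=True)
class CombinationLine:
    """One line of the combination table: minimum counts per category.

    Thresholds are lower bounds; evidence beyond a line's literal counts is
    absorbed by a higher-tier line or satisfies this one a fortiori, which
    keeps the tier monotone in pathogenic evidence.
    """

    name: str
    tier: Tier
    min_counts: tuple[tuple[str, int], ...]

    def matches(self, counts: Counts) -> bool:
        return all(getattr(counts, cat) >= n for cat, n in self.min_counts)


@dataclass(frozen=True)
class RuleDialect:
    """An ordered set of combination lines grouped by tier."""

    name: str
    lines: tuple[CombinationLine, ...]

    def lines_for(self, tier: Tier) -> tuple[CombinationLine, ...]:
        return tuple(l for l in self.lines if l.tier is tier)

    @classmethod
    def from_mapping(cls, spec: Mapping) -> "RuleDialect":
        lines = []
        for entry in spec["lines"]:
            mins = tuple(sorted(
                (str(cat), int(n)) for cat, n in entry["min"].items()
            ))
            for cat, n in mins:
                if cat not in CATEGORY_SIZES or not 1 <= n <= CATEGORY_SIZES[cat]:
                    raise ValueError(f"bad threshold {cat}>={n} in {entry['name']!r}")
            lines.append(CombinationLine(str(entry["name"]), Tier(entry["tier"]), mins))
        return cls(str(spec["name"]), tuple(lines))

    @classmethod
    def from_yaml(cls, path) -> "RuleDialect":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


_BUILTIN_CACHE: dict[str, RuleDialect] = {}


def get_dialect(name: str = "paper_verbatim") -> RuleDialect:
    """Load a built-in rule dialect (``paper_verbatim`` or ``acmg2015``)."""
    if name not in _BUILTIN_CACHE:
        ref = resources.files("bradyvar.data.dialects") / f"{name}.yaml"
        try:
            text = ref.read_text()
        except FileNotFoundError:
            raise ValueError(f"unknown dialect {name!r}") from None
        _BUILTIN_CACHE[name] = RuleDialect.from_mapping(yaml.safe_load(text))
    return _BUILTIN_CACHE[name]


def _resolve(dialect: RuleDialect | str | None) -> RuleDialect:
    if dialect is None:
        return get_dialect("paper_verbatim")
    if isinstance(dialect, str):
        return get_dialect(dialect)
    return dialect


def classify_counts(
    counts: Counts | Sequence[int],
    dialect: RuleDialect | str | None = None,
) -> Classification:
    """Combine per-category evidence counts into a five-tier classification.

    The pathogenic side resolves to the strongest satisfied tier (any
    pathogenic line, else any likely-pathogenic line); the benign side
    likewise (benign, else likely benign).  If both sides are satisfied the
    evidence is contradictory and the result is uncertain significance with
    ``via_contradiction`` set; if neither side is satisfied the result is
    uncertain significance without the flag.
    """
    counts = Counts(*map(int, counts))
    counts.validate()
    dialect = _resolve(dialect)

    matched = tuple(l.name for l in dialect.lines if l.matches(counts))

    def side(*tiers: Tier) -> Tier | None:
        for tier in tiers:
            if any(l.matches(counts) for l in dialect.lines_for(tier)):
                return tier
        return None

    path_tier = side(Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC)
    benign_tier = side(Tier.BENIGN, Tier.LIKELY_BENIGN)

    if path_tier and benign_tier:
        return Classification(Tier.UNCERTAIN, via_contradiction=True,
                              matched_rules=matched)
    if path_tier:
        return Classification(path_tier, matched_rules=matched)
    if benign_tier:
        return Classification(benign_tier, matched_rules=matched)
    return Classification(Tier.UNCERTAIN)


def classify_profile(
    profile: EvidenceProfile | Iterable[str],
    dialect: RuleDialect | str | None = None,
) -> Classification:
    """Classify an evidence profile (set of asserted codes)."""
    if not isinstance(profile, EvidenceProfile):
        profile = EvidenceProfile.from_codes(profile)
    return classify_counts(profile.counts, dialect)


def enumerate_count_vectors() -> list[Counts]:
    """All admissible per-category count vectors, exactly once each.

    The per-category ranges (0..1, 0..4, 0..6, 0..5, 0..1, 0..4, 0..7) give
    2 * 5 * 7 * 6 * 2 * 5 * 8 = 33,600 vectors.
    """
    ranges = [range(CATEGORY_SIZES[cat] + 1) for cat in CATEGORIES]
    return [Counts(*v) for v in itertools.product(*ranges)]


def explain(
    profile: EvidenceProfile | Iterable[str],
    dialect: RuleDialect | str | None = None,
) -> str:
    """Deterministic plain-text audit of every combination line.

    Lists each line of the dialect's table, whether the profile satisfies
    it, and the final tier (flagging the contradiction pathway).
    """
    if not isinstance(profile, EvidenceProfile):
        profile = EvidenceProfile.from_codes(profile)
    dialect = _resolve(dialect)
    counts = profile.counts
    result = classify_counts(counts, dialect)

    out = [
        f"dialect: {dialect.name}",
        "codes: " + (", ".join(profile.sorted_codes()) or "(none)"),
        "counts: " + " ".join(f"{c}={getattr(counts, c)}" for c in CATEGORIES),
        "",
    ]
    for tier in (Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC, Tier.BENIGN,
                 Tier.LIKELY_BENIGN):
        out.append(f"[{tier.value}]")
        for line in dialect.lines_for(tier):
            mark = "MATCH" if line.matches(counts) else "  -  "
            out.append(f"  {mark}  {line.name}")
    out.append("")
    n_matched = len(result.matched_rules)
    out.append(f"matched lines: {n_matched}")
    if result.via_contradiction:
        out.append("pathogenic and benign combinations both satisfied: "
                   "contradictory evidence")
    out.append(f"classification: {result.tier.value}")
    return "\n".join(out)
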
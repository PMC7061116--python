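"""Annotation bundles → ACMG/AMP evidence codes.

This layer turns the per-variant facts a curator can actually collect
(population allele frequency, consequence class, de novo status, family
segregation, functional-study outcome, in-silico verdict) into the evidence
codes the combination engine consumes.  The frequency thresholds are the
review's: an allele frequency strictly below 0.001 satisfies the rarity
criterion PM2 ("absent or extremely low in population databases"), and a
frequency strictly above 0.5% triggers the stand-alone benign code BA1.
Codes that need knowledge the bundle does not model (e.g. PS1, PM3, PP5)
pass through as manual curator assertions, never auto-assigned and never
auto-revoked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .acmg import (ALL_CODES, Classification, EvidenceProfile, RuleDialect,
                   classify_profile)
from .dataset import VariantRecord

__all__ = [
    "CONSEQUENCES",
    "NULL_CONSEQUENCES",
    "AnnotationBundle",
    "GeneRuleConfig",
    "Thresholds",
    "VocabularyError",
    "assign_codes",
    "classify_variant",
    "consequence_for_splice_hgvs",
    "load_gene_configs",
    "AUTO_CODES",
    "MANUAL_ONLY_CODES",
]

CONSEQUENCES = (
    "missense", "nonsense", "frameshift", "inframe_indel", "stoploss",
    "canonical_splice", "other_splice_region", "synonymous",
    "large_deletion", "other",
)
#: Consequences presumed to abolish gene product function (PVS1 candidates).
NULL_CONSEQUENCES = frozenset(
    {"nonsense", "frameshift", "canonical_splice", "large_deletion"})

_DE_NOVO = ("confirmed", "unconfirmed", "no", "unknown")
_SEGREGATION = ("yes", "no", "unknown")
_FUNCTIONAL = ("supports_pathogenic", "supports_benign", "none")
_IN_SILICO = ("deleterious", "benign_pred", "conflicting", "none")

#: Codes the rules below can emit on their own.
AUTO_CODES = frozenset({"PVS1", "PS2", "PS3", "PM1", "PM2", "PM4", "PM6",
                        "PP1", "PP2", "PP3", "BA1", "BS2", "BS3", "BS4",
                        "BP4"})
#: Codes requiring external knowledge; accepted only as manual assertions.
MANUAL_ONLY_CODES = frozenset(ALL_CODES) - AUTO_CODES


class VocabularyError(ValueError):
    """An annotation field carries a label outside its controlled vocabulary."""


def _check(value: str, allowed: tuple[str, ...], field_name: str) -> str:
    if value not in allowed:
        raise VocabularyError(
            f"{field_name}={value!r} not in {sorted(allowed)}")
    return value


@dataclass(frozen=True)
class AnnotationBundle:
    """Per-variant annotation facts feeding the assignment rules."""

    allele_frequency: float | None = None
    consequence: str = "other"
    de_novo: str = "unknown"
    segregates_in_family: str = "unknown"
    functional_study: str = "none"
    in_silico_verdict: str = "none"
    hotspot_or_domain: bool = False
    observed_healthy_recessive: bool = False
    manual_codes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.allele_frequency is not None and not (
                0.0 <= self.allele_frequency <= 1.0):
            raise ValueError(
                f"allele_frequency {self.allele_frequency} outside [0, 1]")
        _check(self.consequence, CONSEQUENCES, "consequence")
        _check(self.de_novo, _DE_NOVO, "de_novo")
        _check(self.segregates_in_family, _SEGREGATION, "segregates_in_family")
        _check(self.functional_study, _FUNCTIONAL, "functional_study")
        _check(self.in_silico_verdict, _IN_SILICO, "in_silico_verdict")
        for code in self.manual_codes:
            if code not in ALL_CODES:
                raise VocabularyError(f"unknown manual code {code!r}")


@dataclass(frozen=True)
class GeneRuleConfig:
    """Gene-level switches conditioning PVS1 and PP2.

    ``lof_mechanism``: loss of function is an established disease mechanism
    for this gene (prerequisite for PVS1).  ``missense_constrained``: the
    gene has a low rate of benign missense variation (prerequisite for PP2).
    Both default to False, i.e. the codes are withheld unless configured.
    """

    gene: str
    lof_mechanism: bool = False
    missense_constrained: bool = False


@dataclass(frozen=True)
class Thresholds:
    """Allele-frequency cut-offs.

    ``pm2_max_af``: PM2 fires strictly below this (default 0.001).
    ``ba1_min_af``: BA1 fires strictly above this (default 0.005).
    """

    pm2_max_af: float = 0.001
    ba1_min_af: float = 0.005

    def __post_init__(self) -> None:
        if not self.pm2_max_af < self.ba1_min_af:
            raise ValueError(
                f"pm2_max_af ({self.pm2_max_af}) must be below "
                f"ba1_min_af ({self.ba1_min_af})")


def assign_codes(
    annotations: AnnotationBundle,
    gene_config: GeneRuleConfig | None = None,
    thresholds: Thresholds | None = None,
) -> EvidenceProfile:
    """Apply the automatic assignment rules and merge manual assertions.

    Both frequency comparisons are strict, so a frequency exactly at a
    threshold triggers neither code.  An absent allele frequency counts as
    "absent from large population studies" and yields PM2 — the curated
    frameshift/deletion/splice tables list no population frequency for
    variants that were nonetheless evaluated.
    """
    gene_config = gene_config or GeneRuleConfig(gene="")
    thresholds = thresholds or Thresholds()
    ann = annotations
    codes: set[str] = set()

    af = ann.allele_frequency
    if af is None or af < thresholds.pm2_max_af:
        codes.add("PM2")
    if af is not None and af > thresholds.ba1_min_af:
        codes.add("BA1")

    if ann.consequence in NULL_CONSEQUENCES and gene_config.lof_mechanism:
        codes.add("PVS1")
    if ann.consequence in ("inframe_indel", "stoploss"):
        codes.add("PM4")
    if ann.consequence == "missense" and gene_config.missense_constrained:
        codes.add("PP2")

    if ann.de_novo == "confirmed":
        codes.add("PS2")
    elif ann.de_novo == "unconfirmed":
        codes.add("PM6")

    if ann.functional_study == "supports_pathogenic":
        codes.add("PS3")
    elif ann.functional_study == "supports_benign":
        codes.add("BS3")

    if ann.segregates_in_family == "yes":
        codes.add("PP1")
    elif ann.segregates_in_family == "no":
        codes.add("BS4")

    if ann.in_silico_verdict == "deleterious":
        codes.add("PP3")
    elif ann.in_silico_verdict == "benign_pred":
        codes.add("BP4")

    if ann.hotspot_or_domain:
        codes.add("PM1")
    if ann.observed_healthy_recessive:
        codes.add("BS2")

    # manual assertions are additive; set union avoids double-counting a
    # manually repeated auto code
    codes |= set(ann.manual_codes)
    return EvidenceProfile(frozenset(codes))


def classify_variant(
    record: VariantRecord | AnnotationBundle,
    gene_config: GeneRuleConfig | None = None,
    thresholds: Thresholds | None = None,
    dialect: RuleDialect | str | None = None,
) -> Classification:
    """Assignment composed with the combination engine for one variant."""
    if isinstance(record, AnnotationBundle):
        ann = record
    else:
        ann = record.annotations
        if ann is None:
            raise ValueError(
                f"record {record.record_id!r} carries no annotation bundle")
    return classify_profile(assign_codes(ann, gene_config, thresholds), dialect)


def consequence_for_splice_hgvs(hgvs: str) -> str:
    """Map a splice HGVS description to a consequence class.

    Changes at the ±1/±2 intronic positions (``+1G>T``, ``-2A>G`` …) hit the
    canonical donor/acceptor dinucleotide and are treated as null
    (``canonical_splice``); anything deeper is ``other_splice_region``.
    """
    stem = hgvs.split(">")[0].strip()
    stem = stem[:-1] if stem and stem[-1].isalpha() else stem
    for sign in ("+", "-"):
        idx = stem.rfind(sign)
        if idx > 0:
            offset = stem[idx + 1:]
            if offset.isdigit() and int(offset) in (1, 2):
                return "canonical_splice"
    return "other_splice_region"


def load_gene_configs(path: str | Path) -> dict[str, GeneRuleConfig]:
    """Read gene-level rule switches from a YAML mapping.

    Format::

        SCN5A: {lof_mechanism: true, missense_constrained: true}
        TTN:   {lof_mechanism: false}
    """
    with open(path) as fh:
        raw: Mapping = yaml.safe_load(fh) or {}
    return {
        gene: GeneRuleConfig(
            gene=gene,
            lof_mechanism=bool(cfg.get("lof_mechanism", False)),
            missense_constrained=bool(cfg.get("missense_constrained", False)),
        )
        for gene, cfg in raw.items()
    }
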
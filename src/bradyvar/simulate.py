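"""Synthetic cohorts with planted pathogenic genes.

The generator emits annotated variant records whose evidence structure
mirrors what the assignment rules consume, so the whole pipeline —
assignment, combination engine, per-gene prioritization — is testable
without the curated fixture.

Construction guarantees at ``noise_rate = 0``:

* every variant in a *planted* gene draws an annotation bundle that
  deterministically classifies at least likely pathogenic: either a null
  variant in a loss-of-function gene with the rarity code (PVS1 + PM2 →
  likely pathogenic at minimum), or a hot-spot missense variant with forced
  segregation and in-silico support (PM1 + PM2 + PP1 + PP3);
* every variant in a non-planted gene draws either a common-frequency
  benign-leaning bundle (BA1, → benign) or a rare bundle with no further
  evidence (PM2 only, → uncertain significance).

With ``noise_rate > 0`` a non-planted variant instead receives, with that
probability, strong spurious evidence (confirmed de novo plus a supporting
functional study → two strong pathogenic codes), which creates
false-positive high-priority genes and degrades recovery specificity — the
dial the recovery tests turn.

Rare allele frequencies are drawn log-uniform on [1e-6, 5e-4] and common
ones uniform on [0.01, 0.5]; both straddle their respective decision
thresholds (0.001 and 0.005) with a wide margin so that threshold boundary
behaviour is left to the explicit boundary tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import yaml

from .acmg import ALL_CODES, EvidenceProfile
from .assignment import AnnotationBundle, GeneRuleConfig
from .dataset import VariantRecord

__all__ = ["CohortSpec", "SyntheticCohort", "gen_cohort", "gen_profiles"]

_BASES = ("A", "C", "G", "T")
_RARE_AF = (1e-6, 5e-4)     # log-uniform support for rare variants
_COMMON_AF = (0.01, 0.5)    # uniform support for common variants


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``noise_rate`` is the probability that a non-planted variant receives
    pathogenic-leaning evidence; all other probabilities shape the planted
    variants' evidence mix without affecting their guaranteed tier.
    """

    n_genes: int = 10
    n_variants: int = 50
    planted_pathogenic_genes: tuple[str, ...] = ()
    n_planted: int | None = None        # alternative to naming genes
    p_planted_null: float = 0.7         # planted variant is a null variant
    p_af_absent: float = 0.5            # rare variant absent from databases
    p_de_novo_confirmed: float = 0.3
    p_functional_support: float = 0.5
    p_nonplanted_common: float = 0.4    # non-planted variant is common/benign
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_planted_null", "p_af_absent", "p_de_novo_confirmed",
                     "p_functional_support", "p_nonplanted_common",
                     "noise_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_genes < 1 or self.n_variants < 0:
            raise ValueError("n_genes must be >= 1 and n_variants >= 0")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "planted_pathogenic_genes" in raw:
            raw["planted_pathogenic_genes"] = tuple(
                raw["planted_pathogenic_genes"])
        return cls(**raw)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus its construction ground truth."""

    spec: CohortSpec
    records: tuple[VariantRecord, ...]
    gene_configs: Mapping[str, GeneRuleConfig]
    truth_tiers: Mapping[str, str]       # record_id -> intended tier
    planted_genes: tuple[str, ...]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({r.gene for r in self.records}))


def _resolve_genes(spec: CohortSpec) -> tuple[list[str], list[str]]:
    genes = [f"GENE{i:03d}" for i in range(1, spec.n_genes + 1)]
    if spec.planted_pathogenic_genes:
        planted = list(spec.planted_pathogenic_genes)
        missing = set(planted) - set(genes)
        if missing:
            raise ValueError(
                f"planted genes {sorted(missing)} not among generated genes")
    else:
        planted = genes[: (spec.n_planted or 0)]
    if planted and spec.n_variants == 0:
        raise ValueError("planted genes require at least one variant")
    return genes, planted


def _planted_bundle(rng: np.random.Generator, spec: CohortSpec
                    ) -> tuple[AnnotationBundle, str]:
    af = None if rng.random() < spec.p_af_absent else float(np.exp(
        rng.uniform(np.log(_RARE_AF[0]), np.log(_RARE_AF[1]))))
    if rng.random() < spec.p_planted_null:
        consequence = str(rng.choice(
            ["frameshift", "nonsense", "canonical_splice"]))
        bundle = AnnotationBundle(
            allele_frequency=af,
            consequence=consequence,
            de_novo="confirmed"
            if rng.random() < spec.p_de_novo_confirmed else "unknown",
            functional_study="supports_pathogenic"
            if rng.random() < spec.p_functional_support else "none",
        )
    else:
        # hot-spot missense with forced segregation + in-silico support
        bundle = AnnotationBundle(
            allele_frequency=af,
            consequence="missense",
            hotspot_or_domain=True,
            segregates_in_family="yes",
            in_silico_verdict="deleterious",
            functional_study="supports_pathogenic"
            if rng.random() < spec.p_functional_support else "none",
        )
    return bundle, "likely_pathogenic"


def _nonplanted_bundle(rng: np.random.Generator, spec: CohortSpec
                       ) -> tuple[AnnotationBundle, str]:
    if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
        # spurious strong evidence: PS2 + PS3 (+ PM2) -> pathogenic
        return AnnotationBundle(
            allele_frequency=None,
            consequence="missense",
            de_novo="confirmed",
            functional_study="supports_pathogenic",
        ), "uncertain_significance"
    if rng.random() < spec.p_nonplanted_common:
        return AnnotationBundle(
            allele_frequency=float(rng.uniform(*_COMMON_AF)),
            consequence=str(rng.choice(["synonymous", "missense"])),
            in_silico_verdict="benign_pred",
        ), "benign"
    return AnnotationBundle(
        allele_frequency=float(np.exp(
            rng.uniform(np.log(_RARE_AF[0]), np.log(_RARE_AF[1])))),
        consequence="missense",
    ), "uncertain_significance"


def gen_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort; identical spec (incl. seed) → identical cohort."""
    rng = np.random.default_rng(spec.seed)
    genes, planted = _resolve_genes(spec)
    planted_set = set(planted)

    gene_configs = {
        g: GeneRuleConfig(gene=g, lof_mechanism=g in planted_set,
                          missense_constrained=g in planted_set)
        for g in genes
    }

    records: list[VariantRecord] = []
    truth: dict[str, str] = {}
    # round-robin over genes so every planted gene receives >= 1 variant
    for i in range(spec.n_variants):
        gene = genes[i % len(genes)]
        rid = f"SIM-{i + 1:04d}"
        if gene in planted_set:
            bundle, tier = _planted_bundle(rng, spec)
        else:
            bundle, tier = _nonplanted_bundle(rng, spec)
        chrom = str(int(rng.integers(1, 23)))
        pos = int(rng.integers(1_000_000, 200_000_000))
        if bundle.consequence in ("frameshift", "canonical_splice"):
            vclass = ("frameshift" if bundle.consequence == "frameshift"
                      else "splice")
            ref = alt = None
            chrom_out, pos_out = chrom, pos
        else:
            vclass = "snv"
            ref = str(rng.choice(_BASES))
            alt = str(rng.choice([b for b in _BASES if b != ref]))
            chrom_out, pos_out = chrom, pos
        records.append(VariantRecord(
            record_id=rid, gene=gene, chrom=chrom_out, pos=pos_out,
            ref=ref, alt=alt, variant_class=vclass, annotations=bundle,
        ))
        truth[rid] = tier

    if planted_set and spec.n_variants < len(genes):
        covered = {r.gene for r in records}
        if not planted_set <= covered:
            raise ValueError(
                "n_variants too small to cover every planted gene")
    return SyntheticCohort(
        spec=spec,
        records=tuple(records),
        gene_configs=gene_configs,
        truth_tiers=truth,
        planted_genes=tuple(planted),
    )


def gen_profiles(
    n: int,
    code_probs: Mapping[str, float] | float = 0.0,
    seed: int = 0,
) -> list[EvidenceProfile]:
    """Draw ``n`` evidence profiles with independent per-code Bernoulli draws.

    ``code_probs`` is either one probability applied to all 28 codes or a
    mapping from code id to probability (missing codes default to 0).
    Used to fuzz the combination engine against a brute-force oracle.
    """
    if isinstance(code_probs, (int, float)):
        probs = {cid: float(code_probs) for cid in ALL_CODES}
    else:
        probs = {cid: float(code_probs.get(cid, 0.0)) for cid in ALL_CODES}
    for cid, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {cid} outside [0, 1]: {p}")
    rng = np.random.default_rng(seed)
    order = list(ALL_CODES)
    draws = rng.random((n, len(order)))
    out = []
    for row in draws:
        codes = frozenset(cid for cid, u in zip(order, row) if u < probs[cid])
        out.append(EvidenceProfile(codes))
    return out
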
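"""Per-gene aggregation, high-priority gene list, phenotype categories.

A gene is *high priority* for a familial-bradycardia panel when at least one
of its curated variants is classified pathogenic or likely pathogenic
(slashed "Pathogenic/likely pathogenic" verdicts qualify).  On the shipped
dataset this yields the 13-gene panel: ABCC9, ACTN2, CACNA1C, DES, HCN4,
KCNH2, KCNQ1, LAMP2, LMNA, MECP2, NPPA, SCN5A, TRPM4.

Clinical-manifestation tokens are folded into five phenotype categories
(conduction disease, other arrhythmia, cardiomyopathy/myopathy, nervous
system, other) so that the overlap of bradycardia with other presentations
per gene is visible at a glance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .acmg import Classification, Tier, TIER_RANK
from .dataset import VariantRecord, Verdict

log = logging.getLogger(__name__)

__all__ = [
    "PHENOTYPE_CATEGORIES",
    "PhenotypeMap",
    "DEFAULT_PHENOTYPE_MAP",
    "GeneSummary",
    "summarize_by_gene",
    "high_priority_genes",
    "reclassified_to_vus",
    "gene_report_frame",
]

PHENOTYPE_CATEGORIES = (
    "conduction_disease", "other_arrhythmia", "cardiomyopathy_or_myopathy",
    "nervous_system", "other",
)


@dataclass(frozen=True)
class PhenotypeMap:
    """Total mapping from manifestation tokens to phenotype categories.

    Tokens missing from the mapping fall back to ``other`` and are logged,
    so the mapping stays total over any input.
    """

    mapping: Mapping[str, str]

    def category(self, token: str) -> str:
        cat = self.mapping.get(token)
        if cat is None:
            log.warning("unmapped manifestation token %r -> 'other'", token)
            return "other"
        if cat not in PHENOTYPE_CATEGORIES:
            raise ValueError(f"unknown phenotype category {cat!r}")
        return cat


DEFAULT_PHENOTYPE_MAP = PhenotypeMap({
    # bradycardia / conduction phenotypes
    "SSS": "conduction_disease",
    "AVB": "conduction_disease",
    "PCCD": "conduction_disease",
    "CCD": "conduction_disease",
    # other arrhythmia
    "AF": "other_arrhythmia",
    "AFL": "other_arrhythmia",
    "VT": "other_arrhythmia",
    "LQT": "other_arrhythmia",
    "WPW": "other_arrhythmia",
    "SCD": "other_arrhythmia",
    "Timothy syndrome 1 (TS1)": "other_arrhythmia",  # long-QT spectrum
    # cardiomyopathy / myopathy
    "DCM": "cardiomyopathy_or_myopathy",
    "HCM": "cardiomyopathy_or_myopathy",
    "LVNC": "cardiomyopathy_or_myopathy",
    "cardiomyopathy": "cardiomyopathy_or_myopathy",
    "muscular dystrophy": "cardiomyopathy_or_myopathy",
    "Danon disease": "cardiomyopathy_or_myopathy",
    # nervous system
    "nerve system disease": "nervous_system",
    # everything else observed in the curated tables
    "HF": "other",
    "ASD": "other",
    "congenital cardiovascular diseases (CCVD)": "other",
    "atrial dilatation (AD)": "other",
    "focal segmental glomerulosclerosis (FSGS)": "other",
})


@dataclass(frozen=True)
class GeneSummary:
    """Aggregate over all records of one gene."""

    gene: str
    n_records: int
    best_classification: Tier
    best_label: str | None
    high_priority: bool
    phenotype_categories: frozenset[str]

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("a gene summary needs at least one record")


def _verdict_rank(verdict: Verdict | None) -> int:
    # records without a printed verdict contribute as uncertain
    return TIER_RANK[Tier.UNCERTAIN] if verdict is None else verdict.rank


def summarize_by_gene(
    records: Sequence[VariantRecord],
    phenomap: PhenotypeMap | None = None,
    verdict_source: str = "printed",
    classifier: Callable[[VariantRecord], Classification] | None = None,
) -> list[GeneSummary]:
    """Build one :class:`GeneSummary` per distinct gene.

    ``verdict_source='printed'`` ranks records by their published
    classification (records without one count as uncertain);
    ``'computed'`` ranks them by running ``classifier`` — typically a
    closure over :func:`bradyvar.assignment.classify_variant` — on each
    record.  ``best_classification`` is the strongest tier among the gene's
    records on the order benign < likely_benign < uncertain <
    likely_pathogenic < pathogenic, slashed verdicts contributing their
    stronger side.
    """
    if verdict_source not in ("printed", "computed"):
        raise ValueError("verdict_source must be 'printed' or 'computed'")
    if verdict_source == "computed" and classifier is None:
        raise ValueError("verdict_source='computed' requires a classifier")
    phenomap = phenomap or DEFAULT_PHENOTYPE_MAP

    by_gene: dict[str, list[VariantRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, []).append(rec)

    summaries = []
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        if verdict_source == "printed":
            ranked = [(_verdict_rank(r.verdict),
                       r.verdict.label if r.verdict else None) for r in recs]
        else:
            tiers = [classifier(r).tier for r in recs]
            ranked = [(TIER_RANK[t], t.value) for t in tiers]
        best_rank, best_label = max(ranked, key=lambda t: t[0])
        best_tier = next(t for t, k in TIER_RANK.items() if k == best_rank)
        cats = frozenset(
            phenomap.category(tok) for r in recs for tok in r.manifestations)
        summaries.append(GeneSummary(
            gene=gene,
            n_records=len(recs),
            best_classification=best_tier,
            best_label=best_label,
            high_priority=best_rank >= TIER_RANK[Tier.LIKELY_PATHOGENIC],
            phenotype_categories=cats,
        ))
    return summaries


def high_priority_genes(summaries: Iterable[GeneSummary]) -> list[str]:
    """Alphabetical symbols of genes with at least one P/LP record."""
    return sorted(s.gene for s in summaries if s.high_priority)


def reclassified_to_vus(summaries: Iterable[GeneSummary]) -> list[str]:
    """Genes whose strongest record is uncertain significance.

    On the curated SNV table these are the previously-published-pathogenic
    genes demoted to VUS by the rule-engine reevaluation.
    """
    return sorted(s.gene for s in summaries
                  if s.best_classification is Tier.UNCERTAIN)


def gene_report_frame(summaries: Sequence[GeneSummary]):
    """Gene report as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "gene": s.gene,
            "n_records": s.n_records,
            "best_classification": s.best_classification.value,
            "best_label": s.best_label or "",
            "high_priority": s.high_priority,
            "phenotype_categories": ";".join(sorted(s.phenotype_categories)),
        }
        for s in summaries
    ])
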
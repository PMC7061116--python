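"""Curated variant dataset and study-screening ledger.

The package ships, as plain-TSV package data, a hand transcription of the
variant tables from a systematic review of familial-bradycardia pedigree
reports (2008–2019): 73 SNVs with published rule-engine verdicts (table T3),
16 frameshift records (T4), 1 large deletion (T5) and 9 splice records (T6)
— 99 records over 34 genes after gene-symbol normalization.  Each printed
table row is one record, so a variant reported by two independent studies
appears twice; that row-as-record convention is what the 99-record total
counts.

Fixture files carry SHA-256 sidecars; loaders verify them so a corrupted
transcription fails loudly rather than silently shifting counts.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .acmg import Tier, TIER_RANK

log = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "ScreeningLedger",
    "Verdict",
    "parse_verdict",
    "FixtureIntegrityError",
    "load_curated",
    "load_screening_ledger",
    "included_count",
    "distinct_genes",
    "read_records_tsv",
    "write_records_tsv",
    "export_vcf",
]

VARIANT_CLASSES = ("snv", "frameshift", "large_deletion", "splice", "other")

#: Printed symbols collapsed onto current HGNC symbols. The printed spelling
#: is retained in ``gene_printed``.
GENE_ALIASES = {"NKX2.5": "NKX2-5", "TGF beta 1": "TGFB1"}


class FixtureIntegrityError(RuntimeError):
    """Checksum mismatch on a shipped fixture file."""


@dataclass(frozen=True)
class Verdict:
    """A parsed printed classification.

    Slashed verdicts ("Pathogenic/likely pathogenic") keep both sides; the
    stronger side (further from uncertain) drives ranking, the pair is kept
    so neither reading is lost.  "Conflicting interpretations of
    pathogenicity" ranks as uncertain significance.
    """

    label: str
    stronger: Tier
    weaker: Tier
    is_conflicting: bool = False

    @property
    def rank(self) -> int:
        return TIER_RANK[self.stronger]


_TIER_LABELS = {
    "pathogenic": Tier.PATHOGENIC,
    "likely pathogenic": Tier.LIKELY_PATHOGENIC,
    "uncertain significance": Tier.UNCERTAIN,
    "uncertain significant": Tier.UNCERTAIN,  # spelling used in table T4
    "likely benign": Tier.LIKELY_BENIGN,
    "benign": Tier.BENIGN,
}


def parse_verdict(label: str | None) -> Verdict | None:
    """Parse a printed classification label; ``None``/empty means no verdict."""
    if label is None or not str(label).strip():
        return None
    text = str(label).strip()
    low = text.lower()
    if low.startswith("conflicting"):
        return Verdict(text, Tier.UNCERTAIN, Tier.UNCERTAIN, is_conflicting=True)
    if "/" in low:
        left, _, right = low.partition("/")
        tiers = [_TIER_LABELS[left.strip()], _TIER_LABELS[right.strip()]]
        # stronger = further from uncertain on the pathogenicity axis
        tiers.sort(key=lambda t: abs(TIER_RANK[t] - TIER_RANK[Tier.UNCERTAIN]))
        return Verdict(text, stronger=tiers[-1], weaker=tiers[0])
    if low not in _TIER_LABELS:
        raise ValueError(f"unrecognized classification label {label!r}")
    tier = _TIER_LABELS[low]
    return Verdict(text, tier, tier)


@dataclass(frozen=True)
class VariantRecord:
    """One curated, user-supplied, or simulated variant."""

    record_id: str
    gene: str
    table_of_origin: str | None = None
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    hgvs: str | None = None
    dbsnp: str | None = None
    gene_printed: str | None = None
    locus_label: str | None = None
    variant_class: str = "snv"
    printed_classification: str | None = None
    functional_study_note: str | None = None
    gnomad_af_label: str | None = None
    manifestations: tuple[str, ...] = ()
    source: str | None = None
    annotations: "object | None" = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError(f"record {self.record_id!r} lacks a gene symbol")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")
        if self.variant_class == "snv":
            if not all((self.chrom, self.pos, self.ref, self.alt)):
                raise ValueError(
                    f"snv record {self.record_id!r} must carry chrom/pos/ref/alt")
            if self.ref == self.alt:
                raise ValueError(f"snv record {self.record_id!r} has ref == alt")

    @property
    def verdict(self) -> Verdict | None:
        return parse_verdict(self.printed_classification)

    @property
    def has_coordinates(self) -> bool:
        return all((self.chrom, self.pos, self.ref, self.alt))


@dataclass(frozen=True)
class ScreeningLedger:
    """Article counts from the study-selection flow of the literature search."""

    enrolled: int
    excluded: int
    included: int

    def __post_init__(self) -> None:
        if min(self.enrolled, self.excluded, self.included) < 0:
            raise ValueError("ledger counts must be non-negative")


def included_count(ledger: ScreeningLedger) -> int:
    """Articles surviving screening: enrolled minus excluded.

    Cross-checks the stored ``included`` field and rejects an inconsistent
    or negative ledger.
    """
    n = ledger.enrolled - ledger.excluded
    if n < 0:
        raise ValueError("excluded exceeds enrolled")
    if n != ledger.included:
        raise ValueError(
            f"ledger inconsistent: enrolled-excluded={n} != included={ledger.included}")
    return n


# --------------------------------------------------------------------------
# fixture IO

_TSV_COLUMNS = [
    "record_id", "table_of_origin", "chrom", "pos", "ref", "alt", "hgvs",
    "dbsnp", "gene", "gene_printed", "locus_label", "variant_class",
    "printed_classification", "functional_study_note", "gnomad_af_label",
    "manifestations", "source",
]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("bradyvar.data") / name))


def _verify_checksum(path: Path) -> None:
    sidecar = Path(str(path) + ".sha256")
    expected = sidecar.read_text().split()[0]
    actual = hashlib.sha256(path.read_bytes()).hexdigest()
    if actual != expected:
        raise FixtureIntegrityError(
            f"{path.name}: SHA-256 {actual} != recorded {expected}")


def read_records_tsv(path: str | Path) -> list[VariantRecord]:
    """Read a variant-record table in the package's TSV dialect."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.to_dict("records"):
        records.append(VariantRecord(
            record_id=row["record_id"],
            table_of_origin=row.get("table_of_origin") or None,
            chrom=row.get("chrom") or None,
            pos=int(row["pos"]) if row.get("pos") else None,
            ref=row.get("ref") or None,
            alt=row.get("alt") or None,
            hgvs=row.get("hgvs") or None,
            dbsnp=row.get("dbsnp") or None,
            gene=row["gene"],
            gene_printed=row.get("gene_printed") or None,
            locus_label=row.get("locus_label") or None,
            variant_class=row.get("variant_class") or "snv",
            printed_classification=row.get("printed_classification") or None,
            functional_study_note=row.get("functional_study_note") or None,
            gnomad_af_label=row.get("gnomad_af_label") or None,
            manifestations=tuple(
                t.strip() for t in row.get("manifestations", "").split(";")
                if t.strip()),
            source=row.get("source") or None,
        ))
    return records


def write_records_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records in the same TSV dialect ``read_records_tsv`` accepts."""
    rows = []
    for r in records:
        row = {}
        for col in _TSV_COLUMNS:
            value = getattr(r, col)
            if col == "manifestations":
                value = ";".join(value)
            row[col] = "" if value is None else str(value)
        rows.append(row)
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def load_curated(verify: bool = True) -> list[VariantRecord]:
    """Load the shipped 99-record curated dataset.

    ``verify=True`` (default) checks the SHA-256 sidecar first and raises
    :class:`FixtureIntegrityError` on mismatch.
    """
    path = _data_path("curated_variants.tsv")
    if verify:
        _verify_checksum(path)
    records = read_records_tsv(path)
    for rec in records:
        if rec.table_of_origin == "T3" and rec.verdict is None:
            raise FixtureIntegrityError(
                f"T3 record {rec.record_id} lacks a printed classification")
    return records


def load_screening_ledger(verify: bool = True) -> ScreeningLedger:
    """Load the article-screening ledger (enrolled / excluded / included)."""
    path = _data_path("screening_ledger.tsv")
    if verify:
        _verify_checksum(path)
    df = pd.read_csv(path, sep="\t")
    row = df.iloc[0]
    return ScreeningLedger(int(row["enrolled"]), int(row["excluded"]),
                           int(row["included"]))


def distinct_genes(records: Iterable[VariantRecord]) -> set[str]:
    """Distinct normalized gene symbols across records."""
    return {r.gene for r in records}


# --------------------------------------------------------------------------
# VCF export

_CHROM_ORDER = {str(c): i for i, c in enumerate(
    [*range(1, 23), "X", "Y", "MT"], start=1)}


def _info_escape(text: str) -> str:
    """Replace characters VCF 4.2 forbids in INFO values."""
    for ch in " ;,=":
        text = text.replace(ch, "_")
    return text


def export_vcf(records: Sequence[VariantRecord], path: str | Path) -> int:
    """Write coordinate-complete records as a minimal VCF 4.2 file.

    Positions are 1-based GRCh38 as curated.  The printed classification,
    source tag and origin table travel in INFO.  Records without full
    chrom/pos/ref/alt are skipped and counted in the log; returns the number
    of records written.
    """
    exportable = [r for r in records if r.has_coordinates]
    skipped = len(records) - len(exportable)
    if skipped:
        log.info("export_vcf: skipped %d records lacking coordinates", skipped)
    exportable.sort(key=lambda r: (_CHROM_ORDER.get(r.chrom, 99), r.pos,
                                   r.record_id))
    contigs = sorted({r.chrom for r in exportable},
                     key=lambda c: _CHROM_ORDER.get(c, 99))
    lines = [
        "##fileformat=VCFv4.2",
        '##reference=GRCh38',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description='
        '"Published classification">',
        '##INFO=<ID=SOURCE,Number=1,Type=String,Description="Reporting study">',
        '##INFO=<ID=TABLE,Number=1,Type=String,Description="Origin table">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in exportable:
        info = [f"GENE={_info_escape(r.gene)}"]
        if r.printed_classification:
            info.append(f"CLASS={_info_escape(r.printed_classification)}")
        if r.source:
            info.append(f"SOURCE={_info_escape(r.source)}")
        if r.table_of_origin:
            info.append(f"TABLE={r.table_of_origin}")
        lines.append("\t".join([
            r.chrom, str(r.pos), r.dbsnp or r.record_id, r.ref, r.alt,
            ".", ".", ";".join(info),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
    return len(exportable)
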
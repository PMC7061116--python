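"""Readers and writers for annotated variant cohorts.

Two input dialects are supported:

* **TSV** — one header row; one variant per line.  Required columns:
  ``record_id``, ``gene``.  Optional columns: the
  :class:`~bradyvar.assignment.AnnotationBundle` field names
  (``allele_frequency``, ``consequence``, ``de_novo``,
  ``segregates_in_family``, ``functional_study``, ``in_silico_verdict``,
  ``hotspot_or_domain``, ``observed_healthy_recessive``, ``manual_codes`` —
  comma-separated), locus columns (``chrom``, ``pos``, ``ref``, ``alt``,
  ``variant_class``) and per-gene rule switches (``lof_mechanism``,
  ``missense_constrained``).  Empty cells mean "absent/unknown".

* **VCF** — one variant per data line; annotations read from INFO keys
  ``AF`` (float), ``GENE``, ``CSQ_CLASS`` (consequence vocabulary),
  ``DENOVO``, ``SEGREGATION``, ``FUNC``, ``INSILICO``, ``MANUAL``
  (comma-separated codes).  Missing keys default like empty TSV cells.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam

from .assignment import AnnotationBundle, GeneRuleConfig
from .dataset import VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "MalformedRowError",
    "read_annotated_tsv",
    "write_annotated_tsv",
    "read_annotated_vcf",
]

_BUNDLE_COLUMNS = (
    "allele_frequency", "consequence", "de_novo", "segregates_in_family",
    "functional_study", "in_silico_verdict", "hotspot_or_domain",
    "observed_healthy_recessive", "manual_codes",
)
_TRUE = {"1", "true", "yes"}


class MalformedRowError(ValueError):
    """A cohort row that cannot be interpreted."""


def _parse_bool(value: str) -> bool:
    return str(value).strip().lower() in _TRUE


def _as_tuple(value) -> tuple:
    if value is None:
        return ()
    if isinstance(value, (tuple, list)):
        return tuple(value)
    return (value,)


def _bundle_from_row(row: dict) -> AnnotationBundle:
    af = row.get("allele_frequency", "")
    manual = row.get("manual_codes", "")
    return AnnotationBundle(
        allele_frequency=float(af) if str(af).strip() else None,
        consequence=row.get("consequence", "").strip() or "other",
        de_novo=row.get("de_novo", "").strip() or "unknown",
        segregates_in_family=row.get("segregates_in_family", "").strip() or "unknown",
        functional_study=row.get("functional_study", "").strip() or "none",
        in_silico_verdict=row.get("in_silico_verdict", "").strip() or "none",
        hotspot_or_domain=_parse_bool(row.get("hotspot_or_domain", "")),
        observed_healthy_recessive=_parse_bool(
            row.get("observed_healthy_recessive", "")),
        manual_codes=frozenset(
            c.strip() for c in str(manual).split(",") if c.strip()),
    )


def read_annotated_tsv(
    path: str | Path,
    on_error: str = "raise",
) -> tuple[list[VariantRecord], dict[str, GeneRuleConfig], int]:
    """Read an annotated cohort TSV.

    Returns ``(records, gene_configs, n_skipped)``.  ``on_error='skip'``
    logs and counts malformed rows instead of raising; gene configs are
    collected from the optional per-gene columns (a gene is flagged if any
    of its rows flags it).
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return [], {}, 0
    records: list[VariantRecord] = []
    gene_configs: dict[str, GeneRuleConfig] = {}
    skipped = 0
    for i, row in enumerate(df.to_dict("records"), start=2):  # 1-based + header
        try:
            gene = row.get("gene", "").strip()
            bundle = _bundle_from_row(row)
            records.append(_make_record(row, i, bundle))
            if gene:
                prev = gene_configs.get(gene, GeneRuleConfig(gene=gene))
                gene_configs[gene] = GeneRuleConfig(
                    gene=gene,
                    lof_mechanism=prev.lof_mechanism
                    or _parse_bool(row.get("lof_mechanism", "")),
                    missense_constrained=prev.missense_constrained
                    or _parse_bool(row.get("missense_constrained", "")),
                )
        except (ValueError, KeyError) as exc:
            if on_error == "raise":
                raise MalformedRowError(f"line {i}: {exc}") from exc
            skipped += 1
            log.warning("skipping malformed row at line %d: %s", i, exc)
    return records, gene_configs, skipped


def _make_record(row: dict, line_no: int, bundle: AnnotationBundle) -> VariantRecord:
    chrom = row.get("chrom", "").strip() or None
    vclass = row.get("variant_class", "").strip()
    if not vclass:
        vclass = "snv" if chrom else "other"
    return VariantRecord(
        record_id=row.get("record_id", "").strip() or f"row{line_no}",
        gene=row.get("gene", "").strip(),
        chrom=chrom,
        pos=int(row["pos"]) if row.get("pos", "").strip() else None,
        ref=row.get("ref", "").strip() or None,
        alt=row.get("alt", "").strip() or None,
        variant_class=vclass,
        annotations=bundle,
    )


def write_annotated_tsv(
    records: Sequence[VariantRecord],
    path: str | Path,
    gene_configs: dict[str, GeneRuleConfig] | None = None,
) -> None:
    """Write records (with bundles) in the annotated-cohort TSV dialect."""
    gene_configs = gene_configs or {}
    rows = []
    for r in records:
        ann = r.annotations or AnnotationBundle()
        cfg = gene_configs.get(r.gene, GeneRuleConfig(gene=r.gene))
        rows.append({
            "record_id": r.record_id,
            "gene": r.gene,
            "chrom": r.chrom or "",
            "pos": "" if r.pos is None else str(r.pos),
            "ref": r.ref or "",
            "alt": r.alt or "",
            "variant_class": r.variant_class,
            "allele_frequency": ""
            if ann.allele_frequency is None else repr(ann.allele_frequency),
            "consequence": ann.consequence,
            "de_novo": ann.de_novo,
            "segregates_in_family": ann.segregates_in_family,
            "functional_study": ann.functional_study,
            "in_silico_verdict": ann.in_silico_verdict,
            "hotspot_or_domain": str(ann.hotspot_or_domain).lower(),
            "observed_healthy_recessive":
                str(ann.observed_healthy_recessive).lower(),
            "manual_codes": ",".join(sorted(ann.manual_codes)),
            "lof_mechanism": str(cfg.lof_mechanism).lower(),
            "missense_constrained": str(cfg.missense_constrained).lower(),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_annotated_vcf(
    path: str | Path,
) -> tuple[list[VariantRecord], dict[str, GeneRuleConfig], int]:
    """Read a minimal annotated VCF (INFO-key dialect, see module docs)."""
    records: list[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf, start=1):
            info = dict(rec.info)
            try:
                af = info.get("AF")
                if isinstance(af, tuple):
                    af = af[0]
                bundle = AnnotationBundle(
                    allele_frequency=None if af is None else float(af),
                    consequence=str(info.get("CSQ_CLASS", "other")),
                    de_novo=str(info.get("DENOVO", "unknown")),
                    segregates_in_family=str(info.get("SEGREGATION", "unknown")),
                    functional_study=str(info.get("FUNC", "none")),
                    in_silico_verdict=str(info.get("INSILICO", "none")),
                    manual_codes=frozenset(
                        str(c) for c in _as_tuple(info.get("MANUAL"))),
                )
                alt = rec.alts[0] if rec.alts else None
                records.append(VariantRecord(
                    record_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    gene=str(info.get("GENE", "")),
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=rec.ref,
                    alt=alt,
                    variant_class="snv"
                    if alt and len(rec.ref) == 1 and len(alt) == 1 else "frameshift",
                    annotations=bundle,
                ))
            except ValueError as exc:
                skipped += 1
                log.warning("skipping VCF record %d (%s:%s): %s",
                            i, rec.chrom, rec.pos, exc)
    return records, {}, skipped
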
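"""Delimited annotation and classification file ingestion.

Annotation files come from arbitrary external pipelines (the store never
computes annotations itself); an
:class:`~varledger.specs.AnnotationDialectSpec` describes how to locate
the variant key columns and which columns become which attributes.
Sharing attribute names across annotation dialects is deliberate: it is
the mechanism by which successive pipelines update the same attribute and
its history.

Pathogenicity classification uses the IARC five-tier system (C1 Benign
... C5 Pathogenic) and is stored under the reserved attribute name
``classification`` with the same history semantics as any annotation, so
reclassifications are queryable.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Optional

from .ledger import IngestReport, StoreError, VariantKey, VariantStore, utc_now
from .specs import AnnotationDialectSpec, evaluate_row_filter

log = logging.getLogger(__name__)

CLASSIFICATION_ATTR = "classification"


class AnnotationIngestError(ValueError):
    """Missing key columns or a file/dialect mismatch."""


@dataclass(frozen=True)
class ClassificationTier:
    """One tier of the IARC five-tier pathogenicity classification."""

    code: str
    label: str


#: Bijection between tier codes and labels, ordered C1..C5.
TIERS: tuple[ClassificationTier, ...] = (
    ClassificationTier("C1", "Benign"),
    ClassificationTier("C2", "Likely Benign"),
    ClassificationTier("C3", "Uncertain Significance"),
    ClassificationTier("C4", "Likely Pathogenic"),
    ClassificationTier("C5", "Pathogenic"),
)
TIER_BY_CODE = {t.code: t for t in TIERS}
TIER_BY_LABEL = {t.label: t for t in TIERS}


def _parse_key(row: dict[str, str], key_columns: tuple[str, ...]) -> VariantKey:
    if len(key_columns) == 1:
        return VariantKey.from_string(row[key_columns[0]])
    chrom_c, pos_c, ref_c, alt_c = key_columns
    return VariantKey(row[chrom_c], int(row[pos_c]), row[ref_c], row[alt_c])


def ingest_annotation(
    store: VariantStore,
    path: str,
    dialect: AnnotationDialectSpec,
    create_missing: bool = False,
    source: Optional[str] = None,
    imported_at: Optional[str] = None,
) -> IngestReport:
    """Load one annotation file; every mapped, non-empty cell becomes a write.

    Rows are processed in order; processing stops *before* the first row
    matching the dialect's break condition, then the row filter applies.
    A row keying a variant absent from the store is skipped (and tallied)
    unless ``create_missing`` is set. Empty cells are never written, so no
    history entry ever holds the empty string.
    """
    source = source if source is not None else str(path)
    imported_at = imported_at if imported_at is not None else utc_now()
    report = IngestReport(source=source)

    with open(path, newline="") as fh, store.transaction():
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        rows = list(reader)
        if len(rows) <= dialect.header_rows:
            raise AnnotationIngestError(f"{path}: no header line after {dialect.header_rows} skipped rows")
        header = rows[dialect.header_rows]
        missing = [c for c in dialect.key_columns if c not in header]
        if missing:
            raise AnnotationIngestError(f"{path}: missing key column(s) {missing}")
        for raw in rows[dialect.header_rows + 1 :]:
            row = dict(zip(header, raw))
            if dialect.break_condition is not None and dialect.break_condition.matches(row):
                report.rows_stopped_by_break += 1
                break
            report.rows_read += 1
            if evaluate_row_filter(dialect.row_filter, row):
                report.rows_dropped_by_row_filter += 1
                continue
            try:
                key = _parse_key(row, dialect.key_columns)
            except (StoreError, ValueError, KeyError):
                report.rows_skipped_unparseable += 1
                report.warn("unparseable_key")
                continue
            if store.variant_id(key) is None:
                if not create_missing:
                    report.rows_skipped_missing_variant += 1
                    report.warn("variant_not_in_store")
                    continue
                store.upsert_variant(key)
                report.variants_created += 1
            else:
                report.variants_matched_existing += 1
            report.rows_loaded += 1
            report.records_stored += 1
            for column, attr in dialect.attr_map:
                value = row.get(column)
                if value is None:
                    report.warn(f"column_absent:{column}")
                    continue
                if not value.strip():
                    continue
                outcome = store.record_attribute(key, attr, value, source, imported_at)
                report.count_attribute_outcome(outcome)
    return report


def ingest_classification(
    store: VariantStore,
    path: str,
    create_missing: bool = False,
    source: Optional[str] = None,
    imported_at: Optional[str] = None,
) -> IngestReport:
    """Batch-load tier assignments from a 5-column TSV (chrom pos ref alt tier).

    A leading header row (detected by a non-integer position column) is
    skipped. Tier codes outside C1..C5 reject the row, which is counted in
    the report; valid rows write the reserved ``classification`` attribute
    with full history semantics, so re-uploading an identical tier is a
    history no-op.
    """
    source = source if source is not None else str(path)
    imported_at = imported_at if imported_at is not None else utc_now()
    report = IngestReport(source=source)

    with open(path, newline="") as fh, store.transaction():
        for i, raw in enumerate(csv.reader(fh, delimiter="\t")):
            if not raw or (len(raw) == 1 and not raw[0].strip()):
                continue
            if len(raw) < 5:
                report.rows_skipped_unparseable += 1
                report.warn("short_row")
                continue
            chrom, pos_s, ref, alt, tier = (c.strip() for c in raw[:5])
            if i == 0 and not pos_s.isdigit():
                continue  # header row
            report.rows_read += 1
            if tier not in TIER_BY_CODE:
                report.rows_rejected_bad_tier += 1
                report.warn(f"unknown_tier:{tier}")
                continue
            try:
                key = VariantKey(chrom, int(pos_s), ref, alt)
            except (StoreError, ValueError):
                report.rows_skipped_unparseable += 1
                report.warn("unparseable_key")
                continue
            if store.variant_id(key) is None:
                if not create_missing:
                    report.rows_skipped_missing_variant += 1
                    report.warn("variant_not_in_store")
                    continue
                store.upsert_variant(key)
                report.variants_created += 1
            else:
                report.variants_matched_existing += 1
            report.rows_loaded += 1
            outcome = store.record_attribute(key, CLASSIFICATION_ATTR, tier, source, imported_at)
            report.count_attribute_outcome(outcome)
    return report


def classify(
    store: VariantStore,
    key: VariantKey,
    tier: str,
    source: str = "manual",
    imported_at: Optional[str] = None,
) -> str:
    """Directly set one variant's tier (the CLI equivalent of an interactive
    classification); returns the history outcome."""
    if tier not in TIER_BY_CODE:
        raise AnnotationIngestError(
            f"unknown tier {tier!r}; expected one of {sorted(TIER_BY_CODE)}"
        )
    return store.record_attribute(
        key, CLASSIFICATION_ATTR, tier, source, imported_at if imported_at else utc_now()
    )
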
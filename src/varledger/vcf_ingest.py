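"""Dialect-driven VCF ingestion.

Reads a single-sample VCF (plain or gzip text) under a
:class:`~varledger.specs.VcfDialectSpec`, applies the dialect's row filter
and an optional virtual-panel consent filter, splits multiallelic records
one-alt-per-record, and loads variants, variant attributes and per-sample
observations into the ledger with full history semantics. The returned
:class:`~varledger.ledger.IngestReport` accounts for every input row.

The parser is intentionally small and line-based: the point of the module
is the configurable FORMAT/INFO subfield mapping, not VCF feature
coverage. QUAL and FILTER are ignored; symbolic alts and breakends are
skipped with a warning; phased genotype separators are normalized to ``/``
before filter comparison so ``0|0`` is excluded by a ``0/0`` filter.
"""

from __future__ import annotations

import gzip
import logging
from typing import Optional, TextIO

from .ledger import IngestReport, StoreError, VariantKey, VariantStore, utc_now
from .panels import GenePanel, VirtualPanel, passes_virtual_panel
from .specs import VcfDialectSpec, evaluate_derived, evaluate_row_filter

log = logging.getLogger(__name__)


class VcfIngestError(ValueError):
    """Malformed VCF or dialect/file mismatch that prevents ingestion."""


def _open_text(path: str) -> TextIO:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def parse_info_subfield(info_column: str, key: str) -> Optional[str]:
    """Value of ``key`` in a semicolon-delimited INFO column, or None.

    Flags (keys without ``=``) return the empty-string sentinel.
    """
    if info_column in (".", ""):
        return None
    for token in info_column.split(";"):
        if not token:
            continue
        name, eq, value = token.partition("=")
        if name == key:
            return value if eq else ""
    return None


def parse_info(info_column: str) -> dict[str, str]:
    """Whole INFO column as a mapping; flags map to empty string."""
    out: dict[str, str] = {}
    if info_column in (".", ""):
        return out
    for token in info_column.split(";"):
        if not token:
            continue
        name, eq, value = token.partition("=")
        out[name] = value if eq else ""
    return out


def split_dbxref(value: str) -> dict[str, str]:
    """Split a comma-delimited ``source:token`` cross-reference list.

    Each pair becomes one attribute named ``dbxref_<source>``; tokens
    without a colon are stored whole under ``dbxref_raw``.
    """
    out: dict[str, str] = {}
    if not value or not value.strip():
        return out
    raw_tokens = []
    for token in value.split(","):
        token = token.strip()
        if not token:
            continue
        source, colon, rest = token.partition(":")
        if colon and source:
            out[f"dbxref_{source}"] = rest
        else:
            raw_tokens.append(token)
    if raw_tokens:
        out["dbxref_raw"] = ",".join(raw_tokens)
    return out


_SYMBOLIC_CHARS = ("<", "[", "]")


def _is_symbolic(alt: str) -> bool:
    return alt == "*" or alt == "." or any(c in alt for c in _SYMBOLIC_CHARS)


def _split_format_value(raw: str, alt_index: int, n_alts: int) -> str:
    """Select the per-alt slice of a comma-listed FORMAT value.

    Length ``n_alts`` lists (one value per alt, e.g. AF) keep element
    ``alt_index``; length ``n_alts + 1`` lists (ref + one per alt, e.g.
    AD) keep the ref element plus element ``alt_index + 1``. Anything
    else passes through unchanged.
    """
    if n_alts <= 1 or "," not in raw:
        return raw
    parts = raw.split(",")
    if len(parts) == n_alts:
        return parts[alt_index]
    if len(parts) == n_alts + 1:
        return f"{parts[0]},{parts[alt_index + 1]}"
    return raw


def ingest_vcf(
    store: VariantStore,
    path: str,
    dialect: VcfDialectSpec,
    sample_id: str,
    panel: Optional[GenePanel] = None,
    virtual_panel: Optional[VirtualPanel] = None,
    source: Optional[str] = None,
    imported_at: Optional[str] = None,
) -> IngestReport:
    """Load one single-sample VCF into the store; returns the ingest report.

    Raises :class:`VcfIngestError` on a missing ``#CHROM`` header line, a
    multi-sample file, or a virtual panel requested with a dialect that
    has no ``gene_symbol_source``. Dialect subfields absent from a record
    produce per-record warnings (aggregated in the report) and attribute
    omission, never an exception.
    """
    if virtual_panel is not None and not dialect.gene_symbol_source:
        raise VcfIngestError(
            f"virtual panel {virtual_panel.name!r} requested but dialect "
            f"{dialect.name!r} has no gene_symbol_source"
        )
    if virtual_panel is not None and panel is not None and virtual_panel.parent != panel.name:
        raise VcfIngestError(
            f"virtual panel {virtual_panel.name!r} belongs to panel "
            f"{virtual_panel.parent!r}, not {panel.name!r}"
        )
    source = source if source is not None else str(path)
    imported_at = imported_at if imported_at is not None else utc_now()
    report = IngestReport(source=source)

    with _open_text(path) as fh, store.transaction():
        header_seen = False
        n_columns = 0
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                n_columns = len(cols)
                if n_columns > 10:
                    raise VcfIngestError(
                        f"{path}: multi-sample VCF ({n_columns - 9} samples); "
                        "only single-sample files are supported"
                    )
                header_seen = True
                continue
            if not header_seen:
                raise VcfIngestError(f"{path}: data line {lineno} before #CHROM header line")
            _ingest_data_line(
                store, line, lineno, path, dialect, sample_id, virtual_panel,
                source, imported_at, report,
            )
        if not header_seen:
            raise VcfIngestError(f"{path}: malformed VCF, no #CHROM header line")
    for kind, count in report.warnings.items():
        log.info("%s: %d records with warning '%s'", path, count, kind)
    return report


def _ingest_data_line(
    store, line, lineno, path, dialect, sample_id, virtual_panel, source, imported_at, report
):
    fields = line.split("\t")
    if len(fields) < 8:
        raise VcfIngestError(f"{path}: line {lineno} has {len(fields)} columns, expected >= 8")
    report.rows_read += 1
    chrom, pos_s, _id, ref, alt_s, _qual, _filter, info_s = fields[:8]
    info = parse_info(info_s)

    fmt: dict[str, str] = {}
    if len(fields) >= 10:
        keys = fields[8].split(":")
        values = fields[9].split(":")
        fmt = dict(zip(keys, values))
        if "GT" in fmt:
            fmt["GT"] = fmt["GT"].replace("|", "/")

    # row filter sees FORMAT subfields first, then INFO subfields
    record_view = {**info, **fmt}
    if evaluate_row_filter(dialect.row_filter, record_view):
        report.rows_dropped_by_row_filter += 1
        return

    if virtual_panel is not None:
        symbol = info.get(dialect.gene_symbol_source)
        if not passes_virtual_panel(symbol, virtual_panel):
            report.rows_dropped_by_virtual_panel += 1
            return

    report.rows_loaded += 1
    alts = alt_s.split(",")
    n_alts = len(alts)
    try:
        pos = int(pos_s)
    except ValueError:
        raise VcfIngestError(f"{path}: line {lineno} has unparseable POS {pos_s!r}")

    for alt_index, alt in enumerate(alts):
        if _is_symbolic(alt):
            report.alt_records_skipped += 1
            report.warn("symbolic_alt_skipped")
            continue
        try:
            key = VariantKey(chrom, pos, ref, alt)
        except StoreError:
            report.alt_records_skipped += 1
            report.warn("invalid_allele_skipped")
            continue
        _, created = store.upsert_variant(key)
        report.records_stored += 1
        if created:
            report.variants_created += 1
        else:
            report.variants_matched_existing += 1

        for info_key, attr in dialect.variant_attr_map:
            value = info.get(info_key)
            if value is None:
                report.warn(f"info_subfield_absent:{info_key}")
                continue
            if attr == "dbxref":
                for sub_attr, sub_value in split_dbxref(value).items():
                    outcome = store.record_attribute(key, sub_attr, sub_value, source, imported_at)
                    report.count_attribute_outcome(outcome)
                continue
            if not value.strip():
                continue
            outcome = store.record_attribute(key, attr, value, source, imported_at)
            report.count_attribute_outcome(outcome)

        record_fmt = {
            k: _split_format_value(v, alt_index, n_alts) for k, v in fmt.items()
        }
        for fmt_key, attr in dialect.sample_attr_map:
            value = record_fmt.get(fmt_key)
            if value is None:
                report.warn(f"format_subfield_absent:{fmt_key}")
                continue
            if not value.strip() or value == ".":
                continue
            store.record_sample_attribute(sample_id, key, attr, value, source, imported_at)
            report.sample_attributes_written += 1
        for expr in dialect.derived_attrs:
            derived = evaluate_derived(expr, record_fmt)
            if derived is None:
                report.warn(f"derived_undefined:{expr.target_attr}")
                continue
            store.record_sample_attribute(
                sample_id, key, expr.target_attr, repr(derived), source, imported_at
            )
            report.sample_attributes_written += 1
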
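"""Declarative input-file dialect definitions.

Clinical laboratories receive VCFs and annotation tables from many callers
and pipelines, each with its own FORMAT/INFO subfields and column layouts.
A *dialect spec* describes, as data, how one such file type maps onto the
store's attributes: which subfields or columns become which attributes,
which rows to skip (row filters), when to stop reading (break conditions),
and how to derive attributes that the file does not carry directly (e.g.
an allele-frequency percent computed as AD/DP x 100 for callers that
report depths but no AF subfield).

Specs are plain dataclasses, validated on construction, and round-trip
losslessly through dict/YAML/JSON configs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import yaml

log = logging.getLogger(__name__)

_FILTER_OPERATORS = ("equals", "not-equals", "in-set", "not-in-set")
_FILTER_ACTIONS = ("exclude", "include-only")


class DialectError(ValueError):
    """Invalid dialect configuration; the message names the offending field."""


@dataclass(frozen=True)
class RowFilter:
    """Single-field row predicate applied during ingestion.

    ``action="exclude"`` drops matching rows; ``action="include-only"``
    keeps only matching rows. A filter never matches a row in which its
    field is absent, so rows lacking the field survive an exclude filter
    and are dropped by an include-only filter.
    """

    field: str
    operator: str
    values: tuple[str, ...]
    action: str = "exclude"

    def __post_init__(self) -> None:
        if not self.field:
            raise DialectError("row filter: 'field' must be non-empty")
        if self.operator not in _FILTER_OPERATORS:
            raise DialectError(
                f"row filter: operator {self.operator!r} not one of {_FILTER_OPERATORS}"
            )
        if self.action not in _FILTER_ACTIONS:
            raise DialectError(f"row filter: action {self.action!r} not one of {_FILTER_ACTIONS}")
        if self.operator in ("equals", "not-equals") and len(self.values) != 1:
            raise DialectError(f"row filter: operator {self.operator!r} takes exactly one value")
        if not self.values:
            raise DialectError("row filter: 'values' must be non-empty")

    def matches(self, record: Mapping[str, str]) -> bool:
        """Whether the filter's predicate holds; absent field never matches."""
        if self.field not in record:
            return False
        value = record[self.field]
        if self.operator == "equals":
            return value == self.values[0]
        if self.operator == "not-equals":
            return value != self.values[0]
        if self.operator == "in-set":
            return value in self.values
        return value not in self.values

    def drops(self, record: Mapping[str, str]) -> bool:
        """True when the record must be dropped under this filter's action."""
        matched = self.matches(record)
        return matched if self.action == "exclude" else not matched

    def to_dict(self) -> dict:
        return {
            "field": self.field,
            "operator": self.operator,
            "values": list(self.values),
            "action": self.action,
        }

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "RowFilter":
        values = cfg.get("values", cfg.get("value"))
        if values is None:
            raise DialectError("row filter: missing 'value'/'values'")
        if isinstance(values, str):
            values = [values]
        return cls(
            field=cfg.get("field", ""),
            operator=cfg.get("operator", "equals"),
            values=tuple(str(v) for v in values),
            action=cfg.get("action", "exclude"),
        )


def evaluate_row_filter(flt: Optional[RowFilter], record: Mapping[str, str]) -> bool:
    """Pure, total predicate: True iff the record is dropped. No filter keeps all."""
    if flt is None:
        return False
    return flt.drops(record)


@dataclass(frozen=True)
class DerivedExpr:
    """A sample attribute computed as ``scale * numerator / denominator``.

    The canonical use is an allele-frequency percent from allele depth and
    read depth (AD/DP x 100). Evaluation is undefined — the attribute is
    omitted, with a warning — when the denominator is zero or either field
    is absent.
    """

    target_attr: str
    numerator_field: str
    denominator_field: str
    scale: float = 100.0

    def to_dict(self) -> dict:
        return {
            "target_attr": self.target_attr,
            "numerator_field": self.numerator_field,
            "denominator_field": self.denominator_field,
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "DerivedExpr":
        try:
            return cls(
                target_attr=cfg["target_attr"],
                numerator_field=cfg["numerator_field"],
                denominator_field=cfg["denominator_field"],
                scale=float(cfg.get("scale", 100.0)),
            )
        except KeyError as exc:
            raise DialectError(f"derived expression: missing field {exc.args[0]!r}") from None


def _first_alt_component(raw: str) -> float:
    """Numeric value of a FORMAT field; comma lists use index 1 (the first alt).

    After multiallelic splitting each record carries one alt allele, so a
    per-allele list such as AD is ``ref_depth,alt_depth``.
    """
    parts = raw.split(",")
    token = parts[1] if len(parts) > 1 else parts[0]
    return float(token)


def evaluate_derived(expr: DerivedExpr, record: Mapping[str, str]) -> Optional[float]:
    """Evaluate on parsed FORMAT fields; None (with a warning) when undefined."""
    num_raw = record.get(expr.numerator_field)
    den_raw = record.get(expr.denominator_field)
    if num_raw is None or den_raw is None:
        log.warning(
            "derived attribute %s omitted: field %s absent",
            expr.target_attr,
            expr.numerator_field if num_raw is None else expr.denominator_field,
        )
        return None
    try:
        num = _first_alt_component(num_raw)
        den = float(den_raw.split(",")[0])
    except (ValueError, IndexError):
        log.warning("derived attribute %s omitted: unparseable operands", expr.target_attr)
        return None
    if den == 0:
        log.warning("derived attribute %s omitted: zero denominator", expr.target_attr)
        return None
    return expr.scale * num / den


@dataclass(frozen=True)
class VcfDialectSpec:
    """How to read one VCF flavor into the store.

    ``sample_attr_map`` maps FORMAT subfields to per-sample attributes,
    ``variant_attr_map`` maps INFO subfields to variant attributes, and
    ``derived_attrs`` add computed sample attributes. A dialect flagged
    ``virtual_panel_compatible`` must name the INFO subfield that carries
    the gene symbol (``gene_symbol_source``) so consent filtering can
    resolve each record's gene.
    """

    name: str
    vcf_version: str = "4.2"
    sample_attr_map: tuple[tuple[str, str], ...] = ()
    variant_attr_map: tuple[tuple[str, str], ...] = ()
    derived_attrs: tuple[DerivedExpr, ...] = ()
    row_filter: Optional[RowFilter] = None
    gene_symbol_source: Optional[str] = None
    virtual_panel_compatible: bool = False
    format_subfields: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise DialectError("vcf dialect: 'name' must be non-empty")
        if not self.sample_attr_map and not self.variant_attr_map and not self.derived_attrs:
            raise DialectError(
                f"vcf dialect {self.name!r}: at least one of sample_attr_map/"
                "variant_attr_map must be non-empty"
            )
        attrs = (
            [a for _, a in self.sample_attr_map]
            + [a for _, a in self.variant_attr_map]
            + [d.target_attr for d in self.derived_attrs]
        )
        dupes = {a for a in attrs if attrs.count(a) > 1}
        if dupes:
            raise DialectError(
                f"vcf dialect {self.name!r}: duplicate attribute names {sorted(dupes)}"
            )
        declared = {k for k, _ in self.sample_attr_map} | set(self.format_subfields)
        for d in self.derived_attrs:
            for fld in (d.numerator_field, d.denominator_field):
                if fld not in declared:
                    raise DialectError(
                        f"vcf dialect {self.name!r}: derived attribute {d.target_attr!r} "
                        f"references FORMAT subfield {fld!r} not declared in the dialect"
                    )
        if self.virtual_panel_compatible and not self.gene_symbol_source:
            raise DialectError(
                f"vcf dialect {self.name!r}: virtual_panel_compatible requires "
                "gene_symbol_source"
            )

    def to_dict(self) -> dict:
        out: dict = {
            "name": self.name,
            "vcf_version": self.vcf_version,
            "sample_attr_map": [list(p) for p in self.sample_attr_map],
            "variant_attr_map": [list(p) for p in self.variant_attr_map],
            "derived_attrs": [d.to_dict() for d in self.derived_attrs],
            "virtual_panel_compatible": self.virtual_panel_compatible,
        }
        if self.row_filter is not None:
            out["row_filter"] = self.row_filter.to_dict()
        if self.gene_symbol_source is not None:
            out["gene_symbol_source"] = self.gene_symbol_source
        if self.format_subfields:
            out["format_subfields"] = list(self.format_subfields)
        return out


def _pairs(cfg, key, dialect_name) -> tuple[tuple[str, str], ...]:
    raw = cfg.get(key) or []
    pairs = []
    for item in raw:
        if isinstance(item, Mapping):
            if len(item) != 1:
                raise DialectError(f"dialect {dialect_name!r}: {key} entries map one field")
            ((k, v),) = item.items()
        else:
            k, v = item
        pairs.append((str(k), str(v)))
    return tuple(pairs)


def define_vcf_dialect(config: Mapping) -> VcfDialectSpec:
    """Validate a structured config into a :class:`VcfDialectSpec`.

    Invalid configs raise :class:`DialectError` naming the offending field.
    """
    name = config.get("name", "")
    return VcfDialectSpec(
        name=name,
        vcf_version=str(config.get("vcf_version", "4.2")),
        sample_attr_map=_pairs(config, "sample_attr_map", name),
        variant_attr_map=_pairs(config, "variant_attr_map", name),
        derived_attrs=tuple(
            DerivedExpr.from_dict(d) for d in config.get("derived_attrs") or []
        ),
        row_filter=(
            RowFilter.from_dict(config["row_filter"]) if config.get("row_filter") else None
        ),
        gene_symbol_source=config.get("gene_symbol_source"),
        virtual_panel_compatible=bool(config.get("virtual_panel_compatible", False)),
        format_subfields=tuple(config.get("format_subfields") or ()),
    )


@dataclass(frozen=True)
class AnnotationDialectSpec:
    """How to read one delimited annotation/classification file type.

    ``key_columns`` resolve the variant identity: either the four column
    names for chrom/pos/ref/alt, or a single column holding the pipe form
    ``chrom|pos|ref|alt``. ``header_rows`` leading rows are skipped before
    the column-name header line. Processing stops at the first row matching
    ``break_condition``.
    """

    name: str
    delimiter: str = "\t"
    key_columns: tuple[str, ...] = ()
    attr_map: tuple[tuple[str, str], ...] = ()
    row_filter: Optional[RowFilter] = None
    break_condition: Optional[RowFilter] = None
    header_rows: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise DialectError("annotation dialect: 'name' must be non-empty")
        if self.delimiter not in ("\t", ","):
            raise DialectError(
                f"annotation dialect {self.name!r}: delimiter must be tab or comma"
            )
        if len(self.key_columns) not in (1, 4):
            raise DialectError(
                f"annotation dialect {self.name!r}: key_columns must name either the "
                "four chrom/pos/ref/alt columns or one pipe-form key column"
            )
        cols = [c for c, _ in self.attr_map]
        if len(set(cols)) != len(cols):
            raise DialectError(f"annotation dialect {self.name!r}: duplicate source columns")
        attrs = [a for _, a in self.attr_map]
        if len(set(attrs)) != len(attrs):
            raise DialectError(f"annotation dialect {self.name!r}: duplicate attribute names")
        if self.header_rows < 0:
            raise DialectError(f"annotation dialect {self.name!r}: header_rows must be >= 0")

    def to_dict(self) -> dict:
        out: dict = {
            "name": self.name,
            "delimiter": "tab" if self.delimiter == "\t" else "comma",
            "key_columns": list(self.key_columns),
            "attr_map": [list(p) for p in self.attr_map],
            "header_rows": self.header_rows,
        }
        if self.row_filter is not None:
            out["row_filter"] = self.row_filter.to_dict()
        if self.break_condition is not None:
            out["break_condition"] = self.break_condition.to_dict()
        return out


def define_annotation_dialect(config: Mapping) -> AnnotationDialectSpec:
    """Validate a structured config into an :class:`AnnotationDialectSpec`."""
    name = config.get("name", "")
    delim = config.get("delimiter", "tab")
    delim = {"tab": "\t", "\t": "\t", "comma": ",", ",": ","}.get(delim, delim)
    return AnnotationDialectSpec(
        name=name,
        delimiter=delim,
        key_columns=tuple(config.get("key_columns") or ()),
        attr_map=_pairs(config, "attr_map", name),
        row_filter=(
            RowFilter.from_dict(config["row_filter"]) if config.get("row_filter") else None
        ),
        break_condition=(
            RowFilter.from_dict(config["break_condition"])
            if config.get("break_condition")
            else None
        ),
        header_rows=int(config.get("header_rows", 0)),
    )


def define_dialect(config: Mapping):
    """Dispatch on ``kind: vcf|annotation`` (default vcf)."""
    kind = config.get("kind", "vcf")
    if kind == "vcf":
        return define_vcf_dialect(config)
    if kind == "annotation":
        return define_annotation_dialect(config)
    raise DialectError(f"dialect kind must be 'vcf' or 'annotation', got {kind!r}")


def load_dialect_config(path: str) -> dict:
    """Read a dialect config from a YAML (or JSON — YAML superset) file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise DialectError(f"dialect config {path!r} does not contain a mapping")
    return dict(cfg)


def dump_dialect_config(spec, path: str) -> None:
    cfg = spec.to_dict()
    cfg["kind"] = "annotation" if isinstance(spec, AnnotationDialectSpec) else "vcf"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
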
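"""Persistent variant store with full attribute-change history.

The store keeps three kinds of facts:

* unique variants, identified by :class:`VariantKey` (chrom, pos, ref, alt)
  after canonicalization — importing the same variant from any number of
  files yields a single record;
* variant attributes (annotations), each as an ordered history of values:
  re-importing an identical value refreshes the current entry's timestamp,
  while a differing value appends a new entry and preserves the old one;
* per-sample observations (genotype, allele-frequency percent, ...) under
  the same overwrite-if-identical / track-if-different rule.

The backing store is a single SQLite file (or ``:memory:``); each import
runs inside one transaction, so an import either fully applies or not at
all.
"""

from __future__ import annotations

import json
import re
import sqlite3
from contextlib import contextmanager
from dataclasses import dataclass, field, fields as dc_fields
from datetime import datetime, timezone
from typing import Iterator, Mapping, Optional

_ALLELE_RE = re.compile(r"^[ACGTN]+$")


class StoreError(Exception):
    """Invalid key, unknown variant, or store misuse."""


def canonical_chrom(chrom: str) -> str:
    """Normalize a chromosome label to the ``chr``-prefixed form.

    Bare names gain the ``chr`` prefix; an existing prefix (any case) is
    normalized to lowercase ``chr``. ``MT`` is folded to ``M`` and the
    sex/mito letters are uppercased, so ``13``, ``chr13`` and ``Chr13``
    collapse to ``chr13`` and ``mt``/``chrMT`` to ``chrM``.
    """
    body = chrom.strip()
    if body[:3].lower() == "chr":
        body = body[3:]
    if body.lower() in ("x", "y", "m", "mt"):
        body = "M" if body.lower() in ("m", "mt") else body.upper()
    return "chr" + body


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: chr1..chr22, chrX, chrY, chrM, then others."""
    body = chrom[3:] if chrom[:3].lower() == "chr" else chrom
    if body.isdigit():
        n = int(body)
        if 1 <= n <= 22:
            return (0, n, "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if body.upper() in special:
        return (0, special[body.upper()], "")
    return (1, 0, body)


@dataclass(frozen=True, order=True)
class VariantKey:
    """Normalized identity of a variant: 1-based VCF coordinates, one alt.

    Equality is component-wise after canonicalization; the canonical text
    form is ``chrom|pos|ref|alt``. No left-alignment or parsimony
    normalization is applied, so differently-represented indels are
    distinct records.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", canonical_chrom(self.chrom))
        object.__setattr__(self, "ref", self.ref.strip().upper())
        object.__setattr__(self, "alt", self.alt.strip().upper())
        if not isinstance(self.pos, int) or self.pos < 1:
            raise StoreError(f"variant position must be a positive integer, got {self.pos!r}")
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not _ALLELE_RE.match(allele):
                raise StoreError(f"{label} allele {allele!r} is not a non-empty A/C/G/T/N string")
        if self.ref == self.alt:
            raise StoreError(f"ref and alt are identical ({self.ref!r})")

    def __str__(self) -> str:
        return f"{self.chrom}|{self.pos}|{self.ref}|{self.alt}"

    @classmethod
    def from_string(cls, text: str) -> "VariantKey":
        """Parse the pipe form ``chrom|pos|ref|alt``."""
        parts = text.strip().split("|")
        if len(parts) != 4:
            raise StoreError(f"expected chrom|pos|ref|alt, got {text!r}")
        chrom, pos, ref, alt = parts
        try:
            pos_i = int(pos)
        except ValueError:
            raise StoreError(f"unparseable position {pos!r} in {text!r}") from None
        return cls(chrom, pos_i, ref, alt)

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class HistoryEntry:
    """One value in an attribute's history, with provenance."""

    value: str
    imported_at: str
    source: str


@dataclass
class IngestReport:
    """Per-import tallies: every input row's fate is accounted for.

    ``rows_read = rows_dropped_by_row_filter + rows_dropped_by_virtual_panel
    + rows_loaded`` (multiallelic-split accounting is carried separately in
    ``records_stored`` / ``alt_records_skipped``).
    """

    source: str = ""
    rows_read: int = 0
    rows_dropped_by_row_filter: int = 0
    rows_dropped_by_virtual_panel: int = 0
    rows_loaded: int = 0
    rows_stopped_by_break: int = 0
    rows_skipped_unparseable: int = 0
    rows_skipped_missing_variant: int = 0
    rows_rejected_bad_tier: int = 0
    records_stored: int = 0
    alt_records_skipped: int = 0
    variants_created: int = 0
    variants_matched_existing: int = 0
    attributes_created: int = 0
    attributes_unchanged: int = 0
    attributes_updated: int = 0
    sample_attributes_written: int = 0
    warnings: dict = field(default_factory=dict)

    def warn(self, kind: str) -> None:
        self.warnings[kind] = self.warnings.get(kind, 0) + 1

    def count_attribute_outcome(self, outcome: str) -> None:
        if outcome == "created":
            self.attributes_created += 1
        elif outcome == "unchanged":
            self.attributes_unchanged += 1
        else:
            self.attributes_updated += 1

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=False)


def utc_now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


_SCHEMA = """
CREATE TABLE IF NOT EXISTS variants (
    id INTEGER PRIMARY KEY,
    chrom TEXT NOT NULL, pos INTEGER NOT NULL,
    ref TEXT NOT NULL, alt TEXT NOT NULL,
    UNIQUE (chrom, pos, ref, alt)
);
CREATE TABLE IF NOT EXISTS variant_attrs (
    id INTEGER PRIMARY KEY,
    variant_id INTEGER NOT NULL REFERENCES variants(id),
    name TEXT NOT NULL, seq INTEGER NOT NULL,
    value TEXT NOT NULL, imported_at TEXT NOT NULL, source TEXT NOT NULL,
    UNIQUE (variant_id, name, seq)
);
CREATE INDEX IF NOT EXISTS idx_vattr_name ON variant_attrs (name, variant_id, seq);
CREATE TABLE IF NOT EXISTS sample_attrs (
    id INTEGER PRIMARY KEY,
    sample_id TEXT NOT NULL,
    variant_id INTEGER NOT NULL REFERENCES variants(id),
    name TEXT NOT NULL, seq INTEGER NOT NULL,
    value TEXT NOT NULL, imported_at TEXT NOT NULL, source TEXT NOT NULL,
    UNIQUE (sample_id, variant_id, name, seq)
);
CREATE INDEX IF NOT EXISTS idx_sattr_variant ON sample_attrs (variant_id);
CREATE TABLE IF NOT EXISTS dialects (
    name TEXT PRIMARY KEY, kind TEXT NOT NULL, config TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS panels (
    name TEXT PRIMARY KEY, genes TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS virtual_panels (
    name TEXT PRIMARY KEY, parent TEXT NOT NULL REFERENCES panels(name),
    genes TEXT NOT NULL
);
"""


class VariantStore:
    """SQLite-backed store of variants, attribute histories and observations."""

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._conn = sqlite3.connect(path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "VariantStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @contextmanager
    def transaction(self):
        """All-or-nothing scope for an import."""
        try:
            yield self
            self._conn.commit()
        except BaseException:
            self._conn.rollback()
            raise

    # -- variants ----------------------------------------------------------

    def upsert_variant(self, key: VariantKey) -> tuple[int, bool]:
        """Insert the key if new; return ``(variant_id, created)``.

        Idempotent: a second call with an equal key returns the same id
        with ``created=False``.
        """
        cur = self._conn.execute(
            "SELECT id FROM variants WHERE chrom=? AND pos=? AND ref=? AND alt=?",
            (key.chrom, key.pos, key.ref, key.alt),
        )
        row = cur.fetchone()
        if row is not None:
            return row[0], False
        cur = self._conn.execute(
            "INSERT INTO variants (chrom, pos, ref, alt) VALUES (?,?,?,?)",
            (key.chrom, key.pos, key.ref, key.alt),
        )
        return cur.lastrowid, True

    def variant_id(self, key: VariantKey) -> Optional[int]:
        cur = self._conn.execute(
            "SELECT id FROM variants WHERE chrom=? AND pos=? AND ref=? AND alt=?",
            (key.chrom, key.pos, key.ref, key.alt),
        )
        row = cur.fetchone()
        return None if row is None else row[0]

    def _require_variant(self, key: VariantKey) -> int:
        vid = self.variant_id(key)
        if vid is None:
            raise StoreError(f"unknown variant {key}")
        return vid

    def unique_variant_count(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM variants").fetchone()[0]

    def iter_variants(self) -> Iterator[tuple[int, VariantKey]]:
        """All variants in canonical order (natural chrom, pos, ref, alt)."""
        rows = self._conn.execute("SELECT id, chrom, pos, ref, alt FROM variants").fetchall()
        keyed = [(vid, VariantKey(c, p, r, a)) for vid, c, p, r, a in rows]
        keyed.sort(key=lambda t: t[1].sort_key())
        return iter(keyed)

    # -- variant attributes ------------------------------------------------

    def record_attribute(
        self,
        key: VariantKey,
        name: str,
        value: str,
        source: str,
        imported_at: Optional[str] = None,
    ) -> str:
        """Write one attribute value; returns ``created|unchanged|updated``.

        Values are compared whitespace-trimmed and case-sensitively. An
        identical value refreshes the current entry's timestamp/source
        without growing the history; a differing value appends an entry.
        """
        vid = self._require_variant(key)
        return self._record(
            "variant_attrs", "variant_id=?", (vid,), (vid,), name, value, source, imported_at
        )

    def _record(self, table, scope_sql, scope, ins_prefix, name, value, source, imported_at) -> str:
        value = value.strip()
        if not value:
            raise StoreError(f"refusing to record empty value for attribute {name!r}")
        if imported_at is None:
            imported_at = utc_now()
        cur = self._conn.execute(
            f"SELECT id, seq, value FROM {table} WHERE {scope_sql} AND name=? "
            "ORDER BY seq DESC LIMIT 1",
            (*scope, name),
        )
        row = cur.fetchone()
        if row is None:
            self._conn.execute(
                f"INSERT INTO {table} ({'variant_id' if table == 'variant_attrs' else 'sample_id, variant_id'}, name, seq, value, imported_at, source) "
                f"VALUES ({','.join('?' * len(ins_prefix))},?,1,?,?,?)",
                (*ins_prefix, name, value, imported_at, source),
            )
            return "created"
        entry_id, seq, current = row
        if current == value:
            self._conn.execute(
                f"UPDATE {table} SET imported_at=?, source=? WHERE id=?",
                (imported_at, source, entry_id),
            )
            return "unchanged"
        self._conn.execute(
            f"INSERT INTO {table} ({'variant_id' if table == 'variant_attrs' else 'sample_id, variant_id'}, name, seq, value, imported_at, source) "
            f"VALUES ({','.join('?' * len(ins_prefix))},?,?,?,?,?)",
            (*ins_prefix, name, seq + 1, value, imported_at, source),
        )
        return "updated"

    def attribute_history(self, key: VariantKey, name: str) -> list[HistoryEntry]:
        """Ordered history (oldest first); empty if the attribute was never set."""
        vid = self._require_variant(key)
        rows = self._conn.execute(
            "SELECT value, imported_at, source FROM variant_attrs "
            "WHERE variant_id=? AND name=? ORDER BY seq",
            (vid, name),
        ).fetchall()
        return [HistoryEntry(*r) for r in rows]

    def current_attributes(self, key: VariantKey) -> dict[str, str]:
        """Current value of every attribute set on the variant."""
        vid = self._require_variant(key)
        rows = self._conn.execute(
            "SELECT name, value FROM variant_attrs a WHERE variant_id=? AND seq="
            "(SELECT MAX(seq) FROM variant_attrs b WHERE b.variant_id=a.variant_id AND b.name=a.name)",
            (vid,),
        ).fetchall()
        return dict(rows)

    def attribute_names(self, key: VariantKey) -> list[str]:
        vid = self._require_variant(key)
        rows = self._conn.execute(
            "SELECT DISTINCT name FROM variant_attrs WHERE variant_id=? ORDER BY name", (vid,)
        ).fetchall()
        return [r[0] for r in rows]

    def all_histories(self, name: str) -> dict[int, list[HistoryEntry]]:
        """variant_id -> ordered history, for one attribute name across the store."""
        rows = self._conn.execute(
            "SELECT variant_id, value, imported_at, source FROM variant_attrs "
            "WHERE name=? ORDER BY variant_id, seq",
            (name,),
        ).fetchall()
        out: dict[int, list[HistoryEntry]] = {}
        for vid, value, ts, src in rows:
            out.setdefault(vid, []).append(HistoryEntry(value, ts, src))
        return out

    def key_of(self, variant_id: int) -> VariantKey:
        row = self._conn.execute(
            "SELECT chrom, pos, ref, alt FROM variants WHERE id=?", (variant_id,)
        ).fetchone()
        if row is None:
            raise StoreError(f"unknown variant id {variant_id}")
        return VariantKey(*row)

    # -- sample observations ----------------------------------------------

    def record_sample_attribute(
        self,
        sample_id: str,
        key: VariantKey,
        name: str,
        value: str,
        source: str,
        imported_at: Optional[str] = None,
    ) -> str:
        """Same overwrite/track semantics as variant attributes, per sample."""
        vid = self._require_variant(key)
        return self._record(
            "sample_attrs",
            "sample_id=? AND variant_id=?",
            (sample_id, vid),
            (sample_id, vid),
            name,
            value,
            source,
            imported_at,
        )

    def sample_observations(self, sample_id: str, key: VariantKey) -> dict[str, str]:
        vid = self._require_variant(key)
        rows = self._conn.execute(
            "SELECT name, value FROM sample_attrs a WHERE sample_id=? AND variant_id=? AND seq="
            "(SELECT MAX(seq) FROM sample_attrs b WHERE b.sample_id=a.sample_id "
            " AND b.variant_id=a.variant_id AND b.name=a.name)",
            (sample_id, vid),
        ).fetchall()
        return dict(rows)

    def samples_with_variant(self, key: VariantKey) -> set[str]:
        """Every sample with at least one observation of the variant, once each."""
        vid = self.variant_id(key)
        if vid is None:
            return set()
        rows = self._conn.execute(
            "SELECT DISTINCT sample_id FROM sample_attrs WHERE variant_id=?", (vid,)
        ).fetchall()
        return {r[0] for r in rows}

    def sample_count(self) -> int:
        return self._conn.execute("SELECT COUNT(DISTINCT sample_id) FROM sample_attrs").fetchone()[0]

    # -- dialect / panel persistence --------------------------------------

    def save_dialect(self, name: str, kind: str, config: Mapping) -> None:
        self._conn.execute(
            "INSERT OR REPLACE INTO dialects (name, kind, config) VALUES (?,?,?)",
            (name, kind, json.dumps(dict(config), sort_keys=True)),
        )
        self._conn.commit()

    def load_dialect(self, name: str) -> tuple[str, dict]:
        row = self._conn.execute(
            "SELECT kind, config FROM dialects WHERE name=?", (name,)
        ).fetchone()
        if row is None:
            raise StoreError(f"no dialect named {name!r} is defined in the store")
        return row[0], json.loads(row[1])

    def list_dialects(self) -> list[tuple[str, str]]:
        return self._conn.execute("SELECT name, kind FROM dialects ORDER BY name").fetchall()

    def save_panel(self, name: str, genes: set[str]) -> None:
        if self._conn.execute("SELECT 1 FROM panels WHERE name=?", (name,)).fetchone():
            raise StoreError(f"panel {name!r} already exists")
        self._conn.execute(
            "INSERT INTO panels (name, genes) VALUES (?,?)",
            (name, json.dumps(sorted(genes))),
        )
        self._conn.commit()

    def load_panel(self, name: str) -> set[str]:
        row = self._conn.execute("SELECT genes FROM panels WHERE name=?", (name,)).fetchone()
        if row is None:
            raise StoreError(f"no panel named {name!r}")
        return set(json.loads(row[0]))

    def save_virtual_panel(self, name: str, parent: str, genes: set[str]) -> None:
        if self._conn.execute("SELECT 1 FROM virtual_panels WHERE name=?", (name,)).fetchone():
            raise StoreError(f"virtual panel {name!r} already exists")
        self._conn.execute(
            "INSERT INTO virtual_panels (name, parent, genes) VALUES (?,?,?)",
            (name, parent, json.dumps(sorted(genes))),
        )
        self._conn.commit()

    def load_virtual_panel(self, name: str) -> tuple[str, set[str]]:
        row = self._conn.execute(
            "SELECT parent, genes FROM virtual_panels WHERE name=?", (name,)
        ).fetchone()
        if row is None:
            raise StoreError(f"no virtual panel named {name!r}")
        return row[0], set(json.loads(row[1]))

    # -- audit -------------------------------------------------------------

    def check_history_wellformed(self) -> None:
        """Assert store-wide history invariants; raises StoreError on violation.

        No two consecutive entries of any history may hold the same value,
        and sequence numbers must be 1..n without gaps.
        """
        for table, scope_cols in (
            ("variant_attrs", ("variant_id",)),
            ("sample_attrs", ("sample_id", "variant_id")),
        ):
            cols = ", ".join(scope_cols)
            rows = self._conn.execute(
                f"SELECT {cols}, name, seq, value FROM {table} ORDER BY {cols}, name, seq"
            ).fetchall()
            prev_scope, prev_value, prev_seq = None, None, 0
            for row in rows:
                scope, seq, value = row[:-2], row[-2], row[-1]
                if scope != prev_scope:
                    prev_scope, prev_value, prev_seq = scope, None, 0
                if seq != prev_seq + 1:
                    raise StoreError(f"{table} history gap at {scope}: seq {seq} after {prev_seq}")
                if value == prev_value:
                    raise StoreError(f"{table} consecutive duplicate value at {scope}: {value!r}")
                if not value:
                    raise StoreError(f"{table} empty value at {scope}")
                prev_value, prev_seq = value, seq

    def snapshot(self) -> dict:
        """Full logical content, for round-trip and idempotence comparisons."""
        out = {}
        for table, order in (
            ("variants", "chrom, pos, ref, alt"),
            ("variant_attrs", "variant_id, name, seq"),
            ("sample_attrs", "sample_id, variant_id, name, seq"),
        ):
            cur = self._conn.execute(f"SELECT * FROM {table} ORDER BY {order}")
            out[table] = cur.fetchall()
        return out

    def stats(self) -> dict:
        return {
            "store": self.path,
            "unique_variants": self.unique_variant_count(),
            "samples": self.sample_count(),
            "attribute_entries": self._conn.execute(
                "SELECT COUNT(*) FROM variant_attrs"
            ).fetchone()[0],
            "sample_attribute_entries": self._conn.execute(
                "SELECT COUNT(*) FROM sample_attrs"
            ).fetchone()[0],
        }
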
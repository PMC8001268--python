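"""Search over current attribute values and attribute-change detection.

The change search is the reinterpretation trigger: after re-annotation it
answers questions of the form "which variants were ever called benign or
of uncertain significance but are now pathogenic?", so that the carriers
of reclassified variants can be identified for recontact.

By default a "previous" value matches ANY strictly-prior historical value,
not only the immediately preceding one — the clinical question is "was
this variant ever called X?" — with a strict mode restricting the match
to the immediate predecessor.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Union

from .annotation_ingest import CLASSIFICATION_ATTR, TIERS
from .ledger import HistoryEntry, VariantKey, VariantStore


class QueryError(ValueError):
    """Structurally invalid query."""


def _as_set(value: Union[None, str, Iterable[str]]) -> Optional[frozenset[str]]:
    if value is None:
        return None
    if isinstance(value, str):
        return frozenset((value,))
    return frozenset(value)


@dataclass(frozen=True)
class ChangeQuery:
    """Predicates over an attribute's current and previous values.

    ``previous_in`` matches historical values strictly before the current
    entry (any prior by default; only the immediate predecessor when
    ``strict_previous``). ``current_equals`` constrains the current value.
    ``since`` restricts to changes whose current value was imported at or
    after the given ISO timestamp.
    """

    attribute: str
    previous_in: Optional[frozenset[str]] = None
    current_equals: Optional[frozenset[str]] = None
    since: Optional[str] = None
    strict_previous: bool = False
    case_insensitive: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "previous_in", _as_set(self.previous_in))
        object.__setattr__(self, "current_equals", _as_set(self.current_equals))
        if not self.attribute:
            raise QueryError("change query: attribute name must be non-empty")
        if self.previous_in is None and self.current_equals is None:
            raise QueryError("change query: at least one of previous_in/current_equals required")

    def _norm(self, value: str) -> str:
        value = value.strip()
        return value.lower() if self.case_insensitive else value

    def norm_set(self, values: Optional[frozenset[str]]) -> Optional[frozenset[str]]:
        return None if values is None else frozenset(self._norm(v) for v in values)


@dataclass(frozen=True)
class ChangeHit:
    """One matching variant with the qualifying prior and current values."""

    variant: VariantKey
    previous_value: str
    current_value: str
    changed_at: str


def _evaluate_history(q: ChangeQuery, history: list[HistoryEntry]) -> Optional[tuple[str, str, str]]:
    """(matched previous, current, changed_at) or None for one history."""
    if not history:
        return None
    current = history[-1]
    cur_set = q.norm_set(q.current_equals)
    if cur_set is not None and q._norm(current.value) not in cur_set:
        return None
    if q.since is not None and current.imported_at < q.since:
        return None
    if q.previous_in is None:
        return ("", current.value, current.imported_at)
    prev_set = q.norm_set(q.previous_in)
    candidates = history[-2:-1] if q.strict_previous else history[:-1]
    # most recent qualifying prior value is reported
    for entry in reversed(candidates):
        if q._norm(entry.value) in prev_set:
            return (entry.value, current.value, current.imported_at)
    return None


def search_changes(store: VariantStore, q: ChangeQuery) -> list[ChangeHit]:
    """All variants whose attribute history satisfies the change query.

    Results are in canonical variant order; an attribute name never set
    anywhere yields an empty result, not an error.
    """
    histories = store.all_histories(q.attribute)
    hits: list[ChangeHit] = []
    for vid, history in histories.items():
        result = _evaluate_history(q, history)
        if result is not None:
            prev, cur, ts = result
            hits.append(ChangeHit(store.key_of(vid), prev, cur, ts))
    hits.sort(key=lambda h: h.variant.sort_key())
    return hits


def search_variants(store: VariantStore, criteria: dict[str, str]) -> list[VariantKey]:
    """Variants whose *current* attribute values match all criteria.

    Matching is exact after whitespace trimming. Empty criteria list every
    variant; a criterion on a never-set attribute matches nothing.
    """
    out: list[VariantKey] = []
    norm_criteria = {name: value.strip() for name, value in criteria.items()}
    for _, key in store.iter_variants():
        current = store.current_attributes(key)
        if all(
            name in current and current[name].strip() == value
            for name, value in norm_criteria.items()
        ):
            out.append(key)
    return out


def _percent(count: int, total: int) -> float:
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass(frozen=True)
class TierSummary:
    code: str
    label: str
    count: int
    percent: float


def classification_summary(store: VariantStore) -> tuple[list[TierSummary], int]:
    """Per-tier counts and one-decimal percents over classified variants.

    Only variants with a current ``classification`` value enter the
    denominator; percents are rounded half-up to one decimal. Returns the
    rows (C5 down to C1, zero-count tiers omitted) and the classified
    total.
    """
    counts: dict[str, int] = {}
    for vid, history in store.all_histories(CLASSIFICATION_ATTR).items():
        if history:
            tier = history[-1].value
            counts[tier] = counts.get(tier, 0) + 1
    total = sum(counts.values())
    rows = [
        TierSummary(t.code, t.label, counts[t.code], _percent(counts[t.code], total))
        for t in reversed(TIERS)
        if counts.get(t.code)
    ]
    return rows, total
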
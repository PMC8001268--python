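"""Gene panels and virtual panels for consent-restricted VCF import.

A *gene panel* is the gene content of an assay; a *virtual panel* is a
subset of one panel used to restrict which variants an import may load,
typically because the patient consented only to a subset of the assay's
genes. During a virtual-panel-filtered import, a record whose gene symbol
is not in the virtual panel — or that has no resolvable gene symbol at
all — is dropped and counted as panel-filtered.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Optional


class PanelError(ValueError):
    """Empty gene list, duplicate name, or subset violation."""


def _normalize(genes: Iterable[str]) -> frozenset[str]:
    symbols = {g.strip().upper() for g in genes if g and g.strip()}
    return frozenset(symbols)


@dataclass(frozen=True)
class GenePanel:
    """Named, non-empty set of uppercased gene symbols."""

    name: str
    genes: frozenset[str]


@dataclass(frozen=True)
class VirtualPanel:
    """Consent subset of a parent gene panel; genes must be within the parent."""

    name: str
    parent: str
    genes: frozenset[str]


def create_panel(name: str, genes: Iterable[str]) -> GenePanel:
    """Build a panel; symbols are uppercased and deduplicated."""
    if not name or not name.strip():
        raise PanelError("panel name must be non-empty")
    symbols = _normalize(genes)
    if not symbols:
        raise PanelError(f"panel {name!r}: gene list must be non-empty")
    return GenePanel(name=name.strip(), genes=symbols)


def create_virtual_panel(name: str, parent: GenePanel, genes: Iterable[str]) -> VirtualPanel:
    """Build a virtual panel; its genes must be a subset of the parent's."""
    if not name or not name.strip():
        raise PanelError("virtual panel name must be non-empty")
    symbols = _normalize(genes)
    if not symbols:
        raise PanelError(f"virtual panel {name!r}: gene list must be non-empty")
    outside = symbols - parent.genes
    if outside:
        raise PanelError(
            f"virtual panel {name!r}: genes {sorted(outside)} are not in parent "
            f"panel {parent.name!r}"
        )
    return VirtualPanel(name=name.strip(), parent=parent.name, genes=symbols)


def passes_virtual_panel(gene_symbol: Optional[str], vp: VirtualPanel) -> bool:
    """True iff the case-folded symbol is in the virtual panel.

    A record with no resolvable gene symbol fails the test (conservative
    consent reading) and is attributed to the panel filter by the caller.
    """
    if gene_symbol is None or not gene_symbol.strip():
        return False
    return gene_symbol.strip().upper() in vp.genes


def read_panel_tsv(path: str) -> dict[str, list[str]]:
    """Read two-column TSV (panel_name, gene_symbol) into name -> gene list."""
    panels: dict[str, list[str]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise PanelError(f"panel TSV {path!r}: expected 2 columns, got {row!r}")
            panels.setdefault(row[0].strip(), []).append(row[1])
    return panels
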
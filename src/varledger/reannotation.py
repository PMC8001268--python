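"""Chunked export of unique variants for external re-annotation.

Annotation pipelines evolve (ClinVar submissions, LOVD updates, ...), so
the store's variants are periodically re-annotated: every unique variant
is exported as minimal site-only VCF, annotated outside the store by
whatever pipeline the laboratory runs, and the resulting table is
re-imported through the annotation module, growing attribute histories
wherever a value changed.

Exports are split into files of at most ``chunk_size`` records inside a
single ZIP archive, in a deterministic sort order (natural chromosome
order, then position, ref, alt) so repeated exports of the same store are
identical.
"""

from __future__ import annotations

import zipfile
from typing import Optional

from .ledger import VariantKey, VariantStore

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##source=varledger re-annotation export\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def chunk_count(n: int, chunk_size: int) -> int:
    """Number of chunk files for n records: ceil(n / chunk_size), 0 for empty."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    return -(-n // chunk_size)


def export_unique_variants(
    store: VariantStore,
    out_path: str,
    chunk_size: int = 10_000,
) -> list[str]:
    """Write every unique variant to a ZIP of site-only VCF 4.2 files.

    Files are named ``reannotation_0001.vcf`` onward, each holding at most
    ``chunk_size`` records; an empty store yields an empty archive. The
    export carries no annotations (ID, QUAL, FILTER and INFO are ``.``) —
    the downstream annotator recomputes everything — and no genotype
    columns, since re-annotation needs no per-sample evidence. Returns the
    member file names.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    keys: list[VariantKey] = [key for _, key in store.iter_variants()]
    names: list[str] = []
    with zipfile.ZipFile(out_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for chunk_index in range(chunk_count(len(keys), chunk_size)):
            chunk = keys[chunk_index * chunk_size : (chunk_index + 1) * chunk_size]
            name = f"reannotation_{chunk_index + 1:04d}.vcf"
            body = [VCF_HEADER]
            for key in chunk:
                body.append(f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\t.\t.\n")
            zf.writestr(name, "".join(body))
            names.append(name)
    return names


def read_exported_keys(zip_path: str, member: Optional[str] = None) -> list[VariantKey]:
    """Parse the variant keys back out of an export archive (audit helper)."""
    keys: list[VariantKey] = []
    with zipfile.ZipFile(zip_path) as zf:
        members = [member] if member else sorted(zf.namelist())
        for name in members:
            for line in zf.read(name).decode().splitlines():
                if line.startswith("#") or not line.strip():
                    continue
                chrom, pos, _id, ref, alt = line.split("\t")[:5]
                keys.append(VariantKey(chrom, int(pos), ref, alt))
    return keys
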
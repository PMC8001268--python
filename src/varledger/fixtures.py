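"""Deterministic synthetic fixtures emulating the supported input dialects.

Two VCF flavors are emulated:

* a *hotspot-caller* style (``tss``): VCF 4.1, FORMAT ``GT:AF``, one row
  per hotspot position, so the overwhelming majority of rows are
  homozygous-reference (GT ``0/0``, AF 0) and only a handful carry a
  variant — the reason the GT=0/0 exclude row filter exists;
* a *commercial* style (``ddm``): VCF 4.2, FORMAT ``AD:DP`` with no AF
  subfield (allele-frequency percent must be derived as AD/DP x 100),
  and INFO subfields SGVEP (gene symbol), DBXREF (cross-references) and
  TYPE (mutation type).

Annotation TSVs simulate an external annotation pipeline, optionally
flipping a designated attribute for a seeded subset of variants so that
change detection has a known truth set. All generators are pure functions
of (parameters, seed): repeated calls produce byte-identical files, and
each returns a manifest sufficient to predict every ingest-report field.
The pseudo-random generator identity (Python ``random``, Mersenne
Twister) is recorded in every manifest so truth files are portable.
"""

from __future__ import annotations

import json
import random
from typing import Mapping, Optional, Sequence, Union

from .annotation_ingest import CLASSIFICATION_ATTR
from .ledger import VariantKey, VariantStore
from .specs import AnnotationDialectSpec, VcfDialectSpec, define_annotation_dialect, define_vcf_dialect

_RNG_ID = "python-random-mt19937"
_BASES = "ACGT"

#: Config emulating the hotspot-caller dialect: GT/AF sample attributes and
#: the row filter that excludes homozygous-reference hotspot rows.
TSS_DIALECT_CONFIG: dict = {
    "kind": "vcf",
    "name": "tss",
    "vcf_version": "4.1",
    "sample_attr_map": [["GT", "genotype"], ["AF", "allele_frequency"]],
    "row_filter": {"field": "GT", "operator": "equals", "values": ["0/0"], "action": "exclude"},
}

#: Config emulating the commercial dialect: AD/DP depths with the derived
#: allele-frequency percent, and gene/dbxref/mutation-type INFO attributes.
DDM_DIALECT_CONFIG: dict = {
    "kind": "vcf",
    "name": "ddm",
    "vcf_version": "4.2",
    "sample_attr_map": [["GT", "genotype"], ["AD", "allele_depth"], ["DP", "read_depth"]],
    "variant_attr_map": [
        ["SGVEP", "gene"],
        ["DBXREF", "dbxref"],
        ["TYPE", "mutation_type"],
    ],
    "derived_attrs": [
        {
            "target_attr": "allele_frequency",
            "numerator_field": "AD",
            "denominator_field": "DP",
            "scale": 100,
        }
    ],
    "gene_symbol_source": "SGVEP",
    "virtual_panel_compatible": True,
}

#: Dialect for annotation TSVs written by :func:`generate_annotation_file`
#: and by the simulated re-annotation pipeline (four key columns, ClinVar).
ANNOTATION_DIALECT_CONFIG: dict = {
    "kind": "annotation",
    "name": "external-annotator",
    "delimiter": "tab",
    "key_columns": ["chrom", "pos", "ref", "alt"],
    "attr_map": [["ClinVar", "ClinVar"]],
    "header_rows": 0,
}


def tss_dialect() -> VcfDialectSpec:
    return define_vcf_dialect(TSS_DIALECT_CONFIG)


def ddm_dialect() -> VcfDialectSpec:
    return define_vcf_dialect(DDM_DIALECT_CONFIG)


def annotation_dialect(attrs: Sequence[str] = ("ClinVar",)) -> AnnotationDialectSpec:
    cfg = dict(ANNOTATION_DIALECT_CONFIG)
    cfg["attr_map"] = [[a, a] for a in attrs]
    return define_annotation_dialect(cfg)


def _draw_positions(rng: random.Random, chroms: Sequence[str], n: int) -> list[tuple[str, int]]:
    """n distinct (chrom, pos) pairs; per-chrom positions drawn without replacement."""
    used: dict[str, set[int]] = {c: set() for c in chroms}
    out: list[tuple[str, int]] = []
    for _ in range(n):
        chrom = rng.choice(chroms)
        while True:
            pos = rng.randrange(1_000_000, 90_000_000)
            if pos not in used[chrom]:
                used[chrom].add(pos)
                break
        out.append((chrom, pos))
    return out


def _alleles(rng: random.Random) -> tuple[str, str]:
    ref = rng.choice(_BASES)
    alt = rng.choice([b for b in _BASES if b != ref])
    return ref, alt


def generate_tss_vcf(
    path: str,
    n_rows: int,
    n_nonref: int,
    seed: int,
    sample_id: str = "SAMPLE01",
) -> dict:
    """Write a hotspot-style single-sample VCF 4.1 and return its manifest.

    Exactly ``n_nonref`` rows carry a genotype in {0/1, 1/1} with AF in
    (0, 100]; the remaining rows are GT 0/0 with AF 0, as a hotspot caller
    emits for reference positions. The manifest's ``truth_nonref_keys``
    are the variants an ingest under the GT=0/0 exclude filter must load.
    """
    if not 0 <= n_nonref <= n_rows:
        raise ValueError(f"n_nonref must be within [0, n_rows], got {n_nonref}/{n_rows}")
    rng = random.Random(seed)
    chroms = ["chr13", "chr17", "chr2", "chr11"]
    sites = sorted(
        _draw_positions(rng, chroms, n_rows),
        key=lambda cp: (chroms.index(cp[0]), cp[1]),
    )
    nonref_idx = set(rng.sample(range(n_rows), n_nonref))
    lines = [
        "##fileformat=VCFv4.1\n",
        "##source=varledger synthetic hotspot-caller emulation\n",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n",
    ]
    records = []
    for i, (chrom, pos) in enumerate(sites):
        ref, alt = _alleles(rng)
        if i in nonref_idx:
            gt = rng.choice(["0/1", "1/1"])
            af = round(rng.uniform(1.0, 100.0), 2)
        else:
            gt, af = "0/0", 0.0
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:AF\t{gt}:{af}\n")
        records.append(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "gt": gt, "af": af}
        )
    with open(path, "w") as fh:
        fh.writelines(lines)
    return {
        "generator": "generate_tss_vcf",
        "rng": _RNG_ID,
        "seed": seed,
        "params": {"n_rows": n_rows, "n_nonref": n_nonref, "sample_id": sample_id},
        "records": records,
        "truth_nonref_keys": [
            f"{r['chrom']}|{r['pos']}|{r['ref']}|{r['alt']}"
            for i, r in enumerate(records)
            if i in nonref_idx
        ],
    }


def _apportion(weights: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n records across weighted genes.

    Integer weights summing to n pass through unchanged, so exact per-gene
    record counts can be fixed by construction.
    """
    total = float(sum(weights.values()))
    if total <= 0:
        raise ValueError("gene pool weights must sum to a positive value")
    genes = sorted(weights)
    quotas = {g: n * weights[g] / total for g in genes}
    counts = {g: int(quotas[g]) for g in genes}
    remainder = n - sum(counts.values())
    by_frac = sorted(genes, key=lambda g: (-(quotas[g] - counts[g]), g))
    for g in by_frac[:remainder]:
        counts[g] += 1
    return counts


_CLINVAR_POOL = ("benign", "likely benign", "uncertain significance", "pathogenic")


def generate_ddm_vcf(
    path: str,
    gene_pool: Mapping[str, float],
    n_records: int,
    seed: int,
    sample_id: str = "SAMPLE01",
) -> dict:
    """Write a commercial-style single-sample VCF 4.2 and return its manifest.

    FORMAT is ``GT:AD:DP`` with no AF subfield; each record's INFO carries
    SGVEP (gene), DBXREF and TYPE. Per-gene record counts follow the
    largest-remainder apportionment of ``gene_pool`` weights, so integer
    weights summing to ``n_records`` are exact counts. The manifest stores
    each record's gene and the expected derived allele-frequency percent
    (100 x alt depth / DP).
    """
    if not gene_pool:
        raise ValueError("gene_pool must be non-empty")
    rng = random.Random(seed)
    counts = _apportion(gene_pool, n_records)
    genes_sorted = sorted(counts)
    gene_chrom = {g: f"chr{(i % 22) + 1}" for i, g in enumerate(genes_sorted)}
    gene_base = {g: 1_000_000 * (10 + i) for i, g in enumerate(genes_sorted)}

    records = []
    for gene in genes_sorted:
        used: set[int] = set()
        for _ in range(counts[gene]):
            while True:
                pos = gene_base[gene] + rng.randrange(0, 200_000)
                if pos not in used:
                    used.add(pos)
                    break
            ref, alt = _alleles(rng)
            dp = rng.randrange(20, 400)
            alt_depth = rng.randrange(1, dp + 1)
            gt = "1/1" if alt_depth == dp else "0/1"
            rsid = rng.randrange(1_000, 999_999)
            clinvar = rng.choice(_CLINVAR_POOL)
            records.append(
                {
                    "chrom": gene_chrom[gene],
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": gene,
                    "gt": gt,
                    "ad": f"{dp - alt_depth},{alt_depth}",
                    "dp": dp,
                    "expected_allele_frequency": 100.0 * alt_depth / dp,
                    "dbxref": f"ClinVar:{clinvar},dbsnp:rs{rsid}",
                }
            )
    records.sort(key=lambda r: (VariantKey(r["chrom"], r["pos"], r["ref"], r["alt"]).sort_key()))

    lines = [
        "##fileformat=VCFv4.2\n",
        "##source=varledger synthetic commercial-caller emulation\n",
        '##INFO=<ID=SGVEP,Number=1,Type=String,Description="Gene symbol">\n',
        '##INFO=<ID=DBXREF,Number=1,Type=String,Description="Database cross-references">\n',
        '##INFO=<ID=TYPE,Number=1,Type=String,Description="Mutation type">\n',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n",
    ]
    for r in records:
        info = f"SGVEP={r['gene']};DBXREF={r['dbxref']};TYPE=SNV"
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t{info}"
            f"\tGT:AD:DP\t{r['gt']}:{r['ad']}:{r['dp']}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)
    return {
        "generator": "generate_ddm_vcf",
        "rng": _RNG_ID,
        "seed": seed,
        "params": {
            "gene_pool": dict(gene_pool),
            "n_records": n_records,
            "sample_id": sample_id,
        },
        "gene_counts": counts,
        "records": records,
    }


def manifest_keys(manifest_or_keys: Union[dict, Sequence[VariantKey]]) -> list[VariantKey]:
    """Variant keys from a generator manifest or an explicit key sequence."""
    if isinstance(manifest_or_keys, dict):
        return [
            VariantKey(r["chrom"], r["pos"], r["ref"], r["alt"])
            for r in manifest_or_keys["records"]
        ]
    return list(manifest_or_keys)


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def generate_annotation_file(
    path: str,
    manifest_or_keys: Union[dict, Sequence[VariantKey]],
    attributes: Optional[Mapping[str, Sequence[str]]] = None,
    fraction_changed: float = 0.0,
    seed: int = 0,
    changed_attr: str = "ClinVar",
    baseline_value: str = "uncertain significance",
    changed_value: str = "pathogenic",
) -> dict:
    """Write a simulated external-annotator TSV; returns the change truth.

    One row per variant, key columns chrom/pos/ref/alt. A seeded subset of
    ``round(fraction_changed x n)`` variants receives ``changed_value``
    for the designated attribute while the rest keep ``baseline_value``;
    any extra ``attributes`` columns are drawn from their value pools.
    The returned manifest's ``changed_keys`` is the exact truth set a
    change search must find after baseline + changed files are imported.
    """
    if not 0.0 <= fraction_changed <= 1.0:
        raise ValueError("fraction_changed must be within [0, 1]")
    keys = manifest_keys(manifest_or_keys)
    if not keys:
        raise ValueError("cannot annotate an empty variant set")
    attributes = dict(attributes or {})
    rng = random.Random(seed)
    n_changed = _round_half_up(fraction_changed * len(keys))
    changed_idx = set(rng.sample(range(len(keys)), n_changed))

    extra_cols = sorted(attributes)
    header = ["chrom", "pos", "ref", "alt", changed_attr] + extra_cols
    lines = ["\t".join(header) + "\n"]
    changed_keys = []
    for i, key in enumerate(keys):
        value = changed_value if i in changed_idx else baseline_value
        if i in changed_idx:
            changed_keys.append(str(key))
        row = [key.chrom, str(key.pos), key.ref, key.alt, value]
        row += [rng.choice(list(attributes[c])) for c in extra_cols]
        lines.append("\t".join(row) + "\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
    return {
        "generator": "generate_annotation_file",
        "rng": _RNG_ID,
        "seed": seed,
        "params": {
            "n": len(keys),
            "fraction_changed": fraction_changed,
            "changed_attr": changed_attr,
            "baseline_value": baseline_value,
            "changed_value": changed_value,
        },
        "n_changed": n_changed,
        "changed_keys": changed_keys,
    }


#: The designated reclassified variant of the built scenario: a BRCA2
#: missense call whose ClinVar status moved from uncertain significance to
#: pathogenic, with the matching C3 -> C5 tier reclassification.
SCENARIO_KEY = VariantKey("chr13", 32936829, "A", "G")


def build_reclassification_scenario(
    seed: int = 0, store_path: str = ":memory:"
) -> tuple[VariantStore, dict]:
    """Populate a store with one true reclassification among decoys.

    The designated variant (:data:`SCENARIO_KEY`) has ClinVar history
    [uncertain significance -> pathogenic] and classification history
    [C3 -> C5], and is carried by three samples. Decoys include stable
    pathogenic calls (identical re-imports), a benign -> likely benign
    drift, and never-changed VUS calls — none of which a benign/VUS ->
    pathogenic change search may return. Returns the store and the
    expected query answers.
    """
    rng = random.Random(seed)
    store = VariantStore(store_path)
    with store.transaction():
        truth = _populate_scenario(store, rng)
    return store, truth


def _populate_scenario(store: VariantStore, rng: random.Random) -> dict:
    t0, t1 = "2023-01-05T00:00:00Z", "2024-06-01T00:00:00Z"
    src0, src1 = "annotation_2023.tsv", "annotation_2024.tsv"

    decoy_sites = _draw_positions(rng, ["chr13", "chr17", "chr2"], 20)
    decoys = []
    for chrom, pos in decoy_sites:
        ref, alt = _alleles(rng)
        key = VariantKey(chrom, pos, ref, alt)
        if key == SCENARIO_KEY:
            continue
        decoys.append(key)
        store.upsert_variant(key)
    # decoy histories: stable, drifting within benign, or stable pathogenic
    for i, key in enumerate(decoys):
        kind = i % 4
        if kind == 0:
            store.record_attribute(key, "ClinVar", "benign", src0, t0)
            store.record_attribute(key, "ClinVar", "likely benign", src1, t1)
        elif kind == 1:
            store.record_attribute(key, "ClinVar", "pathogenic", src0, t0)
            store.record_attribute(key, "ClinVar", "pathogenic", src1, t1)  # unchanged
            store.record_attribute(key, CLASSIFICATION_ATTR, "C5", src0, t0)
        elif kind == 2:
            store.record_attribute(key, "ClinVar", "uncertain significance", src0, t0)
            store.record_attribute(key, CLASSIFICATION_ATTR, "C3", src0, t0)
        else:
            store.record_attribute(key, "ClinVar", "benign", src0, t0)
            store.record_attribute(key, CLASSIFICATION_ATTR, "C1", src0, t0)
        carrier = f"S{rng.randrange(10, 99)}"
        store.record_sample_attribute(carrier, key, "genotype", "0/1", src0, t0)

    store.upsert_variant(SCENARIO_KEY)
    store.record_attribute(SCENARIO_KEY, "ClinVar", "uncertain significance", src0, t0)
    store.record_attribute(SCENARIO_KEY, "ClinVar", "pathogenic", src1, t1)
    store.record_attribute(SCENARIO_KEY, CLASSIFICATION_ATTR, "C3", src0, t0)
    store.record_attribute(SCENARIO_KEY, CLASSIFICATION_ATTR, "C5", src1, t1)
    carriers = {"S1", "S2", "S3"}
    for sample in sorted(carriers):
        store.record_sample_attribute(sample, SCENARIO_KEY, "genotype", "0/1", src0, t0)
        store.record_sample_attribute(
            sample, SCENARIO_KEY, "allele_frequency", repr(round(rng.uniform(30, 60), 1)), src0, t0
        )

    truth = {
        "designated": str(SCENARIO_KEY),
        "carriers": sorted(carriers),
        "change_query": {
            "attribute": "ClinVar",
            "previous_in": ["benign", "uncertain significance"],
            "current_equals": ["pathogenic"],
        },
        "expected_change_hits": [str(SCENARIO_KEY)],
        "n_variants": store.unique_variant_count(),
    }
    return truth


def write_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
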
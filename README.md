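# varledger

A variant store for clinical genetics laboratories that must manage the
*lifecycle* of sequence variants, not just a snapshot. Diagnostic labs
accumulate VCFs from several sequencing platforms plus annotation tables from
several pipelines; the interpretation of a variant (its ClinVar status, its
IARC pathogenicity tier) changes over the years, and a variant once reported
as "uncertain significance" may later become "pathogenic" — at which point
every patient carrying it should be identified for possible recontact.

varledger addresses exactly that workflow:

- **Configurable ingestion.** Input formats are described declaratively as
  *dialects*: which FORMAT subfields become per-sample attributes, which INFO
  subfields become variant attributes, which rows to skip, when to stop
  reading. Two common VCF flavors are covered out of the box: a
  hotspot-caller style (FORMAT `GT:AF`, thousands of homozygous-reference
  rows excluded by a `GT = 0/0` row filter) and a commercial style (FORMAT
  `AD:DP` with no AF subfield, gene symbol and cross-references in INFO).
- **Deduplication.** Variants are keyed by `(chrom, pos, ref, alt)` after
  canonicalization; the same variant imported from any number of files and
  platforms is a single record (canonical text form `chr13|32936829|A|G`).
- **Attribute history.** Re-importing an identical attribute value leaves
  the history untouched (only the provenance timestamp refreshes); a
  differing value appends an entry and preserves the old one. Every entry
  carries its source file and import time.
- **Derived attributes.** For callers that report depths but no allele
  frequency, a sample attribute can be computed as

  &nbsp;&nbsp;&nbsp;&nbsp;`allele_frequency = AD / DP × 100`

  (alt-allele depth over total read depth, as a percent).
- **Virtual gene panels.** An import can be restricted to a consented gene
  subset of the assay panel; off-panel records (and records with no
  resolvable gene symbol) are dropped and counted.
- **Re-annotation loop.** All unique variants export as a ZIP of site-only
  VCF files (at most 10,000 records each) for external annotation pipelines;
  the annotated table re-imports through the same history machinery.
- **Change detection.** `search-changes` finds variants whose attribute
  history moved from a set of previous values to a set of current values
  (e.g. benign/VUS → pathogenic), and `samples-with-variant` lists every
  carrier of a given variant.

Storage is a single SQLite file; every import is atomic.

## Worked example

A hotspot-caller VCF of 5,000 rows, of which only 15 are non-reference, is
imported under the built-in `tss` dialect; a baseline annotation is loaded;
an updated annotation (with three ClinVar upgrades) is re-imported; the
change search then reports exactly the upgraded variants. The fixture files
used below are produced by `varledger make-fixtures` or the
`varledger.fixtures` API.

```
$ varledger --store clinic.db init-store
$ varledger --store clinic.db define-dialect --from-config tss.yaml
$ varledger --store clinic.db import-vcf --dialect tss --sample P001 patient1.vcf
{
  "source": "patient1.vcf",
  "rows_read": 5000,
  "rows_dropped_by_row_filter": 4985,
  "rows_loaded": 15,
  "variants_created": 15,
  "sample_attributes_written": 30,
  ...
}
```

5,000 rows were read; 4,985 homozygous-reference rows were excluded by the
dialect's `GT = 0/0` filter; the 15 genuine variants were stored, each with
two sample attributes (genotype and allele-frequency percent) for patient
P001. After a baseline annotation import and an updated one:

```
$ varledger --store clinic.db import-annotation --dialect external-annotator update.tsv
{
  "rows_read": 15,
  "attributes_unchanged": 12,
  "attributes_updated": 3,
  ...
}
$ varledger --store clinic.db search-changes --attr ClinVar \
      --prev benign --prev "uncertain significance" --now pathogenic
{
  "count": 3,
  "results": [
    {
      "variant": "chr2|89329907|A|G",
      "previous": "uncertain significance",
      "current": "pathogenic",
      "changed_at": "2026-09-20T18:56:16Z"
    },
    ...
  ]
}
```

Twelve re-imported values were identical (histories untouched); three
differed, growing those histories — and the change search returns exactly
those three variants, each with the prior value that qualified it.
`varledger samples-with-variant "chr2|89329907|A|G"` would then list the
patients to consider for recontact.

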
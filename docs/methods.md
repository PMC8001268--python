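# Methods

## Data model

The store holds three kinds of facts, all in one SQLite file.

**Variant identity.** A variant is `(chrom, pos, ref, alt)` with 1-based
VCF coordinates and a single alt allele over A/C/G/T/N. Canonicalization
uppercases alleles and normalizes the chromosome label to the
`chr`-prefixed form (`13` → `chr13`, `MT` → `chrM`), so the same variant
reported by different platforms deduplicates to one record. Identity is
otherwise exact-string: no left-alignment or parsimony normalization is
applied. The consequence is deliberate and documented — two representations
of the same indel (e.g. differently anchored) are distinct records. All the
supported callers emit normalized SNV/short-indel calls, and silently
rewriting coordinates would detach stored records from the laboratory's
source files. Multiallelic VCF records are split one-alt-per-record before
keying; per-allele FORMAT lists are sliced accordingly (length-`A` lists
keep the alt's element, length-`R` lists keep the ref element plus the
alt's element).

**Attribute histories.** Each variant attribute is an ordered list of
`(value, imported_at, source)` entries. Writing a value equal to the
current one (whitespace-trimmed, case-sensitive — `Pathogenic` vs
`pathogenic` *is* a change, since capitalization can carry meaning in
upstream exports) refreshes the current entry's timestamp and source
without growing the history, so "last confirmed" remains recoverable;
writing a differing value appends. Two invariants hold store-wide after any
operation sequence and are assertable via `check_history_wellformed()`:
no two consecutive entries are equal, and the current value is the last
entry. Empty strings are refused as values, so ingest layers skip empty
cells rather than recording them.

**Sample observations.** Per-sample evidence (genotype, allele-frequency
percent, depths) follows the same overwrite-if-identical /
track-if-different rule, keyed by `(sample, variant, attribute)`. Carrier
lookup (`samples_with_variant`) is a distinct-sample scan over these
observations.

Every import runs in one SQLite transaction: a failed import leaves the
store byte-identical.

## Dialects

Input formats are described as data, not code. A VCF dialect maps FORMAT
subfields to sample attributes and INFO subfields to variant attributes,
optionally adds derived attributes and a row filter, and may name the INFO
subfield carrying the gene symbol. An annotation dialect names the
delimiter, the key columns (either four chrom/pos/ref/alt columns or one
pipe-form `chrom|pos|ref|alt` column), the column→attribute map, an
optional row filter and an optional break condition. Attribute names are
deliberately shared across dialects: collision is the mechanism by which
two pipelines update the same attribute and its history.

Design choices that were genuinely open:

- **Filter grammar** is a single-field predicate (equals / not-equals /
  in-set / not-in-set, with exclude or include-only action). Every filter
  the workflow needs is of this shape (the canonical one excludes rows
  with genotype `0/0` from hotspot files); an expression language would
  add surface without adding capability.
- **Absent-field semantics**: a filter never matches a record lacking its
  field. Records with a missing GT therefore survive a GT-based exclude
  filter (excluding on absence would silently drop entire dialects that
  lack the subfield), and an include-only filter drops them.
- **Derived expressions** are ratios with a scale constant — the allele
  frequency percent `AD/DP × 100`. Evaluation is undefined (attribute
  omitted, warning counted in the ingest report) when the denominator is
  zero or a field is absent; values are stored at full precision, display
  rounding being a presentation concern. When AD is a comma list the first
  alt's element is used; multiallelic splitting has already assigned one
  alt per record at that point.
- **Declared FORMAT subfields**: a derived expression may reference only
  subfields the dialect declares, which are the keys of the sample
  attribute map plus an optional explicit list. The built-in commercial
  dialect maps AD and DP as sample attributes in their own right, which
  both preserves the raw evidence and satisfies the declaration rule.
- **Annotation header handling**: column names come from a header line;
  `header_rows` counts junk lines to skip *before* that header (0 means
  the file starts with the header). The break condition is evaluated on
  data rows in order, before the row filter, and stops processing at the
  first match, so the number of processed rows equals the matching row's
  0-based index.
- **DBXREF splitting**: the commercial dialect's cross-reference subfield
  is parsed as comma-delimited `source:token` pairs into one attribute per
  source (`dbxref_ClinVar`, `dbxref_dbsnp`, ...), with colonless tokens
  preserved under `dbxref_raw`. The grammar is an assumption about an
  under-documented field and is isolated in `split_dbxref` so it can be
  re-specified without touching ingestion.

The VCF reader itself is a small line-based parser: dialect-driven subfield
mapping is the point of the module, and the supported surface (single-sample
VCF 4.1/4.2 text, plain or gzip) does not need more. QUAL and FILTER are
ignored; symbolic alts and breakends are skipped with counted warnings;
phased separators are normalized (`0|0` → `0/0`) before filter comparison;
multi-sample files are a hard error, the sample identifier being supplied by
the caller since file naming conventions vary. Generated fixtures are
additionally validated with an independent VCF library in the test suite.

## Panels

A gene panel is the assay's gene content; a virtual panel is a named subset
used as a consent filter at import time. Virtual panels are constrained to
be subsets of their parent at creation (a consent filter wider than the
assay is meaningless). Filtering is by gene symbol, case-folded; a record
whose gene symbol cannot be resolved is dropped under an active virtual
panel — the conservative consent reading — and counted separately in the
ingest report. Requesting a virtual panel with a dialect that has no gene
symbol source is a hard error rather than a silent no-op.

## Re-annotation export

All unique variants export as minimal site-only VCF 4.2 (ID/QUAL/FILTER/
INFO all `.`, no genotype columns — the external annotator recomputes
everything and needs no per-sample evidence), sorted by natural chromosome
order (chr1..chr22, chrX, chrY, chrM, then others lexicographically) then
position, ref, alt. Determinism of the order makes repeated exports
byte-identical and chunk boundaries reproducible. Files hold at most
`chunk_size` records (default 10,000, configurable), named
`reannotation_0001.vcf` onward inside one ZIP; an empty store yields an
empty archive.

## Change detection

A change query names an attribute, a set of qualifying previous values, a
set of required current values, and optionally a lower bound on the import
time of the current value. By default "previous" matches *any* strictly
prior historical value: the clinical question is "was this variant ever
called benign or VUS?", not "what was it called immediately before?". A
strict mode restricts matching to the immediate predecessor, and a
case-insensitive flag accommodates upstream exports that vary in
capitalization; matching is otherwise exact after trimming. Results carry
the most recent qualifying prior value and the current entry's timestamp,
in canonical variant order. The implementation fetches all histories for
the attribute in one query and evaluates per history; the test suite checks
it against an independent brute-force scan written over the public history
API, on a thousand randomized stores.

Classification summaries count current values of the reserved
`classification` attribute (IARC tiers C1 Benign … C5 Pathogenic; the
code↔label bijection is fixed). Percents are computed over classified
variants only and rounded half-up to one decimal with `decimal.Decimal`
(avoiding both banker's rounding and float representation artifacts);
with five tiers each rounding can move the sum by up to 0.05, so the
percents sum to 100.0 ± 0.25.

## Synthetic data

The fixture generators define the study conditions under which everything
is tested; no external data is used.

- `generate_tss_vcf` emulates the hotspot-caller profile: `n_rows` hotspot
  positions of which exactly `n_nonref` carry a variant (GT in {0/1, 1/1},
  AF in (0, 100]) and the rest are GT 0/0 with AF 0. The reference profile
  — 5,000 rows with 15 non-reference — is the default in the fixture CLI
  and the acceptance script, matching what a hotspot assay of a few
  thousand positions typically yields per sample.
- `generate_ddm_vcf` emulates the commercial profile: FORMAT `GT:AD:DP`
  with no AF subfield, INFO `SGVEP`/`DBXREF`/`TYPE` per record. Per-gene
  record counts are fixed by largest-remainder apportionment of the gene
  pool weights, so integer weights summing to the record count are exact
  counts — panel-filtering truths are constructions, not draws.
- `generate_annotation_file` simulates the external annotator: one row per
  variant, with a seeded subset of `round(fraction_changed × n)` (half-up)
  receiving a designated transition (default ClinVar VUS → pathogenic) and
  the rest keeping the baseline value; the returned manifest is the exact
  truth set for change searches.
- `build_reclassification_scenario` populates a store with one designated
  reclassified variant (`chr13|32936829|A|G`, ClinVar VUS → pathogenic,
  tier C3 → C5, three carriers) among ~20 decoys covering the confusable
  cases: stable pathogenic with identical re-import, benign → likely
  benign drift, and never-changed VUS/benign.

Positions are drawn without replacement per chromosome so keys never
collide by accident; generators are byte-deterministic in (parameters,
seed) using Python's Mersenne Twister, whose identity is recorded in each
manifest. What the generators do *not* emulate: realistic allele-frequency
spectra, reference-consistent REF alleles, indels and multi-nucleotide
variants in bulk, or annotation noise (contradictory pipelines, malformed
rows beyond the explicit error-path fixtures). Passing tests therefore
demonstrate the bookkeeping semantics — identity, history, filtering,
chunking, change detection — under faithful file *structure*, not
robustness to arbitrary real-world file content.

## Problem sizes and numerical notes

The test suite and acceptance script run at the scales the workflow itself
names: 5,000-row hotspot files, a 22,569-variant store for export chunking
(three files at chunk size 10,000), the 1,016-variant five-tier
distribution (330/38/333/206/109 → 32.5/3.7/32.8/20.3/10.7 percent), and
1,000-fold randomized property checks for history semantics and the
change-search oracle. Timestamps are ISO-8601 UTC strings, compared
lexicographically (valid for this fixed format). Ties in chunk boundaries,
orderings and apportionment are broken deterministically (canonical variant
order; alphabetical gene order at equal remainders).

## Known limitations

- Single-sample VCFs only; multi-sample files must be split upstream.
- No indel normalization (see above) and no liftover; coordinates are
  trusted as imported.
- Genotype strings of multiallelic records are carried through unchanged
  after splitting (a `1/2` genotype appears on both split records).
- The store is single-user and unencrypted; concurrency and deployment
  hardening are out of scope.
- Annotation computation (ClinVar lookup, consequence prediction) is
  external by design; varledger only manages the resulting values.
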
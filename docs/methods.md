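# Methods

## The validation model

`mwstatus` treats a metabolomics repository as a two-level hierarchy of
studies (`ST######`) containing analyses (`AN######`), each analysis served in
two serializations that are supposed to be generated from one deposition: the
sectioned, tab-delimited plain-text dialect and a JSON mirror. Three distinct
failure modes are modelled separately, because they have different causes and
different remedies:

* **gross formatting errors** — the file cannot be tokenized at all
  (truncated data blocks, invalid JSON, unreadable encoding, blank files).
  These usually point at conversion or deposition software. They surface as a
  structured `ParseFailure`, never an exception: the parsers are *total*.
* **minor formatting errors** — the file parses, but violates the file-format
  specification (missing required sections or keys, an empty sample-factor
  table, a data-less analysis). These are itemized `ValidationIssue`s.
* **availability errors** — the file is listed by the source but cannot be
  retrieved. A zero-byte retrieval is deliberately *not* in this class: blank
  files flow to the parser so that a validation log exists for them too.

The boundary between gross and minor is drawn at tokenization: any failure to
tokenize the header line, a section header, an item line or a block sentinel
is gross; anything detectable on a successfully built in-memory file is minor.
This makes the per-file status a simple precedence chain:
absent → Missing; unparsable → Parsing error; any issue → Validation error;
otherwise Passing. The text and JSON twins of one analysis are classified
independently — they genuinely can and do diverge in the wild.

## The text dialect and JSON mirror

The plain-text grammar is encoded as a small table in `mwtab_io`
(header sentinel, `#SECTION` headers, `PREFIX:KEY<TAB>value` item lines,
`<BLOCK>_START`/`<BLOCK>_END` sentinels around matrices, a final `#END`), so a
dialect correction is a data change, not a parser rewrite. Values are stored
as strings and never numerically coerced at the I/O layer; section order and
row order are preserved exactly, which is what makes text re-serialization
byte-identical and round-trip testing meaningful. Input handling tolerates a
UTF-8 BOM and CRLF line endings, since real deposition files vary. Duplicate
keys within a section keep the first occurrence and record a parser note that
the validator surfaces as a minor issue — parsing must stay total.

The JSON mirror is a single top-level object: one header key carrying the
identity fields, then the sections in order (objects for key–value sections,
an array of row objects for the sample-factor table, and
`{Samples, Factors, Data}` for matrices). Key order in emitted JSON is stable,
so writing is deterministic; key order is *not* significant when reading.

## Versioned schema rule tables

What the specification requires is configuration, not code: YAML tables under
`mwstatus/schemas/` list the required sections, the required keys per section,
and which extra sections a mass-spectrometry versus NMR analysis needs
(`CHROMATOGRAPHY` + `MS` + a data block, versus `NMR` + a data block). The
shipped v1.5 table is a defensible core set; v1.6 differs only by additional
required Chromatography keys (`FLOW_RATE`, `COLUMN_TEMPERATURE`, `SOLVENT_A`,
`SOLVENT_B` — editable placeholders to be synced with the official
specification text). Because v1.6 is a strict superset, validation is
monotone across versions: anything passing v1.6 passes v1.5, a property the
tests assert directly from the loaded tables and over generated files.

Schema selection honours the file's header `VERSION` field when it names a
registered table and otherwise falls back to a configurable default (v1.5),
because legacy submissions predate versioning and are never retroactively
updated. An absent version field warns-and-defaults rather than fails, and
additionally surfaces as a schema issue; the selected version and the reason
are recorded in every validation log's run-conditions block. A data-less
analysis (all metadata present, no metabolite-data block) is flagged as a
schema issue — such analyses exist in the wild and are plausibly why some
files are unavailable through the REST interface.

## Comparison policy

The two serializations derive from one deposition, so the comparator uses
exact string comparison after trimming leading/trailing whitespace — no
numeric tolerance. Formatting drift between the formats is exactly the kind
of conversion-software error worth surfacing, and a tolerance would hide it.
Decisions worth stating:

* key/section *order* differences are never discrepancies (order is
  serialization detail); presence and value differences always are;
* a section present on only one side is **one** discrepancy, not one per key,
  to keep counts interpretable;
* an empty-string value and an absent key are distinct (`VALUE_MISMATCH`
  versus `MISSING_IN_*`);
* matrix rows are matched by feature name, cells addressed by sample name;
  factor rows are matched by position;
* the discrepancy list is sorted by path, making output deterministic;
* an ignore-list for volatile fields is supported and defaults to empty —
  everything is compared.

A pair is `Not checked` exactly when either side is missing or unparsable;
`Consistent` requires both parses to succeed with zero discrepancies. The
three comparison outcomes therefore partition the corpus, as do the four
file statuses per format — the structural invariant behind the summary
tables.

## The synthetic corpus generator

`fixtures` emulates a repository mirror at desk scale: paired text/JSON files
per analysis with exactly one defect category each, plus a `manifest.json`
recording the statuses the pipeline *must* assign. The defect taxonomy is
designed so every file status and every comparison outcome has at least one
generating defect: absent files (one side, or both — emulating analyses a
listing names but the interface cannot serve), blank text files, structural
corruption (a deleted block sentinel; truncated JSON), required-key deletion
in one or both formats, and value drift in the JSON side only. Injected
mutations are engineered to map one-to-one onto downstream findings: each
deleted required key produces exactly one validation issue, each drifted
value exactly one comparison discrepancy. Two consequences worth noting:
one-sided key deletion necessarily also makes the pair inconsistent (the
manifest expects that), and value drift avoids the one value the validator
interprets (`ANALYSIS_TYPE`), so drift changes consistency but never
validity.

Defect proportions are apportioned over the corpus by largest-remainder
rounding with ties broken by defect enumeration order, so requested mixes are
hit exactly and deterministically. The default mix (40 % clean, the rest
spread over all ten defect categories) is chosen to exercise every pipeline
path; generated content (species, instruments, metabolite names) comes from a
small vocabulary — schema-shape fidelity, not statistical realism, is the
goal. The whole corpus is a pure function of the seed.

What the generator does *not* emulate: real-world scale of metadata (hundreds
of keys per file), controlled-vocabulary violations, character-encoding
pathologies beyond BOM/CRLF, server errors other than 404, and partial
transfers. Passing the recovery oracle therefore demonstrates that the
pipeline's classification machinery is exact over the defect taxonomy, not
that the shipped v1.5 rule table matches the official specification
clause-for-clause — the rule tables are editable for precisely that reason.

## Harvesting behaviour

REST requests are spaced by a configurable delay (default 1 s) enforced by a
rate limiter with injectable clock and sleep, and retried a configurable
number of times; a persistently failing file degrades to absent rather than
aborting the run, so a harvest always completes. Local-directory sources
apply no throttling. For directories, the corpus manifest (when present) is
the listing authority — it can name analyses whose files are absent, exactly
as a REST listing can name analyses that then 404 — with a file-system scan
as fallback. An optional content-hash cache (SHA-256 over the raw byte pair)
lets scheduled re-runs skip re-validating unchanged analyses; it is off by
default. Traversal order is lexicographic by study then analysis, so runs
are reproducible and reports stable.

## Reporting

Validation logs carry three metadata groups in a fixed order: run conditions
(timestamp, validator version, schema version and why it was selected), file
identity (study, analysis, format, status), then the error count and one line
per issue. The exact field labels are this package's choice. Log files are
named `<ANALYSIS_ID>_<txt|json>.log` and `<ANALYSIS_ID>_comparison.log`.

The status site is plain templated HTML plus one CSS file — no client-side
framework, no JavaScript, no network access during rendering — generated as a
pure function of (records, summary, injected timestamp). Status badges carry
semantic CSS classes (`st-passing`, `st-parsing-error`, …) so tests can parse
the HTML and assert that every badge equals the status in the corresponding
log, and that the index tables equal the computed summary. Publishing the
output directory (e.g. to static hosting) is outside the package's scope.

## Problem sizes and numerical choices

The test suite and the acceptance script work at desk scale: 200 generated
fixtures for round-trip identity, a 500-analysis corpus across 100 studies
for the recovery oracle, mutation counts of 1/2/5 for count-fidelity checks.
These sizes exercise every code path and keep the full suite in the
low seconds. There is no floating-point arithmetic anywhere in the pipeline —
all values are compared as trimmed strings — so there are no tolerances to
tune; the only rounding in the package is the largest-remainder apportionment
of defect mixes, whose tie-break is fixed and documented above.

## Known limitations

* The shipped rule tables are a curated core, not a transcription of the
  official specification; field-level value patterns are supported but not
  populated.
* The comparator decides *that* the formats disagree, never which side is
  correct.
* No controlled-vocabulary or chemical-identifier checking; no semantic
  interpretation of metabolite names.
* NMR binned-data blocks are handled as ordinary data matrices.
* The harvester is strictly sequential — politeness is preferred over
  throughput — and does not resume partial downloads.
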
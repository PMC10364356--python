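# mwstatus

Continuous validation of [Metabolomics Workbench](https://www.metabolomicsworkbench.org/)
analysis data files. The repository serves each analysis in two serializations
— the sectioned, tab-delimited `mwTab` plain-text dialect and a JSON mirror —
and in practice a large fraction of deposited files carry formatting errors,
violate the file-format specification, disagree between the two formats, or
are simply unreachable through the REST interface. `mwstatus` is for data
curators and for researchers reusing public metabolomics data who need to know,
per analysis and per format, whether a file is actually parseable, compliant,
and internally consistent before building on it.

## What it does

For every analysis (an `AN######` identifier inside an `ST######` study) the
pipeline:

1. **Harvests** both file formats from a REST source (with a polite
   configurable delay between requests, 1 s by default) or a local directory.
2. **Parses** each file with total parsers: a gross formatting error becomes a
   structured parse failure, never a crash, and a blank file still gets a log.
3. **Validates** each parsed file against a versioned schema of required
   sections and keys (v1.5 and v1.6 rule tables ship as editable YAML; v1.6
   adds required Chromatography fields), assigning one of four statuses:

   | Status | Meaning |
   |---|---|
   | Passing | parsed, no schema issues |
   | Parsing error | gross formatting error prevented parsing |
   | Validation error | parsed but inconsistent with the specification |
   | Missing | not retrievable from the source |

4. **Compares** the text and JSON twins field by field (header, every
   key–value item, factor rows, sample names, every matrix cell) and classifies
   the pair as Consistent, Inconsistent (with an itemized discrepancy list), or
   Not checked when either side is missing or unparsable.
5. **Reports**: a plain-text validation log per (analysis, format), a
   comparison log per analysis, machine-readable `records.json`/`summary.json`,
   and a deterministic static HTML status site organized by the
   Study → Analysis hierarchy.

A synthetic corpus generator (`mwstatus fixtures`) produces paired text/JSON
files with injected defects of every category plus a ground-truth manifest, so
the whole pipeline is testable end to end without downloading anything.

## Worked example

```sh
mwstatus fixtures --seed 11 --studies 4 --analyses 12 --out corpus
mwstatus validate --source corpus --out results
mwstatus generate --in results --out site --timestamp 2026-01-01T00:00:00Z
```

The `validate` step prints the corpus summary it computed:

```json
{
  "total_analyses": 12,
  "per_format": {
    "txt":  {"Passing": 8, "Parsing error": 2, "Validation error": 2, "Missing": 0},
    "json": {"Passing": 9, "Parsing error": 1, "Validation error": 2, "Missing": 0}
  },
  "comparison": {"Consistent": 6, "Inconsistent": 3, "Not checked": 3}
}
```

Read it column-wise: of 12 analyses, 8 text files and 9 JSON files pass
outright; 2 text files (a blank file and a corrupted data block) could not be
parsed at all; 2 per format violate the schema (deleted required keys); and
the text/JSON pair disagrees for 3 analyses while 3 more could not be compared
because one side was unparsable. Each format's counts sum to 12, as do the
comparison counts — the partition property the summary tables rely on. The
`site/` directory then holds `index.html` (the two summary tables), one page
per study with status badges per analysis, and links into the plain-text logs
under `results/logs/`.

Pointing `--source` at a REST base URL instead of a directory runs the same
pipeline against a live repository mirror; `--cache` enables content-hash
skipping of unchanged analyses on repeated runs.

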
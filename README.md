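# rm5kit

Batch parsing, free-text normalization, outcome-title ontology and
idempotent write-back for RevMan 5 (`.rm5`) systematic-review files.

Systematic reviewers extract trial data with great care into RevMan, the
authoring software behind Cochrane-style reviews — but the resulting
semi-structured data stay locked inside one XML file per review.  rm5kit is
for evidence-synthesis teams and methods researchers who want those data
*out*: it batch-parses directories of `.rm5` files into a typed model,
tidies the messy free text with a replaceable rule file, collects and
clusters the thousands of inconsistent outcome titles into a worksheet a
curator can turn into an ontology, marshals everything into one central
queryable dataset (XML/CSV/JSON), and writes curated content back into the
source reviews without disturbing a byte it doesn't own.

## What it computes

- **Lossless parse.** A documented subset of the RevMan 5.3 dialect
  (references with many-to-one reports per study, the five-field
  characteristics table, per-study risk-of-bias tables, dichotomous
  `events/total` and continuous `mean/SD/N` outcome rows).  Subtrees
  outside the subset are retained opaquely; `read ∘ write` is the identity
  on the model and `write ∘ read` is canonical-XML-equal to the input.
- **Rule-based normalization.** Ordered case-insensitive regexes map
  surface forms to canonical labels (first match by ascending priority,
  total with a fallback label): "double blind" / "double-blind" / "doubly
  blinded" all become `double`.  Cue-anchored extractors parse participant
  counts (`N=120`, "120 inpatients") and durations; bare numbers are never
  trusted.
- **Outcome-title ontology.** Titles are harvested raw (NFC + trim),
  clustered by canonical form (casefold, strip punctuation/enumeration,
  collapse whitespace), exported as a curation worksheet, and a curated
  `title → (category, subcategory)` mapping is applied back to the data.
- **Corpus queries.** Publication-year histogram (years parsed from
  "Name YYYY" study ids with reference-year fallback), the corpus-age
  query `fraction_older(k, ref)`, and per-review participant totals with
  explicit missing counts.
- **Write-back.** Each study's contributed-outcomes list is injected into
  its characteristics table between sentinel comments — idempotent under
  re-runs, and strippable to recover the original exactly.
- **Synthetic corpora.** A seeded generator emits realistic `.rm5` files
  plus a ground-truth manifest, so the whole pipeline is testable without
  access to real review corpora.

## Worked example

```sh
$ rm5kit synth --seed 42 --n-reviews 20 -o corpus
20 reviews, 92 studies -> corpus

$ rm5kit extract corpus -o out/central.xml --created 2026-09-28T00:00:00Z
$ cat out/run_report.json
{
  "command": "extract",
  "failures": [],
  "outcome_rows": 228,
  "reviews": 20,
  "studies": 92
}
```

The generated corpus contains 20 reviews with 92 studies and 228 outcome
data rows; `extract` recovered every one of them (an empty `failures`
list), normalized each study's blinding/allocation text and participant
counts, and marshalled everything into `out/central.xml` — the counts in
the run report equal the generator manifest's totals exactly.

```sh
$ rm5kit stats years corpus --reference-year 2026 | tail -3
# studies dated: 92, undated: 0
# median year: 1996.0
# fraction older than 20y (ref 2026): 0.739

$ rm5kit outcomes worksheet corpus -o worksheet.csv
31 clusters written to worksheet.csv
```

All 92 studies carry a resolvable publication year; half the evidence
predates 1996, and 74% of it is more than two decades old against a 2026
reference — the kind of corpus-age question the flat dataset makes a
one-liner.  The 64 distinct raw outcome titles in this corpus collapse to
31 clusters for curation (fill in the `category` column of the worksheet
and feed it back with `rm5kit outcomes apply`).

Write-back, idempotently:

```sh
rm5kit inject corpus/R0001.rm5 -o R0001.edited.rm5
```

## Layout

- `src/rm5kit/` — `model` (typed data model), `rm5_io` (dialect
  reader/writer, batching), `textnorm` (rule engine + extractors),
  `ontology` (harvest/cluster/worksheet/mapping), `central` (central
  dataset, exports, queries), `writeback` (sentinel injection), `synth`
  (corpus generator + manifest), `cli`.
- `src/rm5kit/data/` — default rule file, blinding/allocation phrase bank,
  outcome-title bank.
- `docs/rm5-dialect.md` — the supported XML dialect; `docs/examples/` —
  three annotated example files; `docs/methods.md` — methods note.
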
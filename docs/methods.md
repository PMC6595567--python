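# Methods

rm5kit is a batch toolkit for the XML save files (`.rm5`) of RevMan 5, the
authoring software behind Cochrane-style systematic reviews.  A review file
holds reliably extracted trial data — references, per-study characteristics
prose, risk-of-bias judgements, numeric outcome tables — but locks them
inside a single document.  The toolkit parses whole directories of such
files into one flat, queryable dataset, normalizes the semi-structured free
text, organizes the chaos of outcome titles into a curatable ontology, and
feeds curated content back into the source files without disturbing
anything else.  This note records the procedures, the parameters that
matter, and the design decisions taken where the design was genuinely open.

## Data model and round-trip contract

The reader covers a documented subset of the RevMan 5.3 dialect
(`docs/rm5-dialect.md`); element names live in a single mapping table so
the dialect can be re-pointed without code changes.  Two properties define
correctness:

- **Model round-trip.** `read(write(r)) == r` field-for-field over the
  supported subset.  Free-text characteristics fields keep their raw inline
  markup verbatim (a plain-text projection — tags stripped, entities
  decoded, whitespace collapsed — is what the rule engine and clustering
  see); subtrees outside the subset are retained opaquely with their
  document position and re-emitted on write.
- **No-edit stability.** `write(read(f))` is canonicalized-XML-equal to
  `f` for every file the toolkit itself produced.  Canonical equality
  (C14N with comments, attribute order and serializer byte-layout
  normalized) rather than byte equality is the contract, because
  serializers legitimately differ in byte layout.

Numbers are serialized with Python's shortest-round-trip float
representation, so numeric fields survive the cycle exactly.  Empty
optional leaf elements are omitted on write; the five top-level section
containers are structural and always present (this keeps retained-subtree
positions well defined).  Fragments are stored in normalized serialized
form; an empty element therefore reads back as `<P/>` regardless of how it
was spelled, which is the one place the verbatim guarantee is "verbatim up
to serialization".

Reads are `lenient` by default (missing optional blocks become empty
collections with a logged warning; invariant violations are logged and
kept) and `strict` for generator CI (missing studies container and any
invariant violation — e.g. dichotomous events exceeding the arm total —
raise).  Batch reads sort by review id, never by filesystem order, and
collect per-file failures instead of aborting.

## Free-text normalization

The same trial attribute appears in many surface forms ("double blind",
"double-blind", "doubly blinded" …).  Normalization is a rule engine over
ordered case-insensitive regular expressions: within a (field, variable)
pair, the matching rule with the smallest priority number wins; no match
yields the fallback label (`unclassified`).  The semantics were chosen for
auditability — a curator can point at the one rule responsible for any
label.  Rules are data (YAML), not code, so another review group can swap
in patterns for its own conventions.  Each rule carries a `variable` key
(e.g. `blinding`, `allocation`) in addition to the source `field`, because
several variables are typically mined from the same methods field and a
single first-match pass could only produce one label.

The shipped rule file covers blinding (double/single/open), allocation
(randomised/quasi/unclear) and care setting; labels are lowercase text,
with an optional label→code table for exports that want numeric factors.
Numeric extraction is cue-anchored only: participant counts require `N=`
or a count followed (within two words) by a participant word; durations
require an explicit unit (weeks, days/7, months×4.345).  Bare numbers are
never used — for auto-curation, a missing value is cheaper than a wrong
one.

## Outcome-title ontology

"Unique title" means exact string equality after Unicode NFC normalization
and whitespace trim — harvesting is deliberately raw.  Grouping happens
only at the clustering step, on a *canonical form*: leading enumeration
("1.1 ") stripped, casefolded, punctuation dropped, whitespace collapsed.
Clustering is exact equality on that form; no edit-distance thresholds in
this version.  The resulting partition is deterministic and explainable,
which suits its purpose: a CSV worksheet a human curator fills in.  The
category vocabulary is user data in the mapping file, never hardcoded;
importing a filled worksheet validates categories against a declared list
when one is supplied, and untouched category columns import as an empty
mapping.

## Central dataset and queries

The central dataset flattens everything to one study table and one
outcome-row table, carrying the preserved plain text and the normalized
labels side by side.  Builds are deterministic: stable sort keys and an
injectable timestamp make rebuilds byte-identical.  A duplicate
(review, study) pair is a hard error — silent deduplication would corrupt
every downstream count.

Publication years resolve from the study id ("Name YYYY" convention;
rightmost plausible 4-digit token, so "Smith 1999a" parses), falling back
to the earliest reference year (the first report), else the study is
counted as undated.  The corpus-age query `fraction_older(k, ref)` is the
share of dated studies with `ref − year > k` — published strictly more
than k years before the reference; a study exactly k years old is not
"older".  Studies are counted once per (review, study) pair: a trial
included in two reviews contributes twice, matching the dataset's
review-centred granularity.  Participant totals are sums of parsed counts
only, with an explicit missing count — never imputed.

## Write-back

The contributed-outcomes list (every outcome table a study has a data row
in, deduplicated, in document order) is appended to the study's outcomes
characteristics field between sentinel XML comments carrying a tool tag
and version.  Re-runs replace the sentinel block rather than appending, so
injection is idempotent; stripping the blocks recovers the hand-written
content exactly.  Replace-via-sentinel was chosen over append because
hand-maintained lists drift — regeneration, not accretion, is the fix.
The flat "`title; title; …`" listing cannot represent titles that
themselves contain "; " (none of the shipped bank's do); the sentinel
block, not the listing, is the machine-readable boundary.  Writes go to a
temporary file moved into place, and in-place edits keep a mandatory
`.bak` copy.

## Synthetic corpus generator

Real review corpora cannot be redistributed, so the generator emulates
their structure with a ground-truth manifest as the oracle: every fact the
pipeline must recover (true N behind "N=120", canonical label behind each
blinding phrase, base title behind each surface variant, exact totals) is
recorded at generation time.  Defaults, chosen once as typical of the
review corpora this tooling targets:

| parameter | default | rationale |
|---|---|---|
| studies per review | 2–8 uniform | small trial sets dominate such corpora |
| reports per study | 1–3 | many-to-one publication is the norm |
| participants per study | 20–400, 10% missing | typical trial sizes; missingness exercises the never-impute path |
| publication years | decade mixture 1960–2015, weighted to recent decades | spans enough history for the corpus-age query to bite |
| blinding phrases | 16-form bank with true labels | covers the classic double/single/open variants plus an undescribed form |
| outcome titles | 37 base titles × up to 4 surface variants | variant count bounds the expected cluster count at exactly 37 |
| trial duration | 4–52 weeks from a fixed menu | common follow-up lengths |
| opaque subtrees | 30% of reviews get excluded-studies / prose blocks | exercises retention on every run |

Generation is deterministic: one seed yields byte-identical files and
manifest.  `corrupt_fixture` produces the three negative cases
(malformed XML, events>total, missing studies block) for error-path tests.

What the generator does **not** emulate: spelt-out numbers ("one hundred
participants"), tables reported only in prose, multi-arm (>2) trials,
cross-over designs, non-English text, and free text whose cue words
mislead (e.g. "N=120 screened, 80 randomised").  Passing tests therefore
demonstrate that the machinery is correct *given* the documented phrase
conventions, not that the shipped regexes would reach 100% on an arbitrary
real corpus — on real data the rule file is expected to need tailoring,
which is exactly why it is data.

## Problem sizes

The test suite runs on generated corpora of 20 reviews (unit level) and
200 reviews / ~1,000 studies (system level), with the round-trip property
checked over 100 generated reviews plus 60 hypothesis-generated arbitrary
models, and rule-priority behaviour checked against a brute-force
all-rules oracle over 1,000 randomized (ruleset, string) pairs.  The
acceptance script (`scripts/acceptance.py`) re-generates everything from
its `--seed` and completes in a few seconds.

## Known limitations

- The dialect is a documented subset; real RevMan exports carry many more
  blocks (footnotes, deep subgroup trees, sensitivity analyses), which
  round-trip opaquely but are invisible to queries.
- Only included studies are parsed; excluded/awaiting tables are retained
  but not modelled.
- Clustering by canonical form cannot merge synonyms ("death" vs
  "mortality"); that is the human curator's job by design.
- Numeric extraction reads the first cue-anchored match; documents with
  several conflicting counts keep only the first.
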
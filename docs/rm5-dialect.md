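# The `.rm5` dialect read and written by rm5kit

rm5kit reads a documented subset of the RevMan 5.3 save-file schema.  All
element and attribute names live in one mapping table
(`rm5kit.rm5_io.TAGS`), so the reader/writer can be re-pointed at another
RevMan dialect without code changes.  Anything outside this subset is
retained opaquely on read and re-emitted in original document order on
write.

## Element tree

```
COCHRANE_REVIEW                      @ID (review id, required), @REVMAN_VERSION
├── COVER_SHEET
│   └── TITLE                        review title (text, optional)
├── STUDIES_AND_REFERENCES
│   └── STUDIES                      required in strict mode
│       ├── INCLUDED_STUDIES
│       │   └── STUDY*               @ID = study id, convention "Name YYYY"
│       │       └── REFERENCE+       @ID = citation id  (>= 1 per study:
│       │           ├── TI           │  several reports per study is normal)
│       │           ├── SO           │  journal (optional)
│       │           └── YR           │  4-digit year, 1800..2100 (optional)
│       └── (EXCLUDED_STUDIES, AWAITING_STUDIES, ... retained opaquely)
├── CHARACTERISTICS_OF_STUDIES
│   └── CHARACTERISTICS_OF_INCLUDED_STUDIES
│       └── INCLUDED_CHAR*           @STUDY_ID
│           ├── CHAR_METHODS         each field holds mixed content: text,
│           ├── CHAR_PARTICIPANTS    inline markup (P, B, I, ...) and XML
│           ├── CHAR_INTERVENTIONS   comments, preserved verbatim; a field
│           ├── CHAR_OUTCOMES        is omitted when empty
│           └── CHAR_NOTES
├── RISK_OF_BIAS
│   └── ROB_TABLE*                   @STUDY_ID  (one table per study)
│       └── ROB_ENTRY*               @NAME = bias domain,
│                                    @RESULT in {LOW, HIGH, UNCLEAR};
│                                    element text = supporting quote
└── ANALYSES_AND_DATA
    └── COMPARISON*                  @ID (unique within review)
        ├── NAME                     comparison name (optional)
        ├── DICH_OUTCOME*            @ID; NAME child = outcome title
        │   └── DICH_DATA*           @STUDY_ID, @EVENTS_1, @TOTAL_1,
        │                            @EVENTS_2, @TOTAL_2  (ints >= 0,
        │                            events <= total per arm)
        └── CONT_OUTCOME*            @ID; NAME child = outcome title
            └── CONT_DATA*           @STUDY_ID, @MEAN_1, @SD_1, @TOTAL_1,
                                     @MEAN_2, @SD_2, @TOTAL_2 (sd, n >= 0)
```

Notes and deliberate simplifications relative to the full RevMan 5.3 schema:

- **Risk of bias per study.** RevMan groups quality items per review with
  per-study entries inside each item; this dialect stores one `ROB_TABLE`
  per study, which matches the per-study reading of the data and makes the
  round-trip ordering contract trivial.
- **Only included studies are parsed.** Excluded/awaiting-classification
  tables, PRISMA flow data, prose sections, meta-analysis results and
  figures are not modelled; unrecognized subtrees under the review root or
  the `STUDIES` container are retained opaquely for lossless write-back.
- **Encoding** is UTF-8 with entity decoding on read.  Optional leaf
  elements are omitted on write rather than emitted empty.  The five
  top-level section containers are structural and always present.
- **Equality contract** is canonical-XML equality (attribute order and
  serializer byte-layout normalized, comments kept), not byte equality.
- **Strict vs lenient reads.** `strict` raises on a missing `STUDIES`
  container and on any model-invariant violation (e.g. events > total);
  `lenient` (the default) logs and continues with empty collections.

Three annotated examples live in `docs/examples/`.
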
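"""Hypothesis strategies generating arbitrary valid Review models.

Strings are drawn from an XML-safe alphabet (letters, digits, space, a few
punctuation marks): control characters are illegal in XML 1.0, and
attribute-value normalization would legitimately rewrite tabs/newlines, so
they are outside the round-trip contract by construction.
"""

from xml.sax.saxutils import escape

from hypothesis import strategies as st

from rm5kit.model import (
    Characteristics,
    Comparison,
    DataType,
    Judgement,
    OutcomeDataRow,
    OutcomeTable,
    Reference,
    Review,
    RobEntry,
    Study,
)

_ALPHABET = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789 -.,:&<>'"

names = (
    st.text(alphabet=_ALPHABET, min_size=1, max_size=20)
    .map(str.strip)
    .filter(bool)
)
ids = st.text(alphabet=_ALPHABET.replace("&", "").replace("<", "").replace(">", ""),
              min_size=1, max_size=16).map(str.strip).filter(bool)
free_text = st.text(alphabet=_ALPHABET, max_size=60).map(escape)
# element content kept non-empty: an empty <P></P> legitimately re-serializes
# as <P/>, which is outside the verbatim-fragment contract
_inner = st.text(alphabet=_ALPHABET, min_size=1, max_size=60).map(escape)
fragments = st.one_of(
    free_text,
    _inner.map(lambda t: f"<P>{t}</P>"),
    st.tuples(_inner, _inner).map(lambda t: f"<P>{t[0]}<B>{t[1]}</B></P>"),
)
years = st.one_of(st.none(), st.integers(1800, 2100))


@st.composite
def references(draw, prefix):
    return Reference(
        citation_id=f"{prefix}-{draw(st.integers(1, 999))}",
        title=draw(names),
        year=draw(years),
        journal=draw(st.one_of(st.none(), names)),
    )


@st.composite
def characteristics(draw):
    return Characteristics(**{
        f: draw(fragments)
        for f in ("methods", "participants", "interventions", "outcomes", "notes")
    })


rob_entries = st.builds(
    RobEntry,
    item_name=names,
    judgement=st.sampled_from(list(Judgement)),
    support=st.one_of(st.just(""), names),
)


@st.composite
def dich_rows(draw, study_ids):
    t1 = draw(st.integers(0, 200))
    t2 = draw(st.integers(0, 200))
    return OutcomeDataRow(
        study_id=draw(st.sampled_from(study_ids)),
        arm1_events=draw(st.integers(0, t1)),
        arm1_total=t1,
        arm2_events=draw(st.integers(0, t2)),
        arm2_total=t2,
    )


@st.composite
def cont_rows(draw, study_ids):
    means = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)
    return OutcomeDataRow(
        study_id=draw(st.sampled_from(study_ids)),
        arm1_mean=draw(means),
        arm1_sd=draw(st.floats(0, 1e3, allow_nan=False)),
        arm1_n=draw(st.integers(0, 500)),
        arm2_mean=draw(means),
        arm2_sd=draw(st.floats(0, 1e3, allow_nan=False)),
        arm2_n=draw(st.integers(0, 500)),
    )


@st.composite
def outcome_tables(draw, study_ids, outcome_id):
    data_type = draw(st.sampled_from(list(DataType)))
    rows_strategy = (
        dich_rows(study_ids) if data_type is DataType.DICHOTOMOUS else cont_rows(study_ids)
    )
    rows = draw(st.lists(rows_strategy, max_size=4)) if study_ids else []
    # at most one row per study within a table
    seen, unique_rows = set(), []
    for r in rows:
        if r.study_id not in seen:
            seen.add(r.study_id)
            unique_rows.append(r)
    return OutcomeTable(
        outcome_id=outcome_id, title=draw(names), data_type=data_type, rows=unique_rows
    )


@st.composite
def reviews(draw):
    review_id = draw(ids)
    study_ids = draw(st.lists(ids, max_size=4, unique=True))
    studies = [
        Study(
            study_id=sid,
            references=draw(
                st.lists(references(prefix=sid), min_size=1, max_size=3)
            ),
            characteristics=draw(characteristics()),
            risk_of_bias=draw(st.lists(rob_entries, max_size=3)),
        )
        for sid in study_ids
    ]
    comparisons = []
    for c in range(draw(st.integers(0, 3))):
        n_out = draw(st.integers(0, 3))
        comparisons.append(
            Comparison(
                comparison_id=f"CMP-{c + 1:02d}",
                name=draw(st.one_of(st.just(""), names)),
                outcomes=[
                    draw(outcome_tables(study_ids, f"OUT-{c + 1:02d}.{o + 1:02d}"))
                    for o in range(n_out)
                ],
            )
        )
    return Review(
        review_id=review_id,
        title=draw(st.one_of(st.just(""), names)),
        studies=studies,
        comparisons=comparisons,
    )
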
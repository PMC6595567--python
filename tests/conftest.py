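import pytest

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
from rm5kit.rm5_io import read_batch
from rm5kit.synth import generate_corpus


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """A 20-review generated corpus with its ground-truth manifest."""
    out = tmp_path_factory.mktemp("corpus20")
    manifest = generate_corpus(seed=42, n_reviews=20, out_dir=out)
    return out, manifest


@pytest.fixture(scope="session")
def corpus_reviews(corpus):
    out, manifest = corpus
    batch = read_batch(out)
    assert not batch.failures
    return batch.reviews, manifest


def build_review(review_id="R-TEST", n_studies=3):
    """A small hand-built review: n studies, 2 comparisons, 5 outcome tables."""
    studies = []
    for i in range(n_studies):
        sid = f"Author {1990 + i}"
        studies.append(
            Study(
                study_id=sid,
                references=[
                    Reference(citation_id=f"{sid}-r1", title=f"Report of {sid}", year=1990 + i)
                ],
                characteristics=Characteristics(
                    methods="<P>Allocation: randomised. Blinding: double blind. "
                    "Duration: 12 weeks.</P>",
                    participants=f"<P>N={60 + 10 * i} inpatients with schizophrenia.</P>",
                ),
                risk_of_bias=[
                    RobEntry("Random sequence generation", Judgement.LOW, "stated")
                ],
            )
        )
    sids = [s.study_id for s in studies]
    comps = [
        Comparison(
            comparison_id="CMP-01",
            name="DRUG versus PLACEBO",
            outcomes=[
                OutcomeTable(
                    "OUT-01.01",
                    "Mental state",
                    DataType.DICHOTOMOUS,
                    rows=[
                        OutcomeDataRow(sid, arm1_events=5, arm1_total=30,
                                       arm2_events=9, arm2_total=30)
                        for sid in sids
                    ],
                ),
                OutcomeTable(
                    "OUT-01.02",
                    "Leaving the study early",
                    DataType.DICHOTOMOUS,
                    rows=[OutcomeDataRow(sids[0], arm1_events=2, arm1_total=30,
                                         arm2_events=3, arm2_total=30)],
                ),
                OutcomeTable(
                    "OUT-01.03",
                    "mental state",
                    DataType.DICHOTOMOUS,
                    rows=[OutcomeDataRow(sids[0], arm1_events=1, arm1_total=30,
                                         arm2_events=1, arm2_total=30)],
                ),
            ],
        ),
        Comparison(
            comparison_id="CMP-02",
            outcomes=[
                OutcomeTable(
                    "OUT-02.01",
                    "Average endpoint score (BPRS)",
                    DataType.CONTINUOUS,
                    rows=[
                        OutcomeDataRow(sids[-1], arm1_mean=30.5, arm1_sd=7.5, arm1_n=28,
                                       arm2_mean=35.0, arm2_sd=8.0, arm2_n=29)
                    ],
                ),
                OutcomeTable(
                    "OUT-02.02",
                    "Weight gain",
                    DataType.CONTINUOUS,
                    rows=[
                        OutcomeDataRow(sids[0], arm1_mean=2.1, arm1_sd=1.0, arm1_n=30,
                                       arm2_mean=0.4, arm2_sd=0.9, arm2_n=30)
                    ],
                ),
            ],
        ),
    ]
    return Review(review_id=review_id, title="Drug versus placebo", studies=studies,
                  comparisons=comps)


@pytest.fixture
def small_review():
    return build_review()
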
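"""Central dataset: conservation of counts, deterministic serialization,
exports, year resolution and the corpus-age and participant queries."""

import pytest

from rm5kit.central import (
    build_central,
    central_from_json,
    central_to_json,
    central_to_xml,
    export_tables,
    publication_year_histogram,
    resolve_study_year,
    sum_participants,
    ROW_COLUMNS,
    STUDY_COLUMNS,
)
from rm5kit.model import Characteristics, Reference, Review, Study
from rm5kit.ontology import OntologyMapping

from .conftest import build_review


def test_counts_conserved_from_parse_to_central(corpus_reviews):
    revs, manifest = corpus_reviews
    ds = build_central(revs, created="pinned")
    assert ds.source_count == manifest.n_reviews
    assert len(ds.studies) == manifest.totals["n_studies"]
    assert len(ds.outcome_rows) == manifest.totals["n_outcome_rows"]


def test_build_is_deterministic_under_input_shuffling(corpus_reviews):
    revs, _ = corpus_reviews
    a = central_to_xml(build_central(revs, created="pinned"))
    b = central_to_xml(build_central(list(reversed(revs)), created="pinned"))
    assert a == b


def test_duplicate_review_study_pair_is_a_hard_error(small_review):
    with pytest.raises(ValueError, match="duplicate"):
        build_central([small_review, small_review], created="pinned")


def test_empty_batch_builds_valid_dataset():
    ds = build_central([], created="pinned")
    assert ds.source_count == 0 and ds.studies == [] and ds.outcome_rows == []
    assert central_to_xml(ds).startswith(b"<?xml")


def test_free_text_and_labels_carried_side_by_side(small_review):
    ds = build_central([small_review], created="pinned")
    s = ds.studies[0]
    assert "double blind" in s.methods  # preserved plain text
    assert s.blinding == "double"  # normalized label alongside
    assert s.n_participants == 60


def test_csv_export_shapes_and_column_order(small_review, tmp_path):
    import pandas as pd

    ds = build_central([small_review], created="pinned")
    paths = export_tables(ds, tmp_path, fmt="csv")
    studies = pd.read_csv(paths["studies"])
    rows = pd.read_csv(paths["outcome_rows"])
    assert list(studies.columns) == STUDY_COLUMNS
    assert list(rows.columns) == ROW_COLUMNS
    assert len(studies) == len(ds.studies)
    assert len(rows) == len(ds.outcome_rows)


def test_json_roundtrip_preserves_all_fields(small_review):
    ds = build_central([small_review], created="pinned")
    assert central_from_json(central_to_json(ds)) == ds


def test_mapping_tags_rows(small_review):
    mapping = OntologyMapping(entries={"Mental state": ("mental state", "binary")})
    ds = build_central([small_review], mapping=mapping, created="pinned")
    tags = {r.outcome_title: r.category for r in ds.outcome_rows}
    assert tags["Mental state"] == "mental state"
    assert tags["Weight gain"] == "UNMAPPED"


@pytest.mark.parametrize(
    "study_id,ref_years,expected",
    [
        ("Smith 1999", [], 1999),
        ("Smith 1999a", [], 1999),  # trailing disambiguation letter
        ("van der Berg 2003 2005", [], 2005),  # rightmost token wins
        ("Smith trial", [2001, 1999], 1999),  # fallback: earliest report
        ("Smith trial", [], None),
    ],
)
def test_year_resolution_rules(study_id, ref_years, expected):
    study = Study(
        study_id=study_id,
        references=[Reference(citation_id=f"c{i}", year=y) for i, y in enumerate(ref_years)]
        or [Reference(citation_id="c0")],
    )
    assert resolve_study_year(study) == expected


def test_histogram_matches_manifest_distribution(corpus_reviews):
    revs, manifest = corpus_reviews
    ds = build_central(revs, created="pinned")
    ys = publication_year_histogram(ds)
    assert {str(y): c for y, c in ys.histogram.items()} == manifest.totals["year_histogram"]
    assert ys.total + ys.excluded == len(ds.studies)


def _review_with_years(review_id, years):
    return Review(
        review_id=review_id,
        studies=[
            Study(
                study_id=f"Author{i} {y}",
                references=[Reference(citation_id=f"{review_id}-{i}")],
                characteristics=Characteristics(),
            )
            for i, y in enumerate(years)
        ],
    )


def test_fraction_older_is_exact_on_constructed_half_split():
    # 4 studies >20y before the pinned reference year 2019, 4 at/after
    rev = _review_with_years("R1", [1980, 1985, 1990, 1995, 1999, 2005, 2010, 2015])
    ds = build_central([rev], created="pinned")
    ys = publication_year_histogram(ds)
    assert ys.fraction_older(20, reference_year=2019) == 0.5
    # boundary: published exactly 20 years before the reference is not "older"
    assert ys.fraction_older(20, reference_year=2019 - 4) == pytest.approx(3 / 8)


def test_sum_participants_arithmetic_and_missing():
    rev = _review_with_years("R1", [1990, 1995, 2000])
    for s, n in zip(rev.studies, [60, 120, 40]):
        s.characteristics = Characteristics(participants=f"<P>N={n} inpatients.</P>")
    ds = build_central([rev], created="pinned")
    assert sum_participants(ds)["R1"].total == 220
    assert sum_participants(ds)["R1"].missing == 0

    # all Ns absent
    bare = _review_with_years("R2", [1990, 1995])
    ds2 = build_central([bare], created="pinned")
    assert sum_participants(ds2)["R2"].total == 0
    assert sum_participants(ds2)["R2"].missing == 2

    # adding a study with N absent leaves the total unchanged, missing + 1
    rev.studies.append(
        Study(study_id="Extra 2001", references=[Reference(citation_id="e1")])
    )
    ds3 = build_central([rev], created="pinned")
    assert sum_participants(ds3)["R1"].total == 220
    assert sum_participants(ds3)["R1"].missing == 1
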
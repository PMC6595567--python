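"""Reader/writer contracts: manifest-exact extraction, lossless round-trip,
opaque retention, deterministic batching, and error paths."""

import shutil
from pathlib import Path

import pytest
from hypothesis import HealthCheck, given, settings

from rm5kit.model import Reference, Review, Study, ValidationError
from rm5kit.rm5_io import (
    Rm5ParseError,
    Rm5SchemaError,
    canonical_xml,
    read_batch,
    read_review,
    review_to_bytes,
    write_review,
)
from rm5kit.synth import corrupt_fixture

from .strategies import reviews

EXAMPLES = Path(__file__).parents[1] / "docs" / "examples"


def test_extraction_counts_match_manifest(corpus_reviews):
    revs, manifest = corpus_reviews
    by_id = {e["review_id"]: e for e in manifest.reviews}
    assert len(revs) == manifest.n_reviews
    for review in revs:
        entry = by_id[review.review_id]
        assert len(review.studies) == len(entry["studies"])
        assert sum(len(s.references) for s in review.studies) == sum(
            s["n_references"] for s in entry["studies"]
        )
        n_rows = sum(len(o.rows) for c in review.comparisons for o in c.outcomes)
        assert n_rows == sum(len(o["row_study_ids"]) for o in entry["outcomes"])


@settings(max_examples=60, deadline=None, suppress_health_check=[HealthCheck.too_slow])
@given(review=reviews())
def test_roundtrip_is_lossless_for_arbitrary_reviews(review, tmp_path_factory):
    """read(write(r)) reproduces r field-for-field over the supported subset."""
    tmp = tmp_path_factory.mktemp("rt")
    path = tmp / "r.rm5"
    write_review(review, path)
    back = read_review(path, schema_mode="strict")
    back.source_path = review.source_path
    assert back == review


def test_write_of_unedited_read_is_canonically_equal(corpus):
    out, _ = corpus
    for f in sorted(out.glob("*.rm5")):
        review = read_review(f, schema_mode="strict")
        assert canonical_xml(review_to_bytes(review)) == canonical_xml(f.read_bytes())


def test_retained_subtrees_round_trip(corpus):
    out, _ = corpus
    retained_seen = 0
    for f in sorted(out.glob("*.rm5")):
        review = read_review(f)
        retained_seen += len(review.unparsed_retained)
        if review.unparsed_retained:
            assert canonical_xml(review_to_bytes(review)) == canonical_xml(f.read_bytes())
    assert retained_seen > 0  # the generator does plant opaque subtrees


def test_batch_order_is_independent_of_filenames(corpus, tmp_path):
    out, manifest = corpus
    shuffled = tmp_path / "shuffled"
    shuffled.mkdir()
    # reverse the lexicographic file order without touching content
    files = sorted(out.glob("*.rm5"))
    for i, f in enumerate(files):
        shutil.copy(f, shuffled / f"z{len(files) - i:03d}.rm5")
    a = [r.review_id for r in read_batch(out).reviews]
    b = [r.review_id for r in read_batch(shuffled).reviews]
    assert a == b == sorted(a)


def test_batch_collects_per_file_failures(corpus, tmp_path):
    out, _ = corpus
    d = tmp_path / "mixed"
    d.mkdir()
    files = sorted(out.glob("*.rm5"))[:3]
    for f in files:
        shutil.copy(f, d / f.name)
    corrupt_fixture(d / files[0].name, "truncate")
    result = read_batch(d)
    assert len(result.reviews) == 2
    assert len(result.failures) == 1
    assert files[0].name in result.failures[0].path


def test_empty_directory_yields_empty_batch(tmp_path):
    assert read_batch(tmp_path).reviews == []


def test_minimal_file_with_zero_studies_reads_cleanly():
    review = read_review(EXAMPLES / "minimal.rm5")
    assert review.studies == [] and review.comparisons == []
    # strict also succeeds: the studies container is present
    read_review(EXAMPLES / "minimal.rm5", schema_mode="strict")


def test_example_files_parse_to_expected_shapes():
    single = read_review(EXAMPLES / "single-study.rm5", schema_mode="strict")
    assert [s.study_id for s in single.studies] == ["Smith 1999"]
    assert len(single.studies[0].references) == 2
    retained = read_review(EXAMPLES / "retained-subtrees.rm5", schema_mode="strict")
    assert len(retained.studies) == 2
    assert any("EXCLUDED_STUDIES" in r.xml for r in retained.unparsed_retained)


def test_truncated_file_raises_parse_error_with_offset(corpus, tmp_path):
    out, _ = corpus
    f = sorted(out.glob("*.rm5"))[0]
    bad = tmp_path / f.name
    shutil.copy(f, bad)
    corrupt_fixture(bad, "truncate")
    with pytest.raises(Rm5ParseError, match="byte offset"):
        read_review(bad)


def test_events_over_total_rejected_in_strict_mode(corpus, tmp_path):
    out, _ = corpus
    target = None
    for f in sorted(out.glob("*.rm5")):
        if b"DICH_DATA" in f.read_bytes():
            target = f
            break
    assert target is not None
    bad = tmp_path / target.name
    shutil.copy(target, bad)
    corrupt_fixture(bad, "bad_numbers")
    with pytest.raises(ValidationError, match="events exceed total"):
        read_review(bad, schema_mode="strict")
    # lenient keeps the data and only warns
    review = read_review(bad, schema_mode="lenient")
    assert review.studies


def test_missing_studies_block_strict_vs_lenient(corpus, tmp_path):
    out, _ = corpus
    f = sorted(out.glob("*.rm5"))[0]
    bad = tmp_path / f.name
    shutil.copy(f, bad)
    corrupt_fixture(bad, "missing_block")
    with pytest.raises(Rm5SchemaError, match="STUDIES_AND_REFERENCES/STUDIES"):
        read_review(bad, schema_mode="strict")
    assert read_review(bad, schema_mode="lenient").studies == []


def test_write_refuses_invalid_review_without_output(tmp_path):
    review = Review(
        review_id="BAD",
        studies=[Study(study_id="No refs 2000", references=[])],
    )
    path = tmp_path / "bad.rm5"
    with pytest.raises(ValidationError, match="no references"):
        write_review(review, path)
    assert not path.exists()


def test_dangling_outcome_row_study_id_is_invalid(small_review):
    small_review.comparisons[0].outcomes[0].rows[0].study_id = "Ghost 1900"
    with pytest.raises(ValidationError, match="does not resolve"):
        small_review.validate()


def test_reference_year_bounds():
    with pytest.raises(ValidationError, match="outside"):
        Reference(citation_id="x", year=1750).validate()
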
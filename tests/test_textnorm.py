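"""Rule-engine behaviour: canonical labels, priority order, totality, and the
cue-anchored numeric extractors."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rm5kit.model import Characteristics, Reference, Study
from rm5kit.synth import load_phrase_bank
from rm5kit.textnorm import (
    NormalizationRule,
    RuleConfigError,
    RuleSet,
    apply_rules,
    default_ruleset,
    extract_duration_weeks,
    extract_participants_total,
    load_ruleset,
    normalize_study,
)


@pytest.fixture(scope="module")
def rules():
    return default_ruleset()


@pytest.mark.parametrize("variant", ["double blind", "double-blind", "doubly blinded"])
def test_quoted_blinding_variants_map_to_double(rules, variant):
    text = f"Allocation: randomised. Blinding: {variant}."
    assert apply_rules(text, rules, "methods", "blinding") == "double"


def test_full_phrase_bank_normalizes_to_its_labels(rules):
    bank = load_phrase_bank()
    assert len(bank["blinding"]) >= 10
    for entry in bank["blinding"]:
        text = f"Blinding: {entry['phrase']}."
        assert apply_rules(text, rules, "methods", "blinding") == entry["label"], entry
    for entry in bank["allocation"]:
        text = f"Allocation: {entry['phrase']}."
        assert apply_rules(text, rules, "methods", "allocation") == entry["label"], entry


def test_no_match_and_empty_text_fall_back(rules):
    assert apply_rules("", rules, "methods", "blinding") == "unclassified"
    assert apply_rules("a 6-week trial", rules, "methods", "blinding") == "unclassified"


_words = st.sampled_from(
    ["blind", "double", "single", "open", "random", "trial", "weeks", "mask", "label"]
)


@settings(max_examples=200, deadline=None)
@given(
    data=st.data(),
    text=st.lists(_words, max_size=8).map(" ".join),
)
def test_priority_order_agrees_with_brute_force_oracle(data, text):
    """When several rules match, the lowest priority number must win: compare
    against an oracle that evaluates every rule and takes the minimum."""
    n = data.draw(st.integers(1, 8))
    priorities = data.draw(
        st.lists(st.integers(0, 100), min_size=n, max_size=n, unique=True)
    )
    ruleset = RuleSet(
        rules=[
            NormalizationRule(
                field="methods",
                variable="v",
                pattern=re.escape(data.draw(_words)),
                canonical=f"label{i}",
                priority=priorities[i],
            )
            for i in range(n)
        ]
    )
    ruleset.validate()
    matches = [
        r for r in ruleset.rules if re.search(r.pattern, text, re.IGNORECASE)
    ]
    expected = (
        min(matches, key=lambda r: r.priority).canonical
        if matches
        else ruleset.fallback_label
    )
    assert apply_rules(text, ruleset, "methods", "v") == expected


@pytest.mark.parametrize(
    "text,expected",
    [
        ("N=120 inpatients with schizophrenia", 120),
        ("n = 64 outpatients", 64),
        ("one hundred participants", None),  # numerals only
        ("12 weeks, N=60", 60),  # cue-anchored, not the first number
        ("120 acutely ill inpatients", 120),
        ("aged 18 to 65", None),  # bare numbers lacking a cue word
        ("", None),
    ],
)
def test_participant_extraction_is_cue_anchored(text, expected):
    assert extract_participants_total(text) == expected


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Duration: 12 weeks.", 12.0),
        ("followed for 14 days", 2.0),
        ("no duration stated", None),
    ],
)
def test_duration_extraction(text, expected):
    assert extract_duration_weeks(text) == expected


def _study(methods="", participants=""):
    return Study(
        study_id="Case 2000",
        references=[Reference(citation_id="c1")],
        characteristics=Characteristics(methods=methods, participants=participants),
    )


def test_normalize_study_combines_labels_and_numbers(rules):
    study = _study(
        methods="<P>Allocation: quasi-randomised. Blinding: single blind. "
        "Duration: 8 weeks.</P>",
        participants="<P>N=90 outpatients.</P>",
    )
    rec = normalize_study(study, rules)
    assert (rec.blinding, rec.allocation) == ("single", "quasi")
    assert rec.n_participants == 90 and rec.duration_weeks == 8.0
    assert rec.extras["setting"] == "outpatient"


def test_empty_characteristics_yield_fallbacks(rules):
    rec = normalize_study(_study(), rules)
    assert rec.blinding == rec.allocation == "unclassified"
    assert rec.n_participants is None and rec.duration_weeks is None


def test_identical_text_gives_identical_records(rules):
    a = normalize_study(_study(methods="<P>double blind</P>"), rules)
    b = normalize_study(_study(methods="<P>double blind</P>"), rules)
    assert a == b


def test_ruleset_file_validation(tmp_path):
    good = tmp_path / "rules.yaml"
    good.write_text(
        "name: t\nfallback: none\nrules:\n"
        "  - {field: methods, variable: v, pattern: 'a', label: x, priority: 5}\n"
        "  - {field: methods, variable: v, pattern: 'b', label: y, priority: 6}\n"
    )
    rs = load_ruleset(good)
    assert len(rs.rules) == 2 and rs.fallback_label == "none"

    dup = tmp_path / "dup.yaml"
    dup.write_text(
        "rules:\n"
        "  - {field: methods, variable: v, pattern: 'a', label: x, priority: 5}\n"
        "  - {field: methods, variable: v, pattern: 'b', label: y, priority: 5}\n"
    )
    with pytest.raises(RuleConfigError, match="duplicate priority 5"):
        load_ruleset(dup)

    bad = tmp_path / "bad.yaml"
    bad.write_text(
        "rules:\n  - {field: methods, variable: v, pattern: '(', label: x, priority: 1}\n"
    )
    with pytest.raises(RuleConfigError, match=re.escape("'('")):
        load_ruleset(bad)


def test_default_ruleset_declares_blinding_rules(rules):
    blinding = rules.select("methods", "blinding")
    assert len(blinding) >= 1
    assert any(r.canonical == "double" for r in blinding)
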
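"""Rule engine mapping messy characteristics free text onto canonical labels.

Review authors express the same trial attribute in many surface forms — a
double-blind trial may appear as "double blind", "double-blind" or "doubly
blinded".  The engine applies an ordered list of case-insensitive regular
expressions to the plain-text projection of a characteristics field and
returns the canonical label of the highest-priority match (lowest priority
number), falling back to a configured label when nothing matches.  Rules are
data, not code: a YAML file defines them, so other review groups can replace
the patterns with regex tailored to their own conventions.

Besides labels, two cue-anchored numeric extractors pull out the total number
of randomised participants (``N=120``, ``120 participants``) and the trial
duration in weeks.  Bare numbers without a cue word are never used: for
auto-curation, precision beats recall.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .model import CHARACTERISTIC_FIELDS, Study

__all__ = [
    "RuleConfigError",
    "NormalizationRule",
    "RuleSet",
    "NormalizedRecord",
    "apply_rules",
    "extract_participants_total",
    "extract_duration_weeks",
    "normalize_study",
    "load_ruleset",
    "default_ruleset",
]

DEFAULT_FALLBACK = "unclassified"


class RuleConfigError(ValueError):
    """A rule file violates the documented layout."""


@dataclass(frozen=True)
class NormalizationRule:
    """One ordered pattern: if ``pattern`` matches (case-insensitively) the
    plain text of characteristics field ``field``, the normalized value of
    ``variable`` is ``canonical``."""

    field: str
    variable: str
    pattern: str
    canonical: str
    priority: int

    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern, re.IGNORECASE)

    def validate(self) -> None:
        if self.field not in CHARACTERISTIC_FIELDS:
            raise RuleConfigError(
                f"rule {self.canonical!r}: field {self.field!r} is not one of "
                f"{CHARACTERISTIC_FIELDS}"
            )
        if not self.canonical:
            raise RuleConfigError(f"rule with pattern {self.pattern!r}: empty label")
        try:
            re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise RuleConfigError(
                f"rule {self.canonical!r}: pattern {self.pattern!r} does not "
                f"compile: {exc}"
            ) from exc


@dataclass
class RuleSet:
    """Ordered normalization rules with a fallback label.

    First-match-wins by ascending priority number; priorities are unique
    within a field so the order is strict.
    """

    name: str = "default"
    rules: list[NormalizationRule] = dc_field(default_factory=list)
    fallback_label: str = DEFAULT_FALLBACK
    label_codes: dict[str, int] = dc_field(default_factory=dict)

    def validate(self) -> None:
        seen: set[tuple[str, int]] = set()
        for rule in self.rules:
            rule.validate()
            key = (rule.field, rule.priority)
            if key in seen:
                raise RuleConfigError(
                    f"ruleset {self.name!r}: duplicate priority {rule.priority} "
                    f"within field {rule.field!r}"
                )
            seen.add(key)

    def select(self, field: str, variable: Optional[str] = None) -> list[NormalizationRule]:
        picked = [
            r
            for r in self.rules
            if r.field == field and (variable is None or r.variable == variable)
        ]
        return sorted(picked, key=lambda r: r.priority)

    def variables(self) -> list[tuple[str, str]]:
        """Distinct (variable, field) pairs in first-appearance order."""
        out: list[tuple[str, str]] = []
        for r in self.rules:
            key = (r.variable, r.field)
            if key not in out:
                out.append(key)
        return out


@dataclass
class NormalizedRecord:
    """Canonical labels and extracted numbers for one study."""

    study_id: str
    blinding: str = DEFAULT_FALLBACK
    allocation: str = DEFAULT_FALLBACK
    duration_weeks: Optional[float] = None
    n_participants: Optional[int] = None
    extras: dict[str, str] = dc_field(default_factory=dict)


def apply_rules(
    text: str,
    rules: RuleSet,
    field: str,
    variable: Optional[str] = None,
) -> str:
    """Return the canonical label of the highest-priority matching rule.

    Total and deterministic: every finite string yields a label — the
    fallback label when no rule matches.  Never raises on content.
    """
    for rule in rules.select(field, variable):
        if rule.compiled().search(text):
            return rule.canonical
    return rules.fallback_label


# --- numeric extractors -----------------------------------------------------

_N_EQ = re.compile(r"\bn\s*=\s*(\d+)", re.IGNORECASE)
_N_CUE = re.compile(
    r"\b(\d+)\s+(?:\w+\s+){0,2}?(?:participants?|patients?|people|in-?patients?|"
    r"out-?patients?|adults|subjects|individuals|men|women)\b",
    re.IGNORECASE,
)
_DURATION = re.compile(
    r"\b(\d+(?:\.\d+)?)\s*(weeks?|wks?|months?|days?)\b", re.IGNORECASE
)


def extract_participants_total(text: str) -> Optional[int]:
    """Parse the randomised-participant count from cue-anchored phrases.

    Accepts ``N=120`` (any spacing/case) and ``120 participants``-style
    phrases with up to two intervening words (``120 acutely ill inpatients``).
    Returns None when no confident match exists; bare numbers lacking a cue
    word are never used, and spelt-out numbers ("one hundred") are out of
    scope.
    """
    m = _N_EQ.search(text)
    if m:
        return int(m.group(1))
    m = _N_CUE.search(text)
    if m:
        return int(m.group(1))
    return None


def extract_duration_weeks(text: str) -> Optional[float]:
    """Parse a trial duration and convert it to weeks (days/7, months*4.345)."""
    m = _DURATION.search(text)
    if not m:
        return None
    value = float(m.group(1))
    unit = m.group(2).lower()
    if unit.startswith("w"):
        weeks = value
    elif unit.startswith("m"):
        weeks = value * 4.345
    else:
        weeks = value / 7.0
    return weeks


def normalize_study(study: Study, rules: RuleSet) -> NormalizedRecord:
    """Build one NormalizedRecord for a study.

    Each configured (variable, field) pair is resolved with
    :func:`apply_rules` against the plain-text projection of that field; the
    participant count is extracted from the participants field and the
    duration from the methods field.  The study's free text is never touched.
    """
    plain = study.characteristics.as_plain()
    record = NormalizedRecord(
        study_id=study.study_id,
        blinding=rules.fallback_label,
        allocation=rules.fallback_label,
    )
    for variable, field in rules.variables():
        label = apply_rules(plain[field], rules, field, variable)
        if variable == "blinding":
            record.blinding = label
        elif variable == "allocation":
            record.allocation = label
        else:
            record.extras[variable] = label
    record.n_participants = extract_participants_total(plain["participants"])
    record.duration_weeks = extract_duration_weeks(plain["methods"])
    return record


# --- rule file --------------------------------------------------------------

def _load_yaml(path_or_text: Union[str, Path], *, is_text: bool = False):
    if is_text:
        return yaml.safe_load(path_or_text)
    with open(path_or_text, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_ruleset(path: Union[str, Path]) -> RuleSet:
    """Load and validate a YAML rule file.

    Layout: top-level ``name``, ``fallback``, optional ``label_codes``
    (label -> integer code), and ``rules:`` — a list of
    ``{field, variable, pattern, label, priority}`` mappings.  Duplicate
    priorities within a field and non-compiling patterns are rejected with
    the offending rule named.
    """
    doc = _load_yaml(path)
    return _ruleset_from_doc(doc, source=str(path))


def _ruleset_from_doc(doc, source: str) -> RuleSet:
    if not isinstance(doc, dict) or "rules" not in doc:
        raise RuleConfigError(f"{source}: rule file must be a mapping with a 'rules' list")
    rules = []
    for i, item in enumerate(doc["rules"]):
        try:
            rules.append(
                NormalizationRule(
                    field=str(item["field"]),
                    variable=str(item.get("variable", item["field"])),
                    pattern=str(item["pattern"]),
                    canonical=str(item["label"]),
                    priority=int(item["priority"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise RuleConfigError(f"{source}: rule #{i + 1} malformed: {exc}") from exc
    rs = RuleSet(
        name=str(doc.get("name", "default")),
        rules=rules,
        fallback_label=str(doc.get("fallback", DEFAULT_FALLBACK)),
        label_codes={str(k): int(v) for k, v in (doc.get("label_codes") or {}).items()},
    )
    try:
        rs.validate()
    except RuleConfigError as exc:
        raise RuleConfigError(f"{source}: {exc}") from exc
    return rs


def default_ruleset() -> RuleSet:
    """The shipped rule file: blinding, allocation and setting rules tuned to
    the phrasing conventions of mental-health trial reviews."""
    text = resources.files("rm5kit.data").joinpath("default_rules.yaml").read_text("utf-8")
    return _ruleset_from_doc(yaml.safe_load(text), source="default_rules.yaml")
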
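"""In-memory data model for the supported subset of the RevMan 5 dialect.

A systematic review saved by RevMan 5 is one XML document holding (i) the
bibliographic references to the reports of each included study (often several
reports per study), (ii) one semi-structured "characteristics" table per study
with five free-text fields, (iii) one risk-of-bias table per study, and (iv)
the comparison/outcome data tables with per-study numeric rows (events/total
for dichotomous outcomes, mean/SD/N for continuous ones).

The classes below mirror exactly that subset.  Free-text fields keep their raw
inline markup (paragraph/emphasis tags, comments) so files round-trip
losslessly; :func:`plain_text` gives the tag-stripped projection used by the
rule engine and the outcome-title clustering.  XML subtrees outside the subset
are carried opaquely as :class:`RetainedSubtree` records and re-emitted on
write.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

__all__ = [
    "ValidationError",
    "Judgement",
    "DataType",
    "Reference",
    "Characteristics",
    "RobEntry",
    "OutcomeDataRow",
    "OutcomeTable",
    "Comparison",
    "Study",
    "RetainedSubtree",
    "Review",
    "plain_text",
]

YEAR_MIN, YEAR_MAX = 1800, 2100

_WS = re.compile(r"\s+")
_STRIP_PARSER = etree.XMLParser(remove_comments=True, resolve_entities=True)


class ValidationError(ValueError):
    """An object violates an invariant of the data model."""


class Judgement(str, enum.Enum):
    """Risk-of-bias judgement vocabulary."""

    LOW = "low"
    HIGH = "high"
    UNCLEAR = "unclear"


class DataType(str, enum.Enum):
    """Outcome data layout: event counts vs. mean/SD summaries."""

    DICHOTOMOUS = "dichotomous"
    CONTINUOUS = "continuous"


def plain_text(raw: str) -> str:
    """Project a raw inline-markup fragment onto plain text.

    Tags and XML comments are stripped, entities decoded, and whitespace
    collapsed to single spaces.  The projection is what the normalization
    rules and title clustering match against; the raw markup stays untouched
    in the model.
    """
    if not raw:
        return ""
    if "<" not in raw and "&" not in raw:
        return _WS.sub(" ", raw).strip()
    wrapped = f"<x>{raw}</x>"
    try:
        el = etree.fromstring(wrapped.encode("utf-8"), parser=_STRIP_PARSER)
    except etree.XMLSyntaxError as exc:  # malformed fragment: degrade, never raise
        raise ValidationError(f"free-text fragment is not well-formed XML: {exc}") from exc
    return _WS.sub(" ", "".join(el.itertext())).strip()


@dataclass
class Reference:
    """One report (publication) of a study; studies often have several."""

    citation_id: str
    title: str = ""
    year: Optional[int] = None
    journal: Optional[str] = None

    def validate(self) -> None:
        if not self.citation_id:
            raise ValidationError("reference citation_id must be non-empty")
        if self.year is not None and not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise ValidationError(
                f"reference {self.citation_id!r}: year {self.year} outside "
                f"[{YEAR_MIN}, {YEAR_MAX}]"
            )


#: fixed order of the five characteristics free-text fields
CHARACTERISTIC_FIELDS = ("methods", "participants", "interventions", "outcomes", "notes")


@dataclass
class Characteristics:
    """The five-field semi-structured 'characteristics of included studies' table.

    Each field holds the raw inline-markup fragment; all five are always
    present (possibly empty).
    """

    methods: str = ""
    participants: str = ""
    interventions: str = ""
    outcomes: str = ""
    notes: str = ""

    def get(self, name: str) -> str:
        if name not in CHARACTERISTIC_FIELDS:
            raise KeyError(name)
        return getattr(self, name)

    def set(self, name: str, value: str) -> None:
        if name not in CHARACTERISTIC_FIELDS:
            raise KeyError(name)
        setattr(self, name, value)

    def as_plain(self) -> dict[str, str]:
        return {f: plain_text(getattr(self, f)) for f in CHARACTERISTIC_FIELDS}


@dataclass
class RobEntry:
    """One row of a study's risk-of-bias table."""

    item_name: str
    judgement: Judgement
    support: str = ""

    def __post_init__(self) -> None:
        self.judgement = Judgement(self.judgement)

    def validate(self) -> None:
        if not self.item_name:
            raise ValidationError("risk-of-bias item_name must be non-empty")


@dataclass
class OutcomeDataRow:
    """One study's numeric contribution to an outcome table.

    Dichotomous rows carry events/total per arm; continuous rows carry
    mean/SD/N per arm.  Any field may be absent.
    """

    study_id: str
    arm1_events: Optional[int] = None
    arm1_total: Optional[int] = None
    arm2_events: Optional[int] = None
    arm2_total: Optional[int] = None
    arm1_mean: Optional[float] = None
    arm1_sd: Optional[float] = None
    arm1_n: Optional[int] = None
    arm2_mean: Optional[float] = None
    arm2_sd: Optional[float] = None
    arm2_n: Optional[int] = None

    def validate(self, data_type: DataType) -> None:
        if not self.study_id:
            raise ValidationError("outcome data row study_id must be non-empty")
        if data_type is DataType.DICHOTOMOUS:
            for arm, ev, tot in (
                (1, self.arm1_events, self.arm1_total),
                (2, self.arm2_events, self.arm2_total),
            ):
                for name, v in ((f"arm{arm}_events", ev), (f"arm{arm}_total", tot)):
                    if v is not None and v < 0:
                        raise ValidationError(f"{name} is negative for {self.study_id!r}")
                if ev is not None and tot is not None and ev > tot:
                    raise ValidationError(
                        f"events exceed total (arm {arm}: {ev} > {tot}) "
                        f"for study {self.study_id!r}"
                    )
        else:
            for name, v in (
                ("arm1_sd", self.arm1_sd),
                ("arm2_sd", self.arm2_sd),
                ("arm1_n", self.arm1_n),
                ("arm2_n", self.arm2_n),
            ):
                if v is not None and v < 0:
                    raise ValidationError(f"{name} is negative for {self.study_id!r}")


@dataclass
class OutcomeTable:
    """A labelled outcome with its per-study numeric rows."""

    outcome_id: str
    title: str
    data_type: DataType
    rows: list[OutcomeDataRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data_type = DataType(self.data_type)

    def validate(self) -> None:
        if not self.outcome_id:
            raise ValidationError("outcome_id must be non-empty")
        if not self.title or not self.title.strip():
            raise ValidationError(f"outcome {self.outcome_id!r}: title must be non-empty")
        for row in self.rows:
            row.validate(self.data_type)


@dataclass
class Comparison:
    comparison_id: str
    name: str = ""
    outcomes: list[OutcomeTable] = field(default_factory=list)

    def validate(self) -> None:
        if not self.comparison_id:
            raise ValidationError("comparison_id must be non-empty")
        seen: set[str] = set()
        for o in self.outcomes:
            o.validate()
            if o.outcome_id in seen:
                raise ValidationError(
                    f"duplicate outcome_id {o.outcome_id!r} in comparison "
                    f"{self.comparison_id!r}"
                )
            seen.add(o.outcome_id)


@dataclass
class Study:
    """An included study: identifier, linked reports, characteristics, risk of bias."""

    study_id: str
    references: list[Reference] = field(default_factory=list)
    characteristics: Characteristics = field(default_factory=Characteristics)
    risk_of_bias: list[RobEntry] = field(default_factory=list)

    def validate(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be non-empty")
        if not self.references:
            raise ValidationError(f"study {self.study_id!r} has no references")
        for r in self.references:
            r.validate()
        for e in self.risk_of_bias:
            e.validate()


@dataclass
class RetainedSubtree:
    """An XML subtree outside the supported subset, kept opaquely for round-trip.

    ``parent`` is a symbolic container key (see :mod:`rm5kit.rm5_io`), ``index``
    the child position in the original document, ``xml`` the canonicalized
    serialization of the subtree.
    """

    parent: str
    index: int
    xml: str


@dataclass
class Review:
    """One parsed .rm5 file over the supported subset."""

    review_id: str
    title: str = ""
    studies: list[Study] = field(default_factory=list)
    comparisons: list[Comparison] = field(default_factory=list)
    source_path: str = ""
    unparsed_retained: list[RetainedSubtree] = field(default_factory=list)

    def study(self, study_id: str) -> Study:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(f"no study {study_id!r} in review {self.review_id!r}")

    def validate(self) -> None:
        if not self.review_id:
            raise ValidationError("review_id must be non-empty")
        ids: set[str] = set()
        for s in self.studies:
            s.validate()
            if s.study_id in ids:
                raise ValidationError(
                    f"duplicate study_id {s.study_id!r} in review {self.review_id!r}"
                )
            ids.add(s.study_id)
        comp_ids: set[str] = set()
        for c in self.comparisons:
            c.validate()
            if c.comparison_id in comp_ids:
                raise ValidationError(
                    f"duplicate comparison_id {c.comparison_id!r} in review "
                    f"{self.review_id!r}"
                )
            comp_ids.add(c.comparison_id)
            for o in c.outcomes:
                for row in o.rows:
                    if row.study_id not in ids:
                        raise ValidationError(
                            f"outcome row study_id {row.study_id!r} (outcome "
                            f"{o.outcome_id!r}) does not resolve to an included study"
                        )
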
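"""Marshal a parsed batch into one central, queryable dataset.

Each review keeps its extracted data locked inside its own file; the point of
batch processing is one flat dataset over the whole corpus.  The central
dataset carries, side by side, the preserved free text (as plain-text
projections) and the normalized labels, one flattened record per study and
one per outcome data row, plus ontology tags where a curated mapping is
supplied.  It serializes to a versioned XML document, to CSV tables and to
JSON, and answers the corpus-level queries the flat layout exists for:
publication-year histograms ("how old is the evidence?") and per-review
participant totals.

Builds are deterministic: records are sorted on stable keys and the creation
timestamp is injectable, so the same batch always yields byte-identical XML.
"""

from __future__ import annotations

import json
import re
import statistics
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from lxml import etree

from .model import Review, Study, CHARACTERISTIC_FIELDS
from .ontology import UNMAPPED, OntologyMapping, harvest_titles, normalize_title
from .textnorm import NormalizedRecord, RuleSet, default_ruleset, normalize_study

__all__ = [
    "StudyRecord",
    "OutcomeRowRecord",
    "CentralDataset",
    "YearStats",
    "ParticipantSummary",
    "MappingReport",
    "build_central",
    "apply_mapping",
    "mapping_report",
    "central_to_xml",
    "central_to_json",
    "central_from_json",
    "export_tables",
    "resolve_study_year",
    "publication_year_histogram",
    "sum_participants",
]

SCHEMA_VERSION = "1.0"

_YEAR_TOKEN = re.compile(r"\d{4}")


@dataclass
class StudyRecord:
    """One flattened study: identity, year, free text, labels, risk of bias."""

    review_id: str
    study_id: str
    year: Optional[int]
    reference_years: list[int]
    methods: str
    participants: str
    interventions: str
    outcomes: str
    notes: str
    blinding: str
    allocation: str
    duration_weeks: Optional[float]
    n_participants: Optional[int]
    extras: dict[str, str]
    risk_of_bias: list[dict[str, str]]


@dataclass
class OutcomeRowRecord:
    """One flattened outcome data row with its review/comparison/outcome
    context and ontology tag."""

    review_id: str
    comparison_id: str
    outcome_id: str
    outcome_title: str
    data_type: str
    category: str
    subcategory: Optional[str]
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


@dataclass
class CentralDataset:
    created: str
    source_count: int
    studies: list[StudyRecord] = field(default_factory=list)
    outcome_rows: list[OutcomeRowRecord] = field(default_factory=list)


def resolve_study_year(study: Study) -> Optional[int]:
    """Publication year of a study.

    Cochrane study IDs follow the "Name YYYY" convention (with an optional
    disambiguation letter, "Smith 1999a"); the rightmost 4-digit token in
    the plausible range wins.  Failing that, the earliest reference year
    (the first report) is used; with neither, the study has no year.
    """
    candidates = [
        int(m.group(0))
        for m in _YEAR_TOKEN.finditer(study.study_id)
        if 1800 <= int(m.group(0)) <= 2100
    ]
    if candidates:
        return candidates[-1]
    ref_years = [r.year for r in study.references if r.year is not None]
    if ref_years:
        return min(ref_years)
    return None


def build_central(
    reviews: Sequence[Review],
    records: Optional[dict[str, dict[str, NormalizedRecord]]] = None,
    mapping: Optional[OntologyMapping] = None,
    ruleset: Optional[RuleSet] = None,
    created: Optional[str] = None,
) -> CentralDataset:
    """Flatten a batch of reviews (plus normalization and optional ontology
    mapping) into one deterministic CentralDataset.

    ``records`` maps review_id -> study_id -> NormalizedRecord; when absent,
    studies are normalized here with ``ruleset`` (default: the shipped rule
    file).  A duplicate (review_id, study_id) pair is a hard error naming
    the collision.  Records are sorted on (review_id, study_id) and outcome
    rows on (review_id, comparison_id, outcome_id, study_id); pass a pinned
    ``created`` timestamp for byte-identical rebuilds.
    """
    if created is None:
        created = datetime.now(timezone.utc).isoformat(timespec="seconds")
    if ruleset is None and records is None:
        ruleset = default_ruleset()

    ds = CentralDataset(created=created, source_count=len(reviews))
    seen: set[tuple[str, str]] = set()
    for review in reviews:
        for study in review.studies:
            key = (review.review_id, study.study_id)
            if key in seen:
                raise ValueError(
                    f"duplicate (review_id, study_id) {key!r} in central build"
                )
            seen.add(key)
            if records is not None:
                rec = records[review.review_id][study.study_id]
            else:
                rec = normalize_study(study, ruleset)
            plain = study.characteristics.as_plain()
            ds.studies.append(
                StudyRecord(
                    review_id=review.review_id,
                    study_id=study.study_id,
                    year=resolve_study_year(study),
                    reference_years=[r.year for r in study.references if r.year is not None],
                    blinding=rec.blinding,
                    allocation=rec.allocation,
                    duration_weeks=rec.duration_weeks,
                    n_participants=rec.n_participants,
                    extras=dict(sorted(rec.extras.items())),
                    risk_of_bias=[
                        {"item": e.item_name, "judgement": e.judgement.value, "support": e.support}
                        for e in study.risk_of_bias
                    ],
                    **plain,
                )
            )
        for comp in review.comparisons:
            for outcome in comp.outcomes:
                title = normalize_title(outcome.title)
                if mapping is not None:
                    category, sub = mapping.lookup(title)
                else:
                    category, sub = UNMAPPED, None
                for row in outcome.rows:
                    ds.outcome_rows.append(
                        OutcomeRowRecord(
                            review_id=review.review_id,
                            comparison_id=comp.comparison_id,
                            outcome_id=outcome.outcome_id,
                            outcome_title=title,
                            data_type=outcome.data_type.value,
                            category=category,
                            subcategory=sub,
                            study_id=row.study_id,
                            arm1_events=row.arm1_events,
                            arm1_total=row.arm1_total,
                            arm2_events=row.arm2_events,
                            arm2_total=row.arm2_total,
                            arm1_mean=row.arm1_mean,
                            arm1_sd=row.arm1_sd,
                            arm1_n=row.arm1_n,
                            arm2_mean=row.arm2_mean,
                            arm2_sd=row.arm2_sd,
                            arm2_n=row.arm2_n,
                        )
                    )
    ds.studies.sort(key=lambda s: (s.review_id, s.study_id))
    ds.outcome_rows.sort(
        key=lambda r: (r.review_id, r.comparison_id, r.outcome_id, r.study_id)
    )
    return ds


def apply_mapping(
    reviews: Sequence[Review],
    mapping: OntologyMapping,
    created: Optional[str] = None,
) -> tuple[CentralDataset, "MappingReport"]:
    """Annotate a batch with a curated ontology mapping.

    Returns the tagged central dataset together with the run report counting
    unmapped titles and occurrences.
    """
    ds = build_central(reviews, mapping=mapping, created=created)
    return ds, mapping_report(reviews, mapping)


@dataclass
class MappingReport:
    """Coverage of an ontology mapping over a corpus."""

    total_titles: int
    unmapped_titles: int
    total_occurrences: int
    unmapped_occurrences: int

    @property
    def unmapped_title_fraction(self) -> float:
        return self.unmapped_titles / self.total_titles if self.total_titles else 0.0

    @property
    def unmapped_occurrence_fraction(self) -> float:
        return (
            self.unmapped_occurrences / self.total_occurrences
            if self.total_occurrences
            else 0.0
        )


def mapping_report(reviews: Sequence[Review], mapping: OntologyMapping) -> MappingReport:
    records = harvest_titles(reviews)
    unmapped = [r for r in records if mapping.lookup(r.raw_title)[0] == UNMAPPED]
    return MappingReport(
        total_titles=len(records),
        unmapped_titles=len(unmapped),
        total_occurrences=sum(r.count for r in records),
        unmapped_occurrences=sum(r.count for r in unmapped),
    )


# ---------------------------------------------------------------------------
# serialization

def _set_opt(el: etree._Element, attr: str, value) -> None:
    if value is not None:
        el.set(attr, str(value))


def central_to_xml(ds: CentralDataset) -> bytes:
    """Serialize to the versioned central XML schema (see docs)."""
    root = etree.Element("RM5KIT_CENTRAL")
    root.set("VERSION", SCHEMA_VERSION)
    root.set("CREATED", ds.created)
    root.set("SOURCE_COUNT", str(ds.source_count))
    studies_el = etree.SubElement(root, "STUDIES")
    for s in ds.studies:
        s_el = etree.SubElement(studies_el, "STUDY")
        s_el.set("REVIEW_ID", s.review_id)
        s_el.set("ID", s.study_id)
        _set_opt(s_el, "YEAR", s.year)
        s_el.set("BLINDING", s.blinding)
        s_el.set("ALLOCATION", s.allocation)
        _set_opt(s_el, "DURATION_WEEKS", s.duration_weeks)
        _set_opt(s_el, "N_PARTICIPANTS", s.n_participants)
        if s.reference_years:
            s_el.set("REFERENCE_YEARS", " ".join(str(y) for y in s.reference_years))
        for name in CHARACTERISTIC_FIELDS:
            text = getattr(s, name)
            if text:
                etree.SubElement(s_el, name.upper()).text = text
        for k, v in s.extras.items():
            e = etree.SubElement(s_el, "EXTRA")
            e.set("NAME", k)
            e.set("VALUE", v)
        for rob in s.risk_of_bias:
            r_el = etree.SubElement(s_el, "ROB")
            r_el.set("ITEM", rob["item"])
            r_el.set("JUDGEMENT", rob["judgement"])
            if rob["support"]:
                r_el.text = rob["support"]
    rows_el = etree.SubElement(root, "OUTCOME_ROWS")
    for r in ds.outcome_rows:
        r_el = etree.SubElement(rows_el, "ROW")
        r_el.set("REVIEW_ID", r.review_id)
        r_el.set("COMPARISON_ID", r.comparison_id)
        r_el.set("OUTCOME_ID", r.outcome_id)
        r_el.set("TITLE", r.outcome_title)
        r_el.set("DATA_TYPE", r.data_type)
        r_el.set("CATEGORY", r.category)
        _set_opt(r_el, "SUBCATEGORY", r.subcategory)
        r_el.set("STUDY_ID", r.study_id)
        for attr, v in (
            ("EVENTS_1", r.arm1_events),
            ("TOTAL_1", r.arm1_total if r.data_type == "dichotomous" else r.arm1_n),
            ("EVENTS_2", r.arm2_events),
            ("TOTAL_2", r.arm2_total if r.data_type == "dichotomous" else r.arm2_n),
            ("MEAN_1", r.arm1_mean),
            ("SD_1", r.arm1_sd),
            ("MEAN_2", r.arm2_mean),
            ("SD_2", r.arm2_sd),
        ):
            _set_opt(r_el, attr, v)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8")


def central_to_json(ds: CentralDataset) -> str:
    doc = {
        "version": SCHEMA_VERSION,
        "created": ds.created,
        "source_count": ds.source_count,
        "studies": [asdict(s) for s in ds.studies],
        "outcome_rows": [asdict(r) for r in ds.outcome_rows],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False)


def central_from_json(text: str) -> CentralDataset:
    doc = json.loads(text)
    return CentralDataset(
        created=doc["created"],
        source_count=doc["source_count"],
        studies=[StudyRecord(**s) for s in doc["studies"]],
        outcome_rows=[OutcomeRowRecord(**r) for r in doc["outcome_rows"]],
    )


STUDY_COLUMNS = [
    "review_id", "study_id", "year", "blinding", "allocation",
    "duration_weeks", "n_participants",
    "methods", "participants", "interventions", "outcomes", "notes",
]
ROW_COLUMNS = [
    "review_id", "comparison_id", "outcome_id", "outcome_title", "data_type",
    "category", "subcategory", "study_id",
    "arm1_events", "arm1_total", "arm2_events", "arm2_total",
    "arm1_mean", "arm1_sd", "arm1_n", "arm2_mean", "arm2_sd", "arm2_n",
]


def export_tables(
    ds: CentralDataset, out_dir: Union[str, Path], fmt: str = "csv"
) -> dict[str, Path]:
    """Write the studies table and the outcome-rows table.

    CSV (RFC-4180, UTF-8) with the documented stable column order, or JSON
    mirroring the XML structure.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        studies = pd.DataFrame([asdict(s) for s in ds.studies])
        rows = pd.DataFrame([asdict(r) for r in ds.outcome_rows])
        studies = studies.reindex(columns=STUDY_COLUMNS)
        rows = rows.reindex(columns=ROW_COLUMNS)
        paths = {
            "studies": out_dir / "studies.csv",
            "outcome_rows": out_dir / "outcome_rows.csv",
        }
        studies.to_csv(paths["studies"], index=False)
        rows.to_csv(paths["outcome_rows"], index=False)
    elif fmt == "json":
        paths = {"central": out_dir / "central.json"}
        paths["central"].write_text(central_to_json(ds), encoding="utf-8")
    else:
        raise ValueError(f"fmt must be 'csv' or 'json', got {fmt!r}")
    return paths


# ---------------------------------------------------------------------------
# corpus-level queries

@dataclass
class YearStats:
    """Publication-year distribution over the dataset's studies.

    Each (review, study) pair contributes one year; studies without a
    resolvable year are counted in ``excluded``.
    """

    histogram: dict[int, int]
    excluded: int

    @property
    def total(self) -> int:
        return sum(self.histogram.values())

    @property
    def median_year(self) -> Optional[float]:
        years = [y for y, c in self.histogram.items() for _ in range(c)]
        return statistics.median(years) if years else None

    def fraction_older(self, years: int, reference_year: int) -> float:
        """Fraction of dated studies published more than ``years`` years
        before ``reference_year`` (the corpus-age query: e.g. what share of
        the evidence is over two decades old)."""
        if not self.total:
            return 0.0
        older = sum(c for y, c in self.histogram.items() if reference_year - y > years)
        return older / self.total


def publication_year_histogram(ds: CentralDataset) -> YearStats:
    hist: dict[int, int] = {}
    excluded = 0
    for s in ds.studies:
        if s.year is None:
            excluded += 1
        else:
            hist[s.year] = hist.get(s.year, 0) + 1
    return YearStats(histogram=dict(sorted(hist.items())), excluded=excluded)


@dataclass
class ParticipantSummary:
    total: int
    n_studies: int
    missing: int


def sum_participants(ds: CentralDataset) -> dict[str, ParticipantSummary]:
    """Per-review participant totals over studies with a parsed count.

    Counts are summed, never imputed; studies lacking a parsed N are counted
    under ``missing``.
    """
    out: dict[str, ParticipantSummary] = {}
    for s in ds.studies:
        summary = out.setdefault(s.review_id, ParticipantSummary(0, 0, 0))
        summary.n_studies += 1
        if s.n_participants is None:
            summary.missing += 1
        else:
            summary.total += s.n_participants
    return out
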
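"""Outcome-title harvesting, clustering, and curated-mapping application.

Across a corpus of reviews the free-text titles of outcome tables are wildly
inconsistent (thousands of unique strings for a few dozen underlying
outcomes).  This module (i) harvests every title with its occurrence count,
(ii) groups titles whose *canonical form* — casefolded, punctuation-stripped,
whitespace-collapsed, leading enumeration removed — coincides, (iii) exports
the clusters as a CSV worksheet for a human curator, and (iv) applies a
curated title -> (category, subcategory) mapping back onto the dataset.

Clustering is deliberately exact on the canonical form: no edit-distance
thresholds.  The clusters must be explainable to the curator who signs off
the ontology, and a deterministic partition is what makes the worksheet
reviewable.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .model import Review, plain_text

__all__ = [
    "TitleRecord",
    "OntologyMapping",
    "MappingImportError",
    "UNMAPPED",
    "normalize_title",
    "canonical_form",
    "harvest_titles",
    "cluster_titles",
    "export_worksheet",
    "import_mapping",
]

UNMAPPED = "UNMAPPED"

WORKSHEET_COLUMNS = ["raw_title", "canonical_form", "count", "category", "subcategory"]

_ENUM_PREFIX = re.compile(r"^\s*\d+(?:\.\d+)*\.?\s+")
_PUNCT = re.compile(r"[^\w\s]+", re.UNICODE)
_WS = re.compile(r"\s+")


class MappingImportError(ValueError):
    """A curation worksheet/mapping file violates the documented layout."""


def normalize_title(raw: str) -> str:
    """Raw uniqueness key: Unicode NFC plus leading/trailing whitespace trim.

    This is deliberately conservative — two titles are "the same" only if
    their strings coincide after NFC and trim; anything fuzzier belongs to
    the clustering step.
    """
    return unicodedata.normalize("NFC", raw).strip()


def canonical_form(title: str) -> str:
    """Cluster key: strip a leading enumeration ("1.1 "), casefold, drop
    punctuation, collapse whitespace."""
    t = unicodedata.normalize("NFC", title)
    t = _ENUM_PREFIX.sub("", t)
    t = t.casefold()
    t = _PUNCT.sub(" ", t)
    return _WS.sub(" ", t).strip()


@dataclass
class TitleRecord:
    """One distinct raw outcome title with its corpus-wide usage."""

    raw_title: str
    canonical_form: str
    count: int
    source_reviews: list[str] = field(default_factory=list)


def harvest_titles(reviews: Iterable[Review]) -> list[TitleRecord]:
    """Collect every outcome title across the corpus.

    One record per distinct raw title (after NFC + trim), counting every
    (review, comparison, outcome) occurrence; records sorted by descending
    count, then title.  The sum of counts equals the total number of outcome
    tables in the corpus.
    """
    counts: dict[str, int] = {}
    sources: dict[str, set[str]] = {}
    for review in reviews:
        for comp in review.comparisons:
            for outcome in comp.outcomes:
                key = normalize_title(plain_text(outcome.title))
                counts[key] = counts.get(key, 0) + 1
                sources.setdefault(key, set()).add(review.review_id)
    records = [
        TitleRecord(
            raw_title=t,
            canonical_form=canonical_form(t),
            count=c,
            source_reviews=sorted(sources[t]),
        )
        for t, c in counts.items()
    ]
    records.sort(key=lambda r: (-r.count, r.raw_title))
    return records


def cluster_titles(records: Sequence[TitleRecord]) -> list[list[TitleRecord]]:
    """Partition records into clusters of equal canonical form.

    Every record lands in exactly one cluster; clusters are sorted by
    descending total count then canonical form, members by descending count
    then title.
    """
    groups: dict[str, list[TitleRecord]] = {}
    for rec in records:
        groups.setdefault(rec.canonical_form, []).append(rec)
    clusters = list(groups.values())
    for cl in clusters:
        cl.sort(key=lambda r: (-r.count, r.raw_title))
    clusters.sort(key=lambda cl: (-sum(r.count for r in cl), cl[0].canonical_form))
    return clusters


@dataclass
class OntologyMapping:
    """Curated raw title -> (category, subcategory) assignments.

    Unmapped titles are simply absent.  When ``categories`` is non-empty it
    is the declared vocabulary and imports reject anything outside it.
    """

    entries: dict[str, tuple[str, Optional[str]]] = field(default_factory=dict)
    categories: list[str] = field(default_factory=list)

    def lookup(self, raw_title: str) -> tuple[str, Optional[str]]:
        return self.entries.get(normalize_title(raw_title), (UNMAPPED, None))

    def __len__(self) -> int:
        return len(self.entries)


def export_worksheet(
    clusters: Sequence[Sequence[TitleRecord]], path: Union[str, Path]
) -> None:
    """Write the curation worksheet CSV (UTF-8, fixed header).

    One row per raw title, cluster-contiguous, with empty category and
    subcategory columns for the curator to fill in (e.g. in a spreadsheet
    program).
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(WORKSHEET_COLUMNS)
        for cluster in clusters:
            for rec in cluster:
                writer.writerow([rec.raw_title, rec.canonical_form, rec.count, "", ""])


def import_mapping(
    path: Union[str, Path],
    allowed_categories: Optional[Sequence[str]] = None,
) -> OntologyMapping:
    """Read a filled-in worksheet back as an OntologyMapping.

    Rows whose category column is empty stay unmapped (an export/import
    round trip with untouched category columns yields an empty mapping).
    With ``allowed_categories`` given, rows using any other category are
    rejected together, with their row numbers listed.
    """
    mapping = OntologyMapping(categories=list(allowed_categories or []))
    bad_rows: list[str] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in WORKSHEET_COLUMNS[:3] + ["category"] if c not in (reader.fieldnames or [])]
        if missing:
            raise MappingImportError(f"{path}: worksheet lacks columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            category = (row.get("category") or "").strip()
            if not category:
                continue
            if mapping.categories and category not in mapping.categories:
                bad_rows.append(f"row {lineno}: unknown category {category!r}")
                continue
            sub = (row.get("subcategory") or "").strip() or None
            mapping.entries[normalize_title(row["raw_title"])] = (category, sub)
    if bad_rows:
        raise MappingImportError(f"{path}: " + "; ".join(bad_rows))
    return mapping
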
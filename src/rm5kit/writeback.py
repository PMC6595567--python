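"""Feed curated content back into source .rm5 files, idempotently.

Review authors conventionally list, in each study's characteristics table,
the outcomes that study contributed data to — a hand-maintained list and a
common source of errors and inconsistencies.  This module regenerates it:
:func:`contributed_outcomes` collects the titles of every outcome table a
study has a data row in, and :func:`inject_outcome_lists` appends that list
to the study's characteristics field between machine-readable sentinel
comments.  Because re-runs replace the sentinel block instead of appending,
injection is idempotent, and stripping the blocks recovers the original file
exactly.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .model import Review, plain_text
from .ontology import normalize_title
from .rm5_io import read_review, review_to_bytes, xml_escape

__all__ = [
    "SENTINEL_OPEN",
    "SENTINEL_CLOSE",
    "EditReport",
    "contributed_outcomes",
    "render_block",
    "strip_blocks",
    "extract_injected",
    "inject_review",
    "inject_outcome_lists",
]

# Sentinel comments carry a tool tag and version so re-runs can find and
# replace exactly the generated block, never hand-written text.
SENTINEL_OPEN = "<!--rm5kit:contributed-outcomes v1-->"
SENTINEL_CLOSE = "<!--/rm5kit:contributed-outcomes-->"

_BLOCK = re.compile(
    re.escape(SENTINEL_OPEN) + r".*?" + re.escape(SENTINEL_CLOSE), re.DOTALL
)


def contributed_outcomes(review: Review, study_id: str) -> list[str]:
    """Titles of every outcome table containing a data row for ``study_id``,
    deduplicated, in comparison-then-outcome document order.

    Raises KeyError for an unknown study_id.
    """
    review.study(study_id)  # raises KeyError if absent
    titles: list[str] = []
    seen: set[str] = set()
    for comp in review.comparisons:
        for outcome in comp.outcomes:
            if any(row.study_id == study_id for row in outcome.rows):
                title = normalize_title(outcome.title)
                if title not in seen:
                    seen.add(title)
                    titles.append(title)
    return titles


def render_block(titles: list[str]) -> str:
    """The generated fragment appended to the characteristics field."""
    listing = "; ".join(titles)
    return (
        f"{SENTINEL_OPEN}<P>Contributing to outcomes: "
        f"{xml_escape(listing)}.</P>{SENTINEL_CLOSE}"
    )


def strip_blocks(raw: str) -> str:
    """Remove every generated sentinel block from a raw fragment, recovering
    the hand-written content exactly."""
    return _BLOCK.sub("", raw)


def extract_injected(raw: str) -> Optional[list[str]]:
    """Parse the outcome list back out of a field's sentinel block (None when
    no block is present).  Titles containing "; " are a documented limitation
    of the flat listing."""
    m = _BLOCK.search(raw)
    if not m:
        return None
    text = plain_text(m.group(0))
    body = text.removeprefix("Contributing to outcomes:").strip()
    body = body.removesuffix(".")
    return [t.strip() for t in body.split(";") if t.strip()] if body else []


@dataclass
class EditReport:
    path: str = ""
    edited: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def n_edits(self) -> int:
        return len(self.edited)


def inject_review(review: Review, field_name: str = "outcomes") -> EditReport:
    """Inject contributed-outcome blocks into a Review in place.

    Studies with no outcome rows are skipped (no block, reported as such);
    any stale block is removed first so repeated injection is idempotent.
    """
    report = EditReport(path=review.source_path)
    for study in review.studies:
        titles = contributed_outcomes(review, study.study_id)
        raw = strip_blocks(study.characteristics.get(field_name))
        if titles:
            study.characteristics.set(field_name, raw + render_block(titles))
            report.edited.append(study.study_id)
        else:
            study.characteristics.set(field_name, raw)
            report.skipped.append(study.study_id)
    return report


def inject_outcome_lists(
    path_in: Union[str, os.PathLike],
    path_out: Optional[Union[str, os.PathLike]] = None,
    field_name: str = "outcomes",
    in_place: bool = False,
    backup_suffix: str = ".bak",
) -> EditReport:
    """Read a .rm5 file, inject every study's contributed-outcome list, and
    write the result.

    With ``in_place`` the source is first copied to ``<name>.bak`` (the
    backup is mandatory) and then replaced.  Output goes to a temporary file
    moved into place, so a failure never leaves partial output.
    """
    path_in = Path(path_in)
    if in_place:
        path_out = path_in
    elif path_out is None:
        raise ValueError("path_out is required unless in_place=True")
    path_out = Path(path_out)

    review = read_review(path_in, schema_mode="lenient")
    report = inject_review(review, field_name=field_name)
    data = review_to_bytes(review)

    if in_place:
        backup = path_in.with_name(path_in.name + backup_suffix)
        backup.write_bytes(path_in.read_bytes())
    tmp = path_out.with_name(path_out.name + ".tmp")
    tmp.write_bytes(data)
    os.replace(tmp, path_out)
    report.path = str(path_out)
    return report
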
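"""Read and write the documented .rm5 XML dialect losslessly.

The dialect (see ``docs/rm5-dialect.md``) is modelled on the public RevMan 5.3
save-file schema: a review root with a cover sheet, a studies-and-references
block, per-study characteristics and risk-of-bias tables, and an analyses
block of comparison -> outcome -> per-study data rows.  Element names live in
the single :data:`TAGS` mapping so the dialect can be re-pointed at another
RevMan variant without code changes.

Round-trip contract: ``read_review(write_review(r)) == r`` field-for-field
over the supported subset, and ``write_review(read_review(f))`` is
canonicalized-XML-equal to ``f`` for any file this package produced.  XML
subtrees outside the subset (e.g. excluded-studies tables, review prose) are
retained opaquely and re-emitted in original document order.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union
from xml.etree.ElementTree import canonicalize as _et_canonicalize
from xml.sax.saxutils import escape as xml_escape

from lxml import etree

from .model import (
    Characteristics,
    Comparison,
    DataType,
    Judgement,
    OutcomeDataRow,
    OutcomeTable,
    Reference,
    RetainedSubtree,
    Review,
    RobEntry,
    Study,
    ValidationError,
)

__all__ = [
    "Rm5ParseError",
    "Rm5SchemaError",
    "BatchFailure",
    "BatchResult",
    "read_review",
    "write_review",
    "review_to_bytes",
    "read_batch",
    "canonical_xml",
    "xml_escape",
    "TAGS",
]

log = logging.getLogger("rm5kit")

# Single point of truth for element/attribute names of the dialect.  Re-point
# these to track another RevMan dialect; the reader/writer only use this table.
TAGS = {
    "root": "COCHRANE_REVIEW",
    "attr_review_id": "ID",
    "attr_version": "REVMAN_VERSION",
    "cover": "COVER_SHEET",
    "title": "TITLE",
    "studies_refs": "STUDIES_AND_REFERENCES",
    "studies": "STUDIES",
    "included_studies": "INCLUDED_STUDIES",
    "study": "STUDY",
    "attr_study_id": "ID",
    "reference": "REFERENCE",
    "attr_citation_id": "ID",
    "ref_title": "TI",
    "ref_journal": "SO",
    "ref_year": "YR",
    "char_section": "CHARACTERISTICS_OF_STUDIES",
    "char_included": "CHARACTERISTICS_OF_INCLUDED_STUDIES",
    "char_entry": "INCLUDED_CHAR",
    "char_methods": "CHAR_METHODS",
    "char_participants": "CHAR_PARTICIPANTS",
    "char_interventions": "CHAR_INTERVENTIONS",
    "char_outcomes": "CHAR_OUTCOMES",
    "char_notes": "CHAR_NOTES",
    "rob_section": "RISK_OF_BIAS",
    "rob_table": "ROB_TABLE",
    "rob_entry": "ROB_ENTRY",
    "attr_rob_name": "NAME",
    "attr_rob_result": "RESULT",
    "analyses": "ANALYSES_AND_DATA",
    "comparison": "COMPARISON",
    "attr_comparison_id": "ID",
    "name": "NAME",
    "dich_outcome": "DICH_OUTCOME",
    "cont_outcome": "CONT_OUTCOME",
    "attr_outcome_id": "ID",
    "dich_data": "DICH_DATA",
    "cont_data": "CONT_DATA",
}

_CHAR_FIELD_TAGS = [
    ("methods", "char_methods"),
    ("participants", "char_participants"),
    ("interventions", "char_interventions"),
    ("outcomes", "char_outcomes"),
    ("notes", "char_notes"),
]

#: symbolic container keys for retained opaque subtrees
PARENT_REVIEW = "review"
PARENT_STUDIES = "studies"

_ROOT_ORDER = ("cover", "studies_refs", "char_section", "rob_section", "analyses")


class Rm5ParseError(ValueError):
    """The file is not well-formed XML."""


class Rm5SchemaError(ValueError):
    """A required block of the dialect is missing (strict mode)."""


# ---------------------------------------------------------------------------
# canonical XML comparison

def canonical_xml(data: Union[str, bytes]) -> str:
    """Canonicalize an XML document: attribute order and entity/quote layout
    normalized, comments kept.  The round-trip contract compares these strings,
    not raw bytes, because serializers legitimately differ in byte layout."""
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    out = io.StringIO()
    _et_canonicalize(xml_data=data, out=out, with_comments=True)
    return out.getvalue()


def _canonical_fragment(el: etree._Element) -> str:
    text = etree.tostring(el, with_tail=False, encoding="unicode")
    if isinstance(el, (etree._Comment, etree._ProcessingInstruction)):
        return text  # bare comments/PIs are not canonicalizable documents
    return canonical_xml(text)


def _inner_xml(el: etree._Element) -> str:
    """Serialize an element's content (mixed text/markup/comments) to a
    well-formed fragment string; plain-text runs are entity-escaped so the
    fragment re-parses identically."""
    parts = [xml_escape(el.text or "")]
    for child in el:
        parts.append(etree.tostring(child, with_tail=False, encoding="unicode"))
        parts.append(xml_escape(child.tail or ""))
    return "".join(parts)


_FRAG_PARSER = etree.XMLParser(remove_comments=False, resolve_entities=True)


def _set_inner_xml(el: etree._Element, raw: str) -> None:
    try:
        frag = etree.fromstring(f"<x>{raw}</x>".encode("utf-8"), parser=_FRAG_PARSER)
    except etree.XMLSyntaxError as exc:
        raise ValidationError(f"free-text fragment is not well-formed: {exc}") from exc
    el.text = frag.text
    for child in frag:
        el.append(child)


# ---------------------------------------------------------------------------
# reading

def _opt_int(value: Optional[str], what: str) -> Optional[int]:
    if value is None or value == "":
        return None
    try:
        return int(value)
    except ValueError as exc:
        raise ValidationError(f"{what}: not an integer: {value!r}") from exc


def _opt_float(value: Optional[str], what: str) -> Optional[float]:
    if value is None or value == "":
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise ValidationError(f"{what}: not a number: {value!r}") from exc


def read_review(path: Union[str, os.PathLike], schema_mode: str = "lenient") -> Review:
    """Parse one .rm5 file into a :class:`~rm5kit.model.Review`.

    Parameters
    ----------
    path:
        File to read; must be well-formed XML.
    schema_mode:
        ``"lenient"`` (default): missing optional blocks yield empty
        collections with a logged warning; invariant violations are logged.
        ``"strict"``: a missing studies container raises
        :class:`Rm5SchemaError` naming the path, and any model-invariant
        violation (e.g. events > total) raises
        :class:`~rm5kit.model.ValidationError`.
    """
    if schema_mode not in ("strict", "lenient"):
        raise ValueError(f"schema_mode must be 'strict' or 'lenient', got {schema_mode!r}")
    path = Path(path)
    data = path.read_bytes()
    try:
        root = etree.fromstring(data, parser=_FRAG_PARSER)
    except etree.XMLSyntaxError as exc:
        offset = _byte_offset(data, exc)
        raise Rm5ParseError(
            f"{path}: malformed XML near byte offset {offset}: {exc.msg}"
        ) from exc

    if root.tag != TAGS["root"]:
        raise Rm5SchemaError(f"{path}: root element is <{root.tag}>, expected <{TAGS['root']}>")

    review = Review(
        review_id=root.get(TAGS["attr_review_id"], ""),
        source_path=str(path),
    )

    known_root = {TAGS[k] for k in _ROOT_ORDER}
    sections: dict[str, etree._Element] = {}
    for i, child in enumerate(root):
        if isinstance(child, etree._Comment) or child.tag not in known_root:
            review.unparsed_retained.append(
                RetainedSubtree(PARENT_REVIEW, i, _canonical_fragment(child))
            )
        else:
            sections[child.tag] = child

    cover = sections.get(TAGS["cover"])
    if cover is not None:
        t = cover.find(TAGS["title"])
        review.title = (t.text or "") if t is not None else ""

    # --- studies & references ---
    studies_refs = sections.get(TAGS["studies_refs"])
    studies_el = None if studies_refs is None else studies_refs.find(TAGS["studies"])
    if studies_el is None:
        msg = (
            f"{path}: missing required block "
            f"{TAGS['studies_refs']}/{TAGS['studies']}"
        )
        if schema_mode == "strict":
            raise Rm5SchemaError(msg)
        log.warning(msg + " (lenient: empty studies)")
        included = None
    else:
        included = None
        for i, child in enumerate(studies_el):
            if not isinstance(child, etree._Comment) and child.tag == TAGS["included_studies"]:
                included = child
            else:
                review.unparsed_retained.append(
                    RetainedSubtree(PARENT_STUDIES, i, _canonical_fragment(child))
                )
    if included is not None:
        for study_el in included.iterfind(TAGS["study"]):
            study = Study(study_id=study_el.get(TAGS["attr_study_id"], ""))
            for ref_el in study_el.iterfind(TAGS["reference"]):
                ti = ref_el.find(TAGS["ref_title"])
                so = ref_el.find(TAGS["ref_journal"])
                yr = ref_el.find(TAGS["ref_year"])
                study.references.append(
                    Reference(
                        citation_id=ref_el.get(TAGS["attr_citation_id"], ""),
                        title=(ti.text or "") if ti is not None else "",
                        journal=so.text if so is not None else None,
                        year=_opt_int(yr.text if yr is not None else None,
                                      f"reference year in study {study.study_id!r}"),
                    )
                )
            review.studies.append(study)

    # --- characteristics ---
    char_section = sections.get(TAGS["char_section"])
    char_included = (
        None if char_section is None else char_section.find(TAGS["char_included"])
    )
    if char_included is not None:
        by_id = {s.study_id: s for s in review.studies}
        for entry in char_included.iterfind(TAGS["char_entry"]):
            sid = entry.get("STUDY_ID", "")
            study = by_id.get(sid)
            if study is None:
                _lenient(schema_mode, f"{path}: characteristics entry for unknown study {sid!r}")
                continue
            ch = Characteristics()
            for field_name, tag_key in _CHAR_FIELD_TAGS:
                el = entry.find(TAGS[tag_key])
                if el is not None:
                    ch.set(field_name, _inner_xml(el))
            study.characteristics = ch

    # --- risk of bias ---
    rob_section = sections.get(TAGS["rob_section"])
    if rob_section is not None:
        by_id = {s.study_id: s for s in review.studies}
        for table in rob_section.iterfind(TAGS["rob_table"]):
            sid = table.get("STUDY_ID", "")
            study = by_id.get(sid)
            if study is None:
                _lenient(schema_mode, f"{path}: risk-of-bias table for unknown study {sid!r}")
                continue
            for entry in table.iterfind(TAGS["rob_entry"]):
                result = entry.get(TAGS["attr_rob_result"], "").lower()
                try:
                    judgement = Judgement(result)
                except ValueError:
                    raise ValidationError(
                        f"{path}: risk-of-bias judgement {result!r} for study "
                        f"{sid!r} is not one of low/high/unclear"
                    ) from None
                study.risk_of_bias.append(
                    RobEntry(
                        item_name=entry.get(TAGS["attr_rob_name"], ""),
                        judgement=judgement,
                        support=entry.text or "",
                    )
                )

    # --- analyses ---
    analyses = sections.get(TAGS["analyses"])
    if analyses is not None:
        for comp_el in analyses.iterfind(TAGS["comparison"]):
            comp = Comparison(comparison_id=comp_el.get(TAGS["attr_comparison_id"], ""))
            name_el = comp_el.find(TAGS["name"])
            comp.name = (name_el.text or "") if name_el is not None else ""
            for out_el in comp_el:
                if out_el.tag == TAGS["dich_outcome"]:
                    comp.outcomes.append(_read_outcome(out_el, DataType.DICHOTOMOUS))
                elif out_el.tag == TAGS["cont_outcome"]:
                    comp.outcomes.append(_read_outcome(out_el, DataType.CONTINUOUS))
            review.comparisons.append(comp)

    try:
        review.validate()
    except ValidationError:
        if schema_mode == "strict":
            raise
        log.warning("%s: validation issue kept in lenient mode", path, exc_info=True)
    return review


def _read_outcome(out_el: etree._Element, data_type: DataType) -> OutcomeTable:
    name_el = out_el.find(TAGS["name"])
    table = OutcomeTable(
        outcome_id=out_el.get(TAGS["attr_outcome_id"], ""),
        title=(name_el.text or "") if name_el is not None else "",
        data_type=data_type,
    )
    data_tag = TAGS["dich_data"] if data_type is DataType.DICHOTOMOUS else TAGS["cont_data"]
    for row_el in out_el.iterfind(data_tag):
        sid = row_el.get("STUDY_ID", "")
        what = f"outcome {table.outcome_id!r} row for {sid!r}"
        if data_type is DataType.DICHOTOMOUS:
            row = OutcomeDataRow(
                study_id=sid,
                arm1_events=_opt_int(row_el.get("EVENTS_1"), what),
                arm1_total=_opt_int(row_el.get("TOTAL_1"), what),
                arm2_events=_opt_int(row_el.get("EVENTS_2"), what),
                arm2_total=_opt_int(row_el.get("TOTAL_2"), what),
            )
        else:
            row = OutcomeDataRow(
                study_id=sid,
                arm1_mean=_opt_float(row_el.get("MEAN_1"), what),
                arm1_sd=_opt_float(row_el.get("SD_1"), what),
                arm1_n=_opt_int(row_el.get("TOTAL_1"), what),
                arm2_mean=_opt_float(row_el.get("MEAN_2"), what),
                arm2_sd=_opt_float(row_el.get("SD_2"), what),
                arm2_n=_opt_int(row_el.get("TOTAL_2"), what),
            )
        table.rows.append(row)
    return table


def _lenient(schema_mode: str, msg: str) -> None:
    if schema_mode == "strict":
        raise Rm5SchemaError(msg)
    log.warning(msg)


def _byte_offset(data: bytes, exc: etree.XMLSyntaxError) -> int:
    line, col = exc.position if exc.position else (exc.lineno or 1, 0)
    lines = data.split(b"\n")
    return sum(len(l) + 1 for l in lines[: max(line - 1, 0)]) + col


# ---------------------------------------------------------------------------
# writing

def _num(v) -> str:
    return str(v)


def review_to_bytes(review: Review) -> bytes:
    """Serialize a validated Review to UTF-8 XML bytes.

    Raises :class:`~rm5kit.model.ValidationError` before producing any output
    if the review violates a model invariant.  Empty optional elements are
    omitted, not emitted empty.
    """
    review.validate()
    root = etree.Element(TAGS["root"])
    root.set(TAGS["attr_review_id"], review.review_id)
    root.set(TAGS["attr_version"], "5.3")

    children: list[etree._Element] = []

    cover = etree.Element(TAGS["cover"])
    if review.title:
        etree.SubElement(cover, TAGS["title"]).text = review.title
    children.append(cover)

    studies_refs = etree.Element(TAGS["studies_refs"])
    studies_el = etree.SubElement(studies_refs, TAGS["studies"])
    included = etree.Element(TAGS["included_studies"])
    for study in review.studies:
        s_el = etree.SubElement(included, TAGS["study"])
        s_el.set(TAGS["attr_study_id"], study.study_id)
        for ref in study.references:
            r_el = etree.SubElement(s_el, TAGS["reference"])
            r_el.set(TAGS["attr_citation_id"], ref.citation_id)
            if ref.title:
                etree.SubElement(r_el, TAGS["ref_title"]).text = ref.title
            if ref.journal is not None:
                etree.SubElement(r_el, TAGS["ref_journal"]).text = ref.journal
            if ref.year is not None:
                etree.SubElement(r_el, TAGS["ref_year"]).text = str(ref.year)
    # retained children of the studies container go back at their positions
    _insert_with_retained(
        studies_el, [included], review, PARENT_STUDIES
    )
    children.append(studies_refs)

    char_section = etree.Element(TAGS["char_section"])
    char_included = etree.SubElement(char_section, TAGS["char_included"])
    for study in review.studies:
        ch = study.characteristics
        if not any(ch.get(f) for f, _ in _CHAR_FIELD_TAGS):
            continue
        entry = etree.SubElement(char_included, TAGS["char_entry"])
        entry.set("STUDY_ID", study.study_id)
        for field_name, tag_key in _CHAR_FIELD_TAGS:
            raw = ch.get(field_name)
            if raw:
                _set_inner_xml(etree.SubElement(entry, TAGS[tag_key]), raw)
    children.append(char_section)

    rob_section = etree.Element(TAGS["rob_section"])
    for study in review.studies:
        if not study.risk_of_bias:
            continue
        table = etree.SubElement(rob_section, TAGS["rob_table"])
        table.set("STUDY_ID", study.study_id)
        for entry in study.risk_of_bias:
            e_el = etree.SubElement(table, TAGS["rob_entry"])
            e_el.set(TAGS["attr_rob_name"], entry.item_name)
            e_el.set(TAGS["attr_rob_result"], entry.judgement.value.upper())
            if entry.support:
                e_el.text = entry.support
    children.append(rob_section)

    analyses = etree.Element(TAGS["analyses"])
    for comp in review.comparisons:
        c_el = etree.SubElement(analyses, TAGS["comparison"])
        c_el.set(TAGS["attr_comparison_id"], comp.comparison_id)
        if comp.name:
            etree.SubElement(c_el, TAGS["name"]).text = comp.name
        for outcome in comp.outcomes:
            dich = outcome.data_type is DataType.DICHOTOMOUS
            o_el = etree.SubElement(
                c_el, TAGS["dich_outcome"] if dich else TAGS["cont_outcome"]
            )
            o_el.set(TAGS["attr_outcome_id"], outcome.outcome_id)
            etree.SubElement(o_el, TAGS["name"]).text = outcome.title
            for row in outcome.rows:
                r_el = etree.SubElement(
                    o_el, TAGS["dich_data"] if dich else TAGS["cont_data"]
                )
                r_el.set("STUDY_ID", row.study_id)
                if dich:
                    for attr, v in (
                        ("EVENTS_1", row.arm1_events),
                        ("TOTAL_1", row.arm1_total),
                        ("EVENTS_2", row.arm2_events),
                        ("TOTAL_2", row.arm2_total),
                    ):
                        if v is not None:
                            r_el.set(attr, _num(v))
                else:
                    for attr, v in (
                        ("MEAN_1", row.arm1_mean),
                        ("SD_1", row.arm1_sd),
                        ("TOTAL_1", row.arm1_n),
                        ("MEAN_2", row.arm2_mean),
                        ("SD_2", row.arm2_sd),
                        ("TOTAL_2", row.arm2_n),
                    ):
                        if v is not None:
                            r_el.set(attr, _num(v))
    children.append(analyses)

    _insert_with_retained(root, children, review, PARENT_REVIEW)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8")


def _insert_with_retained(
    parent: etree._Element,
    known: list[etree._Element],
    review: Review,
    parent_key: str,
) -> None:
    for el in known:
        if el.getparent() is None:
            parent.append(el)
    retained = sorted(
        (r for r in review.unparsed_retained if r.parent == parent_key),
        key=lambda r: r.index,
    )
    for r in retained:
        if r.xml.startswith("<!--"):
            sub: etree._Element = etree.Comment(r.xml[4:-3])
        else:
            sub = etree.fromstring(r.xml.encode("utf-8"), parser=_FRAG_PARSER)
        parent.insert(min(r.index, len(parent)), sub)


def write_review(review: Review, path: Union[str, os.PathLike]) -> None:
    """Validate and write a Review; on invariant violation no bytes are written.

    The file is written to a temporary sibling and atomically moved into
    place so a failure never leaves a partial document.
    """
    data = review_to_bytes(review)  # validates first
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_bytes(data)
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# batch

@dataclass
class BatchFailure:
    path: str
    error: str


@dataclass
class BatchResult:
    """Reviews sorted by review_id plus per-file failures (never fatal)."""

    reviews: list[Review] = field(default_factory=list)
    failures: list[BatchFailure] = field(default_factory=list)

    def __iter__(self):
        return iter(self.reviews)

    def __len__(self) -> int:
        return len(self.reviews)


def read_batch(
    directory: Union[str, os.PathLike],
    glob: str = "*.rm5",
    schema_mode: str = "lenient",
) -> BatchResult:
    """Read every matching file under ``directory``.

    The result is sorted by ``review_id`` so it is deterministic regardless of
    filesystem listing order.  Files that fail to parse (or collide on
    review_id) are collected as :class:`BatchFailure` records.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    paths = sorted(directory.glob(glob))
    if not paths:
        log.warning("no files matching %r under %s", glob, directory)
    result = BatchResult()
    seen_ids: dict[str, str] = {}
    for p in paths:
        try:
            review = read_review(p, schema_mode=schema_mode)
        except (Rm5ParseError, Rm5SchemaError, ValidationError) as exc:
            result.failures.append(BatchFailure(str(p), str(exc)))
            continue
        if review.review_id in seen_ids:
            result.failures.append(
                BatchFailure(
                    str(p),
                    f"duplicate review_id {review.review_id!r} "
                    f"(already read from {seen_ids[review.review_id]})",
                )
            )
            continue
        seen_ids[review.review_id] = str(p)
        result.reviews.append(review)
    result.reviews.sort(key=lambda r: r.review_id)
    return result
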
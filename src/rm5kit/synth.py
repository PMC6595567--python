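"""Seeded generator of synthetic .rm5 review corpora with a ground-truth manifest.

Real review corpora cannot be redistributed, so every pipeline stage is
exercised against generated ones instead.  Each generated review contains the
structures a real save file has — several reports per study, five free-text
characteristics fields assembled from templated sentences with realistically
messy surface forms, a per-study risk-of-bias table, and dichotomous and
continuous outcome tables — while the manifest records the ground truth
behind every sentence: the true participant count behind "N=120", the
canonical label behind each blinding phrase, the base title behind each
outcome-title variant, and the exact corpus totals.  The manifest is the
oracle all extraction tests compare against.

Generation is fully deterministic: the same seed yields byte-identical files
and manifest.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml
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
)
from .rm5_io import PARENT_REVIEW, PARENT_STUDIES, canonical_xml, write_review, xml_escape

__all__ = [
    "BankError",
    "CorpusManifest",
    "load_phrase_bank",
    "load_title_bank",
    "title_variant",
    "generate_review",
    "generate_corpus",
    "corrupt_fixture",
]


class BankError(ValueError):
    """A phrase or title bank is empty or malformed."""


_SURNAMES = [
    "Smith", "Chen", "Garcia", "Okafor", "Nguyen", "Kumar", "Ivanov", "Muller",
    "Rossi", "Tanaka", "Johansson", "Kowalski", "Silva", "Haddad", "Novak",
    "Petrov", "Berg", "Costa", "Dubois", "Farkas", "Moreno", "Ali", "Weber",
    "Lindgren", "Bauer", "Sato", "Kim", "Lopez", "Fischer", "Andersen",
]

_DRUGS = [
    "Chlorpromazine", "Haloperidol", "Risperidone", "Olanzapine", "Quetiapine",
    "Clozapine", "Amisulpride", "Aripiprazole", "Ziprasidone", "Sulpiride",
]

_ROB_ITEMS = [
    "Random sequence generation",
    "Allocation concealment",
    "Blinding of participants and personnel",
    "Blinding of outcome assessment",
    "Incomplete outcome data",
    "Selective reporting",
]

_JOURNALS = [
    "Journal of Clinical Psychiatry", "Schizophrenia Bulletin",
    "Acta Psychiatrica Scandinavica", "British Journal of Psychiatry",
    "Psychological Medicine", None,
]

_SETTINGS = ["inpatients", "outpatients", "people"]

# decade mixture spanning 1960-2015, weighted towards recent evidence
_YEAR_DECADES = [
    ((1960, 1969), 5),
    ((1970, 1979), 10),
    ((1980, 1989), 15),
    ((1990, 1999), 25),
    ((2000, 2009), 30),
    ((2010, 2015), 15),
]

N_TITLE_VARIANTS = 4


def load_phrase_bank(path: Optional[Union[str, Path]] = None) -> dict[str, list[dict]]:
    """Load the phrase bank (default: the shipped one).  Each entry is
    ``{phrase, label}``; the label is the ground truth for normalization."""
    if path is None:
        text = resources.files("rm5kit.data").joinpath("phrase_bank.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    bank = yaml.safe_load(text)
    if not bank or not bank.get("blinding") or not bank.get("allocation"):
        raise BankError("phrase bank must provide non-empty 'blinding' and 'allocation' lists")
    return bank


def load_title_bank(path: Optional[Union[str, Path]] = None) -> list[str]:
    """Load the base outcome-title bank (one title per line)."""
    if path is None:
        text = resources.files("rm5kit.data").joinpath("title_bank.txt").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    titles = [line.strip() for line in text.splitlines() if line.strip()]
    if not titles:
        raise BankError("title bank is empty")
    return titles


def title_variant(base: str, variant: int) -> str:
    """Surface form ``variant`` (0..3) of a base title: as-is, SHOUTED,
    trailing period, or a leading enumeration prefix.  All four share one
    canonical form."""
    v = variant % N_TITLE_VARIANTS
    if v == 0:
        return base
    if v == 1:
        return base.upper()
    if v == 2:
        return base + "."
    return "1.1 " + base


@dataclass
class CorpusManifest:
    """Ground truth for a generated corpus; the oracle for extraction tests."""

    seed: int
    n_reviews: int
    reviews: list[dict] = field(default_factory=list)
    totals: dict = field(default_factory=dict)

    def recompute_totals(self) -> dict:
        """Aggregate the per-review entries; must equal ``totals`` exactly."""
        n_studies = n_refs = n_tables = n_rows = 0
        titles: set[str] = set()
        bases: set[int] = set()
        hist: dict[str, int] = {}
        participants: dict[str, dict] = {}
        for rv in self.reviews:
            part = participants.setdefault(rv["review_id"], {"total": 0, "missing": 0})
            for st in rv["studies"]:
                n_studies += 1
                n_refs += st["n_references"]
                hist[str(st["year"])] = hist.get(str(st["year"]), 0) + 1
                if st["n"] is None:
                    part["missing"] += 1
                else:
                    part["total"] += st["n"]
            for ot in rv["outcomes"]:
                n_tables += 1
                n_rows += len(ot["row_study_ids"])
                titles.add(ot["title"])
                bases.add(ot["base_index"])
        return {
            "n_studies": n_studies,
            "n_references": n_refs,
            "n_outcome_tables": n_tables,
            "n_outcome_rows": n_rows,
            "distinct_titles": len(titles),
            "n_clusters": len(bases),
            "year_histogram": dict(sorted(hist.items())),
            "participants": dict(sorted(participants.items())),
        }

    def validate(self) -> None:
        recomputed = self.recompute_totals()
        if recomputed != self.totals:
            raise ValueError("manifest totals are not self-consistent")

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=1, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "CorpusManifest":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**doc)


def _pick_year(rng: random.Random) -> int:
    decades = [d for d, _ in _YEAR_DECADES]
    weights = [w for _, w in _YEAR_DECADES]
    lo, hi = rng.choices(decades, weights=weights, k=1)[0]
    return rng.randint(lo, hi)


def generate_review(
    rng: random.Random,
    review_id: str,
    phrase_bank: dict,
    title_bank: Sequence[str],
    studies_range: tuple[int, int] = (2, 8),
    n_base_titles: int = 37,
    missing_n_rate: float = 0.1,
    retained_rate: float = 0.3,
) -> tuple[Review, dict]:
    """Generate one review plus its manifest entry."""
    n_base = min(n_base_titles, len(title_bank))
    review = Review(
        review_id=review_id,
        title=f"{rng.choice(_DRUGS)} versus placebo for schizophrenia",
    )
    entry: dict = {"review_id": review_id, "studies": [], "outcomes": []}

    n_studies = rng.randint(*studies_range)
    used_ids: set[str] = set()
    for _ in range(n_studies):
        year = _pick_year(rng)
        base_id = f"{rng.choice(_SURNAMES)} {year}"
        study_id, suffix = base_id, "a"
        while study_id in used_ids:
            study_id = base_id + suffix
            suffix = chr(ord(suffix) + 1)
        used_ids.add(study_id)

        n_refs = rng.randint(1, 3)
        refs = []
        for i in range(n_refs):
            refs.append(
                Reference(
                    citation_id=f"{review_id}-{len(used_ids):02d}-{i + 1}",
                    title=f"Report {i + 1} of {study_id}",
                    journal=rng.choice(_JOURNALS),
                    year=year if i == 0 else min(year + rng.randint(0, 3), 2100),
                )
            )

        blind = rng.choice(phrase_bank["blinding"])
        alloc = rng.choice(phrase_bank["allocation"])
        duration = rng.choice([4, 6, 8, 12, 16, 24, 26, 52])
        has_n = rng.random() >= missing_n_rate
        n_true = rng.randint(20, 400) if has_n else None
        setting = rng.choice(_SETTINGS)
        drug = rng.choice(_DRUGS)

        ch = Characteristics(
            methods=(
                f"<P>Allocation: {xml_escape(alloc['phrase'])}. "
                f"Blinding: {xml_escape(blind['phrase'])}. "
                f"Duration: {duration} weeks.</P>"
            ),
            participants=(
                f"<P>N={n_true} {setting} with schizophrenia.</P>"
                if has_n
                else f"<P>People with schizophrenia, number not stated.</P>"
            ),
            interventions=f"<P><B>{xml_escape(drug)}</B> versus placebo.</P>",
            outcomes="<P>Clinical response, adverse effects.</P>",
            notes="" if rng.random() < 0.5 else "<P>Funding not stated.</P>",
        )

        rob = [
            RobEntry(
                item_name=item,
                judgement=rng.choice(list(Judgement)),
                support=f"Quote: '{item.lower()} procedure reported'.",
            )
            for item in rng.sample(_ROB_ITEMS, k=rng.randint(2, 4))
        ]

        review.studies.append(
            Study(study_id=study_id, references=refs, characteristics=ch, risk_of_bias=rob)
        )
        entry["studies"].append(
            {
                "study_id": study_id,
                "year": year,
                "n_references": n_refs,
                "n": n_true,
                "blinding_phrase": blind["phrase"],
                "blinding_label": blind["label"],
                "allocation_label": alloc["label"],
                "duration_weeks": duration,
            }
        )

    for c in range(rng.randint(1, 3)):
        comp = Comparison(
            comparison_id=f"CMP-{c + 1:02d}",
            name=f"{review.title.split(' versus ')[0].upper()} versus PLACEBO",
        )
        for o in range(rng.randint(1, 4)):
            base_index = rng.randrange(n_base)
            variant = rng.randrange(N_TITLE_VARIANTS)
            title = title_variant(title_bank[base_index], variant)
            data_type = rng.choice([DataType.DICHOTOMOUS, DataType.CONTINUOUS])
            outcome = OutcomeTable(
                outcome_id=f"OUT-{c + 1:02d}.{o + 1:02d}",
                title=title,
                data_type=data_type,
            )
            k = rng.randint(1, len(review.studies))
            chosen = sorted(rng.sample(range(len(review.studies)), k=k))
            for idx in chosen:
                sid = review.studies[idx].study_id
                if data_type is DataType.DICHOTOMOUS:
                    t1, t2 = rng.randint(10, 100), rng.randint(10, 100)
                    outcome.rows.append(
                        OutcomeDataRow(
                            study_id=sid,
                            arm1_events=rng.randint(0, t1),
                            arm1_total=t1,
                            arm2_events=rng.randint(0, t2),
                            arm2_total=t2,
                        )
                    )
                else:
                    outcome.rows.append(
                        OutcomeDataRow(
                            study_id=sid,
                            arm1_mean=round(rng.uniform(0, 100), 1),
                            arm1_sd=round(rng.uniform(0.5, 20), 1),
                            arm1_n=rng.randint(10, 100),
                            arm2_mean=round(rng.uniform(0, 100), 1),
                            arm2_sd=round(rng.uniform(0.5, 20), 1),
                            arm2_n=rng.randint(10, 100),
                        )
                    )
            comp.outcomes.append(outcome)
            entry["outcomes"].append(
                {
                    "comparison_id": comp.comparison_id,
                    "outcome_id": outcome.outcome_id,
                    "base_index": base_index,
                    "variant": variant,
                    "title": title,
                    "data_type": data_type.value,
                    "row_study_ids": [r.study_id for r in outcome.rows],
                }
            )
        review.comparisons.append(comp)

    # opaque subtrees outside the supported subset, retained on read
    if rng.random() < retained_rate:
        review.unparsed_retained.append(
            RetainedSubtree(
                PARENT_STUDIES,
                1,
                canonical_xml(
                    '<EXCLUDED_STUDIES><STUDY ID="Excluded 1990">'
                    "<REFERENCE ID=\"x1\"><TI>Not randomised</TI></REFERENCE>"
                    "</STUDY></EXCLUDED_STUDIES>"
                ),
            )
        )
    if rng.random() < retained_rate:
        review.unparsed_retained.append(
            RetainedSubtree(
                PARENT_REVIEW,
                5,
                canonical_xml(
                    "<MAIN_TEXT><SUMMARY><P>Plain language summary.</P></SUMMARY></MAIN_TEXT>"
                ),
            )
        )
    return review, entry


def generate_corpus(
    seed: int,
    n_reviews: int,
    out_dir: Union[str, Path],
    studies_per_review: tuple[int, int] = (2, 8),
    phrase_bank: Optional[Union[str, Path]] = None,
    title_bank: Optional[Union[str, Path]] = None,
    n_base_titles: int = 37,
    missing_n_rate: float = 0.1,
    write_manifest: bool = True,
) -> CorpusManifest:
    """Write ``n_reviews`` valid .rm5 files plus ``manifest.json``.

    The same seed yields a byte-identical corpus.  With ``n_reviews == 0`` a
    manifest with zero totals is produced and no review files are written.
    """
    if n_reviews < 0:
        raise ValueError("n_reviews must be >= 0")
    bank = load_phrase_bank(phrase_bank)
    titles = load_title_bank(title_bank)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    manifest = CorpusManifest(seed=seed, n_reviews=n_reviews)
    for i in range(n_reviews):
        review_id = f"R{i + 1:04d}"
        review, entry = generate_review(
            rng,
            review_id,
            bank,
            titles,
            studies_range=studies_per_review,
            n_base_titles=n_base_titles,
            missing_n_rate=missing_n_rate,
        )
        path = out_dir / f"{review_id}.rm5"
        write_review(review, path)
        entry["file"] = path.name
        manifest.reviews.append(entry)
    manifest.totals = manifest.recompute_totals()
    if write_manifest:
        manifest.save(out_dir / "manifest.json")
    return manifest


def corrupt_fixture(path: Union[str, Path], mode: str) -> Path:
    """Deterministically corrupt a valid fixture for negative tests.

    ``truncate`` cuts the file in half (malformed XML); ``bad_numbers`` sets
    the first dichotomous row's events above its total (invariant violation);
    ``missing_block`` removes the studies container (schema violation).
    """
    path = Path(path)
    data = path.read_bytes()
    if mode == "truncate":
        path.write_bytes(data[: len(data) // 2])
    elif mode == "bad_numbers":
        root = etree.fromstring(data)
        row = root.find(".//DICH_DATA")
        if row is None:
            raise ValueError(f"{path}: no dichotomous data row to corrupt")
        row.set("EVENTS_1", str(int(row.get("TOTAL_1", "0")) + 5))
        path.write_bytes(etree.tostring(root, xml_declaration=True, encoding="UTF-8"))
    elif mode == "missing_block":
        root = etree.fromstring(data)
        studies = root.find(".//STUDIES")
        if studies is None:
            raise ValueError(f"{path}: no studies block to remove")
        studies.getparent().remove(studies)
        path.write_bytes(etree.tostring(root, xml_declaration=True, encoding="UTF-8"))
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")
    return path
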
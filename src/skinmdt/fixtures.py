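"""Packaged fixtures: the published 5x5 validation matrix (see
:func:`skinmdt.evaluation.load_published_matrix`) and a hand-labelled
structured-case set covering every row of the guideline rule table."""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from importlib import resources

from .labels import OutcomeCode, Recommendation
from .records import LesionRecord


@dataclass
class StructuredCase:
    """One hand-labelled decision case: structured lesions in, expected
    per-lesion outcomes and patient recommendation out."""

    case_id: str
    lesions: list[LesionRecord]
    expected_outcomes: list[OutcomeCode]
    expected_recommendation: Recommendation


def load_structured_cases() -> list[StructuredCase]:
    """Load the packaged structured-case fixture (103 cases, 117 lesions).

    Expected labels were assigned by hand from the guideline rule table,
    independently of the decision engine.
    """
    text = (
        resources.files("skinmdt")
        .joinpath("data", "structured_cases.csv")
        .read_text("utf-8")
    )
    grouped: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in csv.DictReader(io.StringIO(text)):
        cid = row["case_id"]
        if cid not in grouped:
            grouped[cid] = []
            order.append(cid)
        grouped[cid].append(row)
    cases = []
    for cid in order:
        rows = grouped[cid]
        cases.append(
            StructuredCase(
                case_id=cid,
                lesions=[LesionRecord.from_row(r) for r in rows],
                expected_outcomes=[OutcomeCode(r["expected_outcome"]) for r in rows],
                expected_recommendation=Recommendation(
                    rows[0]["expected_recommendation"]
                ),
            )
        )
    return cases
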
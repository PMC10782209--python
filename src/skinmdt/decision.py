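"""Guideline-mapped decision engine.

Maps structured lesion records onto the eleven rule-table outcomes and
aggregates them into one of five patient-level recommendations.  Outputs
are hard classes (a recommendation fires or it does not); no probabilities
or scores are ever attached.

The per-lesion rules are evaluated in a fixed order, first match wins:

1. any other cancer / in-situ / intermediate lesion -> free-text review
2. benign or non-specific (any margin outcome) -> no follow-up
3. BCC on a diagnostic sampling biopsy (punch/incision/shave/curettage)
   -> further excisional, destructive or non-surgical treatment
4. supplemental (re-excision/cavity) specimen -> outcome by margin polarity
5. recurrent BCC -> 5-year surveillance
6. incompletely excised BCC (peripheral, deep or both) -> offer re-excision
7. completely excised single BCC -> no follow-up

Rule 7 is total for BCC excisions, so every valid record maps to exactly
one outcome.  A patient with two or more BCC lesions additionally fires the
multiple-BCC rule (5-year surveillance).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from .labels import (
    DEFAULT_PRECEDENCE,
    OUTCOME_TO_RECOMMENDATION,
    OutcomeCode,
    Recommendation,
)
from .records import (
    DIAGNOSTIC_BIOPSY_TYPES,
    Diagnosis,
    LesionRecord,
    MarginStatus,
)


class DecisionInputError(ValueError):
    """Invalid input to the decision engine (e.g. no lesions)."""


class LetterTemplateError(KeyError):
    """A letter template placeholder could not be resolved."""


@dataclass
class LesionOutcome:
    """One fired row of the guideline rule table."""

    code: OutcomeCode
    triggering_rule: str
    source_lesions: list[str] = field(default_factory=list)

    @property
    def recommendation(self) -> Recommendation:
        return OUTCOME_TO_RECOMMENDATION[self.code]


@dataclass
class PatientDecision:
    """Hard-class management decision for one patient."""

    patient_id: str
    lesion_outcomes: list[LesionOutcome]
    recommendation: Recommendation
    rationale: list[str]


def classify_lesion_outcome(
    record: LesionRecord, is_supplemental: Optional[bool] = None
) -> LesionOutcome:
    """Map one structured lesion to its rule-table outcome.

    ``is_supplemental`` overrides the record's own flag when given (the
    flag marks re-excision / cavity specimens of a previously treated
    lesion, whose margin polarity drives dedicated rule rows).
    """
    record.validate()
    supp = record.supplemental if is_supplemental is None else is_supplemental
    label = [record.specimen_label]

    if record.diagnosis_class in (
        Diagnosis.OTHER_CANCER,
        Diagnosis.OTHER_IN_SITU,
        Diagnosis.OTHER_INTERMEDIATE,
    ):
        return LesionOutcome(
            OutcomeCode.OTHER_CANCER_IN_SITU_INTERMEDIATE, "rule_other_malignancy", label
        )
    if record.diagnosis_class in (Diagnosis.BENIGN, Diagnosis.NON_SPECIFIC):
        return LesionOutcome(
            OutcomeCode.BENIGN_OR_NON_SPECIFIC, "rule_benign_or_non_specific", label
        )
    # from here on the diagnosis is BCC
    if record.excision_type in DIAGNOSTIC_BIOPSY_TYPES:
        return LesionOutcome(
            OutcomeCode.DIAGNOSTIC_BIOPSY_BCC, "rule_diagnostic_biopsy", label
        )
    if supp:
        if record.peripheral_margin is MarginStatus.INVOLVED:
            code, rule = (
                OutcomeCode.SUPPLEMENTAL_PERIPHERAL_POSITIVE,
                "rule_supplemental_peripheral_positive",
            )
        elif record.deep_margin is MarginStatus.INVOLVED:
            code, rule = (
                OutcomeCode.SUPPLEMENTAL_DEEP_POSITIVE,
                "rule_supplemental_deep_positive",
            )
        elif (
            record.deep_margin is MarginStatus.CLEAR
            and record.peripheral_margin is MarginStatus.NOT_STATED
        ):
            code, rule = (
                OutcomeCode.SUPPLEMENTAL_DEEP_NEGATIVE,
                "rule_supplemental_deep_negative",
            )
        else:
            code, rule = (
                OutcomeCode.SUPPLEMENTAL_PERIPHERAL_NEGATIVE,
                "rule_supplemental_peripheral_negative",
            )
        return LesionOutcome(code, rule, label)
    if record.recurrent:
        return LesionOutcome(OutcomeCode.RECURRENT_BCC, "rule_recurrent_bcc", label)
    if (
        record.peripheral_margin is MarginStatus.INVOLVED
        or record.deep_margin is MarginStatus.INVOLVED
    ):
        return LesionOutcome(OutcomeCode.INCOMPLETE_BCC, "rule_incomplete_bcc", label)
    return LesionOutcome(
        OutcomeCode.COMPLETE_SINGLE_BCC, "rule_complete_single_bcc", label
    )


def _validate_precedence(precedence: Sequence[Recommendation]) -> list[Recommendation]:
    prec = [Recommendation(p) for p in precedence]
    if sorted(prec, key=lambda r: r.value) != sorted(
        Recommendation, key=lambda r: r.value
    ):
        raise DecisionInputError(
            "precedence must be a permutation of the five recommendation classes"
        )
    return prec


def aggregate_recommendation(
    records: Sequence[LesionRecord],
    patient_id: str = "",
    precedence: Sequence[Recommendation] = DEFAULT_PRECEDENCE,
) -> PatientDecision:
    """Combine per-lesion outcomes into a single patient recommendation.

    Two or more BCC lesions in the same decision episode additionally fire
    the multiple-BCC surveillance rule.  The patient-level class is the
    highest-precedence recommendation among all fired outcomes.
    """
    if not records:
        raise DecisionInputError("at least one lesion record is required")
    prec = _validate_precedence(precedence)

    outcomes = [classify_lesion_outcome(r) for r in records]
    bcc_labels = [
        r.specimen_label for r in records if r.diagnosis_class is Diagnosis.BCC
    ]
    if len(bcc_labels) >= 2:
        outcomes.append(
            LesionOutcome(OutcomeCode.MULTIPLE_BCCS, "rule_multiple_bccs", bcc_labels)
        )

    rank = {r: i for i, r in enumerate(prec)}
    recommendation = min(
        (o.recommendation for o in outcomes), key=lambda r: rank[r]
    )
    return PatientDecision(
        patient_id=patient_id,
        lesion_outcomes=outcomes,
        recommendation=recommendation,
        rationale=[o.triggering_rule for o in outcomes],
    )


# ---------------------------------------------------------------------------
# Patient letters
# ---------------------------------------------------------------------------

_DIAGNOSIS_WORDING: Mapping[Diagnosis, str] = {
    Diagnosis.BCC: "a basal cell carcinoma (a common, low-risk form of skin cancer)",
    Diagnosis.BENIGN: "a benign (non-cancerous) skin lesion",
    Diagnosis.NON_SPECIFIC: "no specific diagnosis on this sample",
    Diagnosis.OTHER_CANCER: "a skin cancer other than basal cell carcinoma",
    Diagnosis.OTHER_IN_SITU: "an in-situ (surface-confined) skin lesion",
    Diagnosis.OTHER_INTERMEDIATE: "a lesion of intermediate behaviour",
}


def _diagnosis_lines(
    decision: PatientDecision, records: Optional[Sequence[LesionRecord]]
) -> str:
    lines = []
    if records:
        for rec in records:
            wording = _DIAGNOSIS_WORDING[rec.diagnosis_class]
            if rec.diagnosis_class is Diagnosis.BCC and rec.bcc_subtype:
                wording = (
                    f"a {rec.bcc_subtype} basal cell carcinoma "
                    "(a common, low-risk form of skin cancer)"
                )
            lines.append(f"- Specimen {rec.specimen_label}: {wording}.")
    else:
        for outcome in decision.lesion_outcomes:
            if outcome.code is OutcomeCode.MULTIPLE_BCCS:
                continue
            lines.append(
                f"- Specimen {', '.join(outcome.source_lesions)}: "
                f"finding reviewed under rule {outcome.triggering_rule}."
            )
    return "\n".join(lines)


def _load_letter_template(template_id: str) -> string.Template:
    name = f"letter_{template_id}.txt"
    try:
        text = (
            resources.files("skinmdt")
            .joinpath("data", "templates", name)
            .read_text("utf-8")
        )
    except FileNotFoundError as exc:
        raise LetterTemplateError(f"no letter template named {template_id!r}") from exc
    return string.Template(text)


def generate_letter(
    decision: PatientDecision,
    patient_display_fields: Mapping[str, str],
    template_id: str = "default",
    records: Optional[Sequence[LesionRecord]] = None,
) -> str:
    """Render the patient letter for a decision.

    The letter always carries the recommendation label verbatim, one
    diagnosis line per lesion, and the two standard enclosures (the BAD
    information sheet and the Melanoma UK self-examination sheet).
    Rendering is deterministic and fails loudly if a display field needed
    by the template is missing.
    """
    template = _load_letter_template(template_id)
    mapping = dict(patient_display_fields)
    mapping["recommendation"] = decision.recommendation.value
    mapping["diagnosis_lines"] = _diagnosis_lines(decision, records)
    mapping.setdefault("patient_id", decision.patient_id)

    idents = set(template.get_identifiers())
    missing = sorted(idents - set(mapping))
    if missing:
        raise LetterTemplateError(
            "missing patient display field(s): " + ", ".join(missing)
        )
    letter = template.substitute(mapping)
    return letter


def decisions_to_rows(decisions: Iterable[PatientDecision]) -> list[dict]:
    """Flatten decisions to the decisions-CSV schema."""
    return [
        {
            "patient_id": d.patient_id,
            "recommendation": d.recommendation.value,
            "rule_ids": ";".join(d.rationale),
        }
        for d in decisions
    ]
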
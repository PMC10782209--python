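"""Recommendation classes, lesion-outcome codes and their guideline mapping.

The five patient-level recommendation labels are canonical strings: they are
used byte-identically everywhere (decisions CSV, letters, confusion-matrix
axes), because downstream evaluation keys on them.
"""

from __future__ import annotations

from enum import Enum


class Recommendation(str, Enum):
    """The five patient-level management recommendations for BCC after
    primary surgical treatment (2021 BAD guideline mapping)."""

    FOLLOW_UP_5Y = "Follow-up 6-monthly for 5 years"
    FURTHER_SURGERY = (
        "Further excisional surgery, destructive surgical or non-surgical "
        "technique recommended to obtain oncological clearance"
    )
    NO_FOLLOW_UP = "No follow-up"
    RE_EXCISION = "Offer re-excision. If declined follow-up 6-monthly for 2 years"
    REVIEW_REQUIRED = (
        "Other cancerous, in situ or intermediate lesion. Review of "
        "histopathology free text required to guide management"
    )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical axis order for confusion matrices: lexicographic in the label
#: strings (which coincides with the published table's printed order).
CLASS_LABELS: list[str] = sorted(r.value for r in Recommendation)


class OutcomeCode(str, Enum):
    """Eleven per-lesion outcome rows of the guideline rule table."""

    COMPLETE_SINGLE_BCC = "complete_single_bcc"
    INCOMPLETE_BCC = "incomplete_bcc"
    MULTIPLE_BCCS = "multiple_bccs"
    RECURRENT_BCC = "recurrent_bcc"
    SUPPLEMENTAL_PERIPHERAL_POSITIVE = "supplemental_peripheral_positive"
    SUPPLEMENTAL_PERIPHERAL_NEGATIVE = "supplemental_peripheral_negative"
    SUPPLEMENTAL_DEEP_POSITIVE = "supplemental_deep_positive"
    SUPPLEMENTAL_DEEP_NEGATIVE = "supplemental_deep_negative"
    DIAGNOSTIC_BIOPSY_BCC = "diagnostic_biopsy_bcc"
    BENIGN_OR_NON_SPECIFIC = "benign_or_non_specific"
    OTHER_CANCER_IN_SITU_INTERMEDIATE = "other_cancer_in_situ_intermediate"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Each rule-table row maps to exactly one recommendation.
OUTCOME_TO_RECOMMENDATION: dict[OutcomeCode, Recommendation] = {
    OutcomeCode.COMPLETE_SINGLE_BCC: Recommendation.NO_FOLLOW_UP,
    OutcomeCode.INCOMPLETE_BCC: Recommendation.RE_EXCISION,
    OutcomeCode.MULTIPLE_BCCS: Recommendation.FOLLOW_UP_5Y,
    OutcomeCode.RECURRENT_BCC: Recommendation.FOLLOW_UP_5Y,
    OutcomeCode.SUPPLEMENTAL_PERIPHERAL_POSITIVE: Recommendation.RE_EXCISION,
    OutcomeCode.SUPPLEMENTAL_PERIPHERAL_NEGATIVE: Recommendation.NO_FOLLOW_UP,
    OutcomeCode.SUPPLEMENTAL_DEEP_POSITIVE: Recommendation.RE_EXCISION,
    OutcomeCode.SUPPLEMENTAL_DEEP_NEGATIVE: Recommendation.NO_FOLLOW_UP,
    OutcomeCode.DIAGNOSTIC_BIOPSY_BCC: Recommendation.FURTHER_SURGERY,
    OutcomeCode.BENIGN_OR_NON_SPECIFIC: Recommendation.NO_FOLLOW_UP,
    OutcomeCode.OTHER_CANCER_IN_SITU_INTERMEDIATE: Recommendation.REVIEW_REQUIRED,
}

#: Default precedence for aggregating several lesion outcomes into one
#: patient recommendation, highest priority first.  Ranked by escalating
#: need for human intervention: free-text review demands clinician
#: attention, then definitive further surgery, then re-excision offers,
#: then surveillance, then discharge.
DEFAULT_PRECEDENCE: tuple[Recommendation, ...] = (
    Recommendation.REVIEW_REQUIRED,
    Recommendation.FURTHER_SURGERY,
    Recommendation.RE_EXCISION,
    Recommendation.FOLLOW_UP_5Y,
    Recommendation.NO_FOLLOW_UP,
)


def recommendation_from_label(label: str) -> Recommendation:
    """Resolve a canonical label string back to its enum member."""
    try:
        return Recommendation(label)
    except ValueError as exc:
        raise ValueError(f"unknown recommendation label: {label!r}") from exc
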
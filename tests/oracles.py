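"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written in a different style from the package code
(pair-expansion counting; a predicate table walked row by row) so that a
shared mistake is unlikely.
"""

from __future__ import annotations

import math

import numpy as np

NO_FU = "No follow-up"
FU5Y = "Follow-up 6-monthly for 5 years"
FURTHER = (
    "Further excisional surgery, destructive surgical or non-surgical "
    "technique recommended to obtain oncological clearance"
)
RE_EXC = "Offer re-excision. If declined follow-up 6-monthly for 2 years"
REVIEW = (
    "Other cancerous, in situ or intermediate lesion. Review of "
    "histopathology free text required to guide management"
)

#: Escalation order used when several rule rows fire for one patient.
PRECEDENCE = [REVIEW, FURTHER, RE_EXC, FU5Y, NO_FU]

_BIOPSIES = {"punch_biopsy", "incision_biopsy", "shave_biopsy", "curettage"}


def oracle_lesion_recommendation(rec) -> str:
    """Walk the guideline rule rows, first match wins; returns the
    recommendation label for a single lesion."""
    dx = rec.diagnosis_class.value
    if dx in ("other_cancer", "other_in_situ", "other_intermediate"):
        return REVIEW
    if dx in ("benign", "non_specific"):
        return NO_FU
    assert dx == "bcc"
    if rec.excision_type.value in _BIOPSIES:
        return FURTHER
    p, d = rec.peripheral_margin.value, rec.deep_margin.value
    if rec.supplemental:
        if "involved" in (p, d):
            return RE_EXC
        return NO_FU
    if rec.recurrent:
        return FU5Y
    if "involved" in (p, d):
        return RE_EXC
    return NO_FU


def oracle_patient_recommendation(records) -> str:
    """Brute-force patient decision: per-lesion rows plus the multiple-BCC
    row, resolved by the escalation order."""
    fired = {oracle_lesion_recommendation(r) for r in records}
    if sum(1 for r in records if r.diagnosis_class.value == "bcc") >= 2:
        fired.add(FU5Y)
    for label in PRECEDENCE:
        if label in fired:
            return label
    raise AssertionError("no rule fired")


def oracle_ovr_from_matrix(counts: np.ndarray) -> list[dict]:
    """One-vs-rest metrics computed by expanding the matrix into individual
    (reference, prediction) observations and counting binary outcomes."""
    k = counts.shape[0]
    refs, preds = [], []
    for i in range(k):  # row = prediction
        for j in range(k):  # column = reference
            refs.extend([j] * int(counts[i, j]))
            preds.extend([i] * int(counts[i, j]))
    refs = np.array(refs)
    preds = np.array(preds)

    def ratio(num, den):
        return num / den if den > 0 else math.nan

    out = []
    for c in range(k):
        tp = int(np.sum((refs == c) & (preds == c)))
        fn = int(np.sum((refs == c) & (preds != c)))
        fp = int(np.sum((refs != c) & (preds == c)))
        tn = int(np.sum((refs != c) & (preds != c)))
        out.append(
            {
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "tn": tn,
                "sensitivity": ratio(tp, tp + fn),
                "specificity": ratio(tn, tn + fp),
                "ppv": ratio(tp, tp + fp),
                "npv": ratio(tn, tn + fn),
            }
        )
    return out
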
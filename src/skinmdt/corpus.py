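"""Synthetic histopathology-report corpus with gold labels.

Generates labelled BCC / non-BCC reports under the four canonical
subheadings (clinical details, macroscopic, microscopic, conclusion) so the
whole pipeline is testable without any clinical data.  Case anatomy mirrors
the guideline rule table: completely and incompletely excised BCCs,
multiple and recurrent BCCs, supplemental (re-excision/cavity) specimens,
diagnostic sampling biopsies, benign lesions and other malignancies.

The default class mixture reproduces the reference-arm class imbalance of
the published validation cohort (146 / 31 / 770 / 45 / 53 of 1045), which
is the imbalance that motivates micro-averaged evaluation downstream.

Generation is a pure function of the configuration: each patient draws
from an RNG stream split from the master seed by patient index, so the
same config always yields a byte-identical corpus.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .labels import OUTCOME_TO_RECOMMENDATION, OutcomeCode, Recommendation
from .records import (
    Diagnosis,
    ExcisionType,
    LesionRecord,
    MarginStatus,
    RawReport,
    SECTION_ORDER,
)


class CorpusConfigError(ValueError):
    """Invalid corpus-generation configuration."""


#: Reference-arm marginal counts of the published 5x5 validation table,
#: keyed by recommendation class; used as default mixture weights.
REFERENCE_CLASS_WEIGHTS: dict[Recommendation, float] = {
    Recommendation.FOLLOW_UP_5Y: 146.0,
    Recommendation.FURTHER_SURGERY: 31.0,
    Recommendation.NO_FOLLOW_UP: 770.0,
    Recommendation.RE_EXCISION: 45.0,
    Recommendation.REVIEW_REQUIRED: 53.0,
}

DEFAULT_LESION_DISTRIBUTION: dict[int, float] = {1: 0.80, 2: 0.14, 3: 0.04, 4: 0.02}


@dataclass
class GenerationConfig:
    n_patients: int
    class_mixture: dict[Recommendation, float] = field(
        default_factory=lambda: dict(REFERENCE_CLASS_WEIGHTS)
    )
    lesions_per_patient_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LESION_DISTRIBUTION)
    )
    noise_level: float = 0.0
    seed: int = 0
    template_set_id: str = "default"

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise CorpusConfigError("n_patients must be >= 1")
        self.class_mixture = {
            Recommendation(k): float(v) for k, v in self.class_mixture.items()
        }
        if any(v < 0 for v in self.class_mixture.values()):
            raise CorpusConfigError("class_mixture weights must be non-negative")
        total = sum(self.class_mixture.values())
        if total <= 0:
            raise CorpusConfigError("class_mixture weights must sum to > 0")
        self.lesions_per_patient_distribution = {
            int(k): float(v) for k, v in self.lesions_per_patient_distribution.items()
        }
        if any(
            k < 1 or k > 4 for k in self.lesions_per_patient_distribution
        ):
            raise CorpusConfigError("lesion counts must be in 1..4")
        s = sum(self.lesions_per_patient_distribution.values())
        if abs(s - 1.0) > 1e-9:
            raise CorpusConfigError(
                f"lesions_per_patient_distribution must sum to 1, got {s}"
            )
        if not 0.0 <= self.noise_level <= 1.0:
            raise CorpusConfigError("noise_level must be in [0, 1]")
        if self.template_set_id != "default":
            raise CorpusConfigError(
                f"unknown template_set_id {self.template_set_id!r}"
            )

    # --- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "class_mixture": {k.value: v for k, v in self.class_mixture.items()},
            "lesions_per_patient_distribution": {
                str(k): v for k, v in self.lesions_per_patient_distribution.items()
            },
            "noise_level": self.noise_level,
            "seed": self.seed,
            "template_set_id": self.template_set_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerationConfig":
        kwargs = dict(d)
        if "class_mixture" in kwargs:
            kwargs["class_mixture"] = {
                Recommendation(k): v for k, v in kwargs["class_mixture"].items()
            }
        if "lesions_per_patient_distribution" in kwargs:
            kwargs["lesions_per_patient_distribution"] = {
                int(k): v
                for k, v in kwargs["lesions_per_patient_distribution"].items()
            }
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "GenerationConfig":
        text = Path(path).read_text("utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def sha256(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


@dataclass
class GoldCase:
    """A synthetic patient with ground-truth structure and labels."""

    patient_id: str
    lesions: list[LesionRecord]
    expected_lesion_outcomes: list[OutcomeCode]
    expected_recommendation: Recommendation
    # rendering metadata (not part of the structured gold payload)
    lesion_terms: list[str] = field(default_factory=list)
    sites: list[str] = field(default_factory=list)
    age: int = 70

    def __post_init__(self) -> None:
        if not self.lesions:
            raise CorpusConfigError("a gold case needs at least one lesion")


@dataclass
class Corpus:
    config: GenerationConfig
    cases: list[GoldCase]
    reports: list[RawReport]
    manifest: dict


# ---------------------------------------------------------------------------
# Lesion builders (one per rule-table archetype)
# ---------------------------------------------------------------------------

_SITES = (
    "left cheek", "right temple", "nasal tip", "left forearm", "upper back",
    "right lower leg", "scalp vertex", "left ear helix", "forehead", "chin",
)
_BCC_SUBTYPES = ("nodular", "superficial", "infiltrative", "micronodular", "morphoeic")
_BENIGN_TERMS = (
    "seborrhoeic keratosis", "dermatofibroma", "intradermal naevus",
    "benign lichenoid keratosis", "fibroepithelial polyp",
)
_OTHER_TERMS = (
    # (surface term, diagnosis class)
    ("invasive squamous cell carcinoma", Diagnosis.OTHER_CANCER),
    ("malignant melanoma", Diagnosis.OTHER_CANCER),
    ("squamous cell carcinoma in situ (Bowen's disease)", Diagnosis.OTHER_IN_SITU),
    ("melanoma in situ", Diagnosis.OTHER_IN_SITU),
    ("keratoacanthoma", Diagnosis.OTHER_INTERMEDIATE),
    ("atypical fibroxanthoma", Diagnosis.OTHER_INTERMEDIATE),
)
_BIOPSY_TYPES = (
    ExcisionType.PUNCH_BIOPSY,
    ExcisionType.INCISION_BIOPSY,
    ExcisionType.SHAVE_BIOPSY,
    ExcisionType.CURETTAGE,
)


def _mm(rng: np.random.Generator) -> float:
    return float(round(rng.uniform(0.3, 5.0), 1))


def _clear_margins(rng, record_kwargs: dict) -> None:
    if rng.random() < 0.7:
        record_kwargs.update(
            peripheral_margin=MarginStatus.CLEAR,
            deep_margin=MarginStatus.CLEAR,
            peripheral_margin_mm=_mm(rng),
            deep_margin_mm=_mm(rng),
        )
    else:
        record_kwargs.update(
            peripheral_margin=MarginStatus.CLEAR, deep_margin=MarginStatus.CLEAR
        )


def _complete_bcc(rng, label) -> tuple[LesionRecord, OutcomeCode, str]:
    subtype = str(rng.choice(_BCC_SUBTYPES))
    kwargs = dict(
        specimen_label=label,
        diagnosis_class=Diagnosis.BCC,
        bcc_subtype=subtype,
        excision_type=ExcisionType.EXCISION,
    )
    _clear_margins(rng, kwargs)
    return (
        LesionRecord(**kwargs),
        OutcomeCode.COMPLETE_SINGLE_BCC,
        f"{subtype} basal cell carcinoma",
    )


def _recurrent_bcc(rng, label) -> tuple[LesionRecord, OutcomeCode, str]:
    record, _, term = _complete_bcc(rng, label)
    record.recurrent = True
    return record, OutcomeCode.RECURRENT_BCC, term


def _benign(rng, label) -> tuple[LesionRecord, OutcomeCode, str]:
    term = str(rng.choice(_BENIGN_TERMS))
    kwargs = dict(
        specimen_label=label,
        diagnosis_class=Diagnosis.BENIGN,
        excision_type=ExcisionType.EXCISION,
    )
    u = rng.random()
    if u < 0.3:
        kwargs.update(
            peripheral_margin=MarginStatus.CLEAR, deep_margin=MarginStatus.CLEAR
        )
    elif u < 0.4:
        kwargs.update(
            peripheral_margin=MarginStatus.INVOLVED, deep_margin=MarginStatus.INVOLVED
        )
    return LesionRecord(**kwargs), OutcomeCode.BENIGN_OR_NON_SPECIFIC, term


def _biopsy_bcc(rng, label) -> tuple[LesionRecord, OutcomeCode, str]:
    subtype = str(rng.choice(_BCC_SUBTYPES))
    excision = _BIOPSY_TYPES[int(rng.integers(len(_BIOPSY_TYPES)))]
    record = LesionRecord(
        specimen_label=label,
        diagnosis_class=Diagnosis.BCC,
        bcc_subtype=subtype,
        excision_type=excision,
    )
    return record, OutcomeCode.DIAGNOSTIC_BIOPSY_BCC, f"{subtype} basal cell carcinoma"


def _incomplete_bcc(rng, label) -> tuple[LesionRecord, OutcomeCode, str]:
    subtype = str(rng.choice(_BCC_SUBTYPES))
    kwargs = dict(
        specimen_label=label,
        diagnosis_class=Diagnosis.BCC,
        bcc_subtype=subtype,
        excision_type=ExcisionType.EXCISION,
    )
    variant = int(rng.integers(4))
    if variant == 0:  # deep involved numerically, peripheral clear
        kwargs.update(
            peripheral_margin=MarginStatus.CLEAR,
            peripheral_margin_mm=_mm(rng),
            deep_margin=MarginStatus.INVOLVED,
            deep_margin_mm=0.0,
        )
    elif variant == 1:  # peripheral involved lexically, deep clear
        kwargs.update(
            peripheral_margin=MarginStatus.INVOLVED,
            deep_margin=MarginStatus.CLEAR,
            deep_margin_mm=_mm(rng),
        )
    elif variant == 2:  # both involved, generic wording
        kwargs.update(
            peripheral_margin=MarginStatus.INVOLVED,
            deep_margin=MarginStatus.INVOLVED,
        )
    else:  # deep involved, peripheral unmentioned
        kwargs.update(deep_margin=MarginStatus.INVOLVED, deep_margin_mm=0.0)
    return (
        LesionRecord(**kwargs),
        OutcomeCode.INCOMPLETE_BCC,
        f"{subtype} basal cell carcinoma",
    )


def _supplemental_negative(rng, label) -> tuple[LesionRecord, OutcomeCode, str]:
    variant = int(rng.integers(3))
    if variant == 0:  # residual BCC, all margins clear numerically
        subtype = str(rng.choice(_BCC_SUBTYPES))
        record = LesionRecord(
            specimen_label=label,
            diagnosis_class=Diagnosis.BCC,
            bcc_subtype=subtype,
            excision_type=ExcisionType.EXCISION,
            peripheral_margin=MarginStatus.CLEAR,
            deep_margin=MarginStatus.CLEAR,
            peripheral_margin_mm=_mm(rng),
            deep_margin_mm=_mm(rng),
            supplemental=True,
        )
        return (
            record,
            OutcomeCode.SUPPLEMENTAL_PERIPHERAL_NEGATIVE,
            f"residual {subtype} basal cell carcinoma",
        )
    if variant == 1:  # residual BCC, only the deep margin reported (clear)
        subtype = str(rng.choice(_BCC_SUBTYPES))
        record = LesionRecord(
            specimen_label=label,
            diagnosis_class=Diagnosis.BCC,
            bcc_subtype=subtype,
            excision_type=ExcisionType.EXCISION,
            deep_margin=MarginStatus.CLEAR,
            supplemental=True,
        )
        return (
            record,
            OutcomeCode.SUPPLEMENTAL_DEEP_NEGATIVE,
            f"residual {subtype} basal cell carcinoma",
        )
    # no residual tumour in the re-excision: non-specific histology
    record = LesionRecord(
        specimen_label=label,
        diagnosis_class=Diagnosis.NON_SPECIFIC,
        excision_type=ExcisionType.EXCISION,
        supplemental=True,
    )
    return record, OutcomeCode.BENIGN_OR_NON_SPECIFIC, "no residual tumour"


def _supplemental_positive(rng, label) -> tuple[LesionRecord, OutcomeCode, str]:
    subtype = str(rng.choice(_BCC_SUBTYPES))
    if rng.random() < 0.5:  # peripheral positive, lexical
        record = LesionRecord(
            specimen_label=label,
            diagnosis_class=Diagnosis.BCC,
            bcc_subtype=subtype,
            excision_type=ExcisionType.EXCISION,
            peripheral_margin=MarginStatus.INVOLVED,
            supplemental=True,
        )
        code = OutcomeCode.SUPPLEMENTAL_PERIPHERAL_POSITIVE
    else:  # deep positive, numeric 0 mm, peripheral clear
        record = LesionRecord(
            specimen_label=label,
            diagnosis_class=Diagnosis.BCC,
            bcc_subtype=subtype,
            excision_type=ExcisionType.EXCISION,
            peripheral_margin=MarginStatus.CLEAR,
            peripheral_margin_mm=_mm(rng),
            deep_margin=MarginStatus.INVOLVED,
            deep_margin_mm=0.0,
            supplemental=True,
        )
        code = OutcomeCode.SUPPLEMENTAL_DEEP_POSITIVE
    return record, code, f"residual {subtype} basal cell carcinoma"


def _other_lesion(rng, label) -> tuple[LesionRecord, OutcomeCode, str]:
    term, dx = _OTHER_TERMS[int(rng.integers(len(_OTHER_TERMS)))]
    kwargs = dict(
        specimen_label=label, diagnosis_class=dx, excision_type=ExcisionType.EXCISION
    )
    _clear_margins(rng, kwargs)
    return LesionRecord(**kwargs), OutcomeCode.OTHER_CANCER_IN_SITU_INTERMEDIATE, term


# ---------------------------------------------------------------------------
# Case sampling
# ---------------------------------------------------------------------------


def _labels(n: int) -> list[str]:
    return ["1"] if n == 1 else [chr(ord("A") + i) for i in range(n)]


def sample_case(
    target_class: Recommendation,
    rng: np.random.Generator,
    lesions_per_patient_distribution: Optional[dict[int, float]] = None,
) -> GoldCase:
    """Draw one gold case whose expected recommendation is ``target_class``.

    Lesion attributes are mutually consistent with the target class under
    the guideline rule table; incidental attributes (subtype, site, margin
    distances, phrasing variants) vary randomly.
    """
    target = Recommendation(target_class)
    dist = lesions_per_patient_distribution or dict(DEFAULT_LESION_DISTRIBUTION)
    counts = sorted(dist)
    probs = np.array([dist[c] for c in counts], dtype=float)
    probs = probs / probs.sum()
    n = int(rng.choice(counts, p=probs))

    builders: list = []
    if target is Recommendation.NO_FOLLOW_UP:
        primary = [_complete_bcc, _benign, _supplemental_negative][int(rng.integers(3))]
        builders = [primary] + [_benign] * (n - 1)
    elif target is Recommendation.FOLLOW_UP_5Y:
        if n == 1 or rng.random() < 0.4:
            builders = [_recurrent_bcc] + [_benign] * (n - 1)
        else:
            builders = [_complete_bcc] * n
    elif target is Recommendation.FURTHER_SURGERY:
        builders = [_biopsy_bcc] + [_benign] * (n - 1)
    elif target is Recommendation.RE_EXCISION:
        primary = [_incomplete_bcc, _supplemental_positive][int(rng.integers(2))]
        builders = [primary] + [_benign] * (n - 1)
    elif target is Recommendation.REVIEW_REQUIRED:
        builders = [_other_lesion] + [_benign] * (n - 1)
    else:  # pragma: no cover - enum is closed
        raise CorpusConfigError(f"unreachable recommendation class: {target}")

    labels = _labels(len(builders))
    lesions, outcomes, terms = [], [], []
    for builder, label in zip(builders, labels):
        record, code, term = builder(rng, label)
        lesions.append(record)
        outcomes.append(code)
        terms.append(term)
    n_bcc = sum(1 for r in lesions if r.diagnosis_class is Diagnosis.BCC)
    case_outcomes = list(outcomes)
    if n_bcc >= 2:
        case_outcomes.append(OutcomeCode.MULTIPLE_BCCS)

    # construction-time consistency check against the precedence mapping
    from .labels import DEFAULT_PRECEDENCE

    rank = {r: i for i, r in enumerate(DEFAULT_PRECEDENCE)}
    implied = min(
        (OUTCOME_TO_RECOMMENDATION[c] for c in case_outcomes), key=lambda r: rank[r]
    )
    if implied is not target:
        raise CorpusConfigError(
            f"scenario for {target.value!r} implies {implied.value!r}"
        )

    sites = [str(rng.choice(_SITES)) for _ in lesions]
    age = int(rng.integers(40, 96))
    return GoldCase(
        patient_id="",
        lesions=lesions,
        expected_lesion_outcomes=case_outcomes,
        expected_recommendation=target,
        lesion_terms=terms,
        sites=sites,
        age=age,
    )


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def _an(term: str) -> str:
    return ("an " if term[0].lower() in "aeiou" else "a ") + term


def _pick(rng, options: Sequence[str]) -> str:
    return options[int(rng.integers(len(options)))]


def _macro_sentence(rng, record: LesionRecord, site: str) -> str:
    a, b = int(rng.integers(8, 26)), int(rng.integers(4, 15))
    if record.supplemental:
        return _pick(
            rng,
            (
                f"Re-excision specimen from the {site} scar: ellipse of skin "
                f"{a} x {b} mm.",
                f"Further excision of the cavity wall at the {site}: skin "
                f"excision {a} x {b} mm.",
                f"Cavity re-excision from the {site}: ellipse of skin "
                f"{a} x {b} mm.",
            ),
        )
    ex = record.excision_type
    if ex is ExcisionType.EXCISION:
        return _pick(
            rng,
            (
                f"Ellipse of skin from the {site} measuring {a} x {b} mm.",
                f"Skin excision specimen from the {site}, {a} x {b} mm.",
                f"Wide local excision of skin from the {site}, {a} x {b} mm.",
            ),
        )
    d = int(rng.integers(3, 7))
    if ex is ExcisionType.PUNCH_BIOPSY:
        return _pick(
            rng,
            (
                f"Punch biopsy of skin from the {site}, {d} mm.",
                f"A {d} mm punch biopsy of skin from the {site}.",
                f"Skin punch biopsy from the {site} measuring {d} mm.",
            ),
        )
    if ex is ExcisionType.INCISION_BIOPSY:
        return _pick(
            rng,
            (
                f"Incision biopsy of skin from the {site}.",
                f"Incisional biopsy from the {site}.",
                f"An incision biopsy specimen from the {site}.",
            ),
        )
    if ex is ExcisionType.SHAVE_BIOPSY:
        return _pick(
            rng,
            (
                f"Shave biopsy of skin from the {site}.",
                f"Superficial shave biopsy from the {site}.",
                f"A shave biopsy specimen from the {site}.",
            ),
        )
    return _pick(
        rng,
        (
            f"Curettage specimen from the {site}.",
            f"Curettings of skin from the {site}.",
            f"Skin curettage specimen from the {site}.",
        ),
    )


def _fmt_mm(v: float) -> str:
    return f"{v:g}"


def _margin_sentence(rng, record: LesionRecord) -> Optional[str]:
    p, d = record.peripheral_margin, record.deep_margin
    p_mm, d_mm = record.peripheral_margin_mm, record.deep_margin_mm
    if p is MarginStatus.NOT_STATED and d is MarginStatus.NOT_STATED:
        if record.excision_type in (
            ExcisionType.PUNCH_BIOPSY,
            ExcisionType.INCISION_BIOPSY,
            ExcisionType.SHAVE_BIOPSY,
            ExcisionType.CURETTAGE,
        ):
            return "Margins are not assessable in this diagnostic sample."
        return None
    if (
        p is MarginStatus.CLEAR
        and d is MarginStatus.CLEAR
        and p_mm is not None
        and d_mm is not None
    ):
        pf, df = _fmt_mm(p_mm), _fmt_mm(d_mm)
        return _pick(
            rng,
            (
                f"The lesion is completely excised; nearest peripheral margin "
                f"{pf} mm, deep margin {df} mm.",
                f"Excision appears complete with peripheral margin {pf} mm and "
                f"deep margin {df} mm.",
                f"Clear of all margins; peripheral {pf} mm, deep {df} mm.",
            ),
        )
    if p is MarginStatus.CLEAR and d is MarginStatus.CLEAR:
        return _pick(
            rng,
            (
                "The lesion is completely excised.",
                "The lesion appears completely excised.",
                "Excision appears complete.",
            ),
        )
    if (
        p is MarginStatus.INVOLVED
        and d is MarginStatus.INVOLVED
        and p_mm is None
        and d_mm is None
    ):
        return _pick(
            rng,
            ("The lesion is incompletely excised.", "Excision is incomplete."),
        )
    frags = []
    if p is MarginStatus.CLEAR:
        frags.append(
            f"nearest peripheral margin {_fmt_mm(p_mm)} mm"
            if p_mm is not None
            else "the peripheral margin is clear"
        )
    elif p is MarginStatus.INVOLVED:
        frags.append(
            "peripheral margin 0 mm"
            if p_mm is not None
            else _pick(
                rng,
                (
                    "the tumour extends to the peripheral margin",
                    "tumour reaches the peripheral margin",
                    "tumour involves the peripheral margin",
                ),
            )
        )
    if d is MarginStatus.CLEAR:
        frags.append(
            f"deep margin {_fmt_mm(d_mm)} mm"
            if d_mm is not None
            else "the deep margin is clear"
        )
    elif d is MarginStatus.INVOLVED:
        frags.append(
            "deep margin 0 mm"
            if d_mm is not None
            else _pick(
                rng,
                (
                    "the tumour extends to the deep margin",
                    "tumour reaches the deep margin",
                    "tumour involves the deep margin",
                ),
            )
        )
    sentence = "; ".join(frags)
    return sentence[0].upper() + sentence[1:] + "."


def _micro_sentences(rng, record: LesionRecord, term: str) -> list[str]:
    if record.diagnosis_class is Diagnosis.NON_SPECIFIC:
        body = [
            _pick(
                rng,
                (
                    "No residual basal cell carcinoma is seen; sections show "
                    "scar tissue only.",
                    "Sections show scar with no residual basal cell carcinoma.",
                ),
            )
        ]
    else:
        opener = _pick(
            rng,
            (
                f"Sections show {_an(term)}.",
                f"There is {_an(term)} within the dermis.",
                f"Histology demonstrates {_an(term)}.",
            ),
        )
        body = [opener]
        if term.startswith("malignant melanoma"):
            body.append(
                f"Breslow thickness {_fmt_mm(round(float(rng.uniform(0.4, 2.4)), 1))} mm."
            )
    margin = _margin_sentence(rng, record)
    if margin:
        body.append(margin)
    return body


def _conclusion_sentences(rng, record: LesionRecord, term: str) -> list[str]:
    cap = term[0].upper() + term[1:]
    if record.diagnosis_class is Diagnosis.NON_SPECIFIC:
        return ["No residual tumour identified."]
    p, d = record.peripheral_margin, record.deep_margin
    prefix = "Recurrent " + term if record.recurrent else cap
    if p is MarginStatus.CLEAR and d is MarginStatus.CLEAR:
        sentences = [f"{prefix}, completely excised."]
    elif p is MarginStatus.INVOLVED and d is MarginStatus.INVOLVED:
        sentences = [f"{prefix}, incompletely excised."]
    elif MarginStatus.INVOLVED in (p, d) and MarginStatus.CLEAR in (p, d):
        sentences = [f"{prefix}, incompletely excised."]
    elif p is MarginStatus.INVOLVED:
        sentences = [f"{prefix}; peripheral margin involved."]
    elif d is MarginStatus.INVOLVED:
        sentences = [f"{prefix}; deep margin involved."]
    elif d is MarginStatus.CLEAR and p is MarginStatus.NOT_STATED:
        sentences = [f"{prefix}.", "The deep margin is clear."]
    else:
        sentences = [f"{prefix}."]
    if record.diagnosis_class is Diagnosis.BENIGN and rng.random() < 0.3:
        sentences.append("No evidence of basal cell carcinoma.")
    return sentences


_RECURRENCE_CLINICAL = (
    "Recurrent lesion at the {site}.",
    "Recurrence of a previously excised lesion at the {site}.",
    "Re-presentation of a lesion at the {site}, previously excised.",
)

_DISTRACTORS = (
    "There is background solar elastosis.",
    "Mild chronic inflammation is noted in the dermis.",
    "The epidermis shows hyperkeratosis.",
    "No perineural invasion is identified.",
)

_SPELLING_FLIPS = (
    ("tumour", "tumor"),
    ("Tumour", "Tumor"),
    ("naevus", "nevus"),
    ("seborrhoeic", "seborrheic"),
)


def _apply_noise(rng, sentence: str, noise_level: float) -> str:
    if noise_level <= 0 or rng.random() >= noise_level:
        return sentence
    op = int(rng.integers(3))
    if op == 0:  # hedging prefix
        prefix = _pick(rng, ("In my opinion, ", "It appears that "))
        return prefix + sentence[0].lower() + sentence[1:]
    if op == 1:  # spelling flip
        for before, after in _SPELLING_FLIPS:
            if before in sentence:
                return sentence.replace(before, after)
        return sentence
    # mild synonym swap
    return sentence.replace("Sections show", "Histological sections demonstrate")


def render_report(
    case: GoldCase, config: GenerationConfig, rng: np.random.Generator
) -> RawReport:
    """Realise a gold case as report text under the canonical subheadings.

    Every gold attribute is surfaced by one of several phrasings; lexical
    noise (hedging, spelling flips, distractor sentences) rewords or adds
    text but never removes the realisation of a gold attribute.
    """
    multi = len(case.lesions) > 1
    noise = config.noise_level

    clinical = [f"{case.age}-year-old patient."]
    for record, site in zip(case.lesions, case.sites):
        clinical.append(f"Lesion at the {site}.")
        if record.recurrent and not multi:
            clinical.append(_pick(rng, _RECURRENCE_CLINICAL).format(site=site))
        if record.supplemental and not multi:
            clinical.append(f"Previous excision at the {site}; re-excision of margins.")

    macro, micro, conclusion = [], [], []
    for i, (record, site, term) in enumerate(
        zip(case.lesions, case.sites, case.lesion_terms)
    ):
        label = f"{record.specimen_label}. " if multi else ""
        macro_s = [_macro_sentence(rng, record, site)]
        micro_s = _micro_sentences(rng, record, term)
        concl_s = _conclusion_sentences(rng, record, term)
        micro_s = [_apply_noise(rng, s, noise) for s in micro_s]
        if noise > 0 and rng.random() < noise:
            micro_s.append(_pick(rng, _DISTRACTORS))
        macro.append(label + " ".join(macro_s))
        micro.append(label + " ".join(micro_s))
        conclusion.append(label + " ".join(concl_s))

    return RawReport(
        report_id="",
        patient_id=case.patient_id,
        subheadings={
            "clinical_details": " ".join(clinical),
            "macroscopic": " ".join(macro),
            "microscopic": " ".join(micro),
            "conclusion": " ".join(conclusion),
        },
    )


# ---------------------------------------------------------------------------
# Corpus generation and I/O
# ---------------------------------------------------------------------------


def generate_corpus(config: GenerationConfig) -> Corpus:
    """Generate the full labelled corpus for a configuration.

    Pure function of the config: per-patient RNG streams are derived from
    ``(seed, patient_index)``, so regenerating any patient in isolation
    reproduces the same case.
    """
    classes = sorted(config.class_mixture, key=lambda r: r.value)
    weights = np.array([config.class_mixture[c] for c in classes], dtype=float)
    probs = weights / weights.sum()

    cases: list[GoldCase] = []
    reports: list[RawReport] = []
    class_counts = {c.value: 0 for c in classes}
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        target = classes[int(rng.choice(len(classes), p=probs))]
        case = sample_case(target, rng, config.lesions_per_patient_distribution)
        case.patient_id = f"P{i + 1:05d}"
        report = render_report(case, config, rng)
        report.report_id = f"R{i + 1:05d}"
        report.patient_id = case.patient_id
        cases.append(case)
        reports.append(report)
        class_counts[target.value] += 1

    manifest = {
        "generator": "skinmdt.corpus",
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "n_patients": config.n_patients,
        "class_counts": class_counts,
    }
    return Corpus(config=config, cases=cases, reports=reports, manifest=manifest)


GOLD_FIELDS = (
    "patient_id",
    "report_id",
    *LesionRecord.CSV_FIELDS,
    "expected_outcome",
    "expected_recommendation",
)

CORPUS_FIELDS = (
    "patient_id",
    "report_id",
    "clinical_details",
    "macroscopic",
    "microscopic",
    "conclusion",
)


def write_corpus(corpus: Corpus, out_dir) -> None:
    """Write reports (one UTF-8 text file each), corpus CSV, gold CSV and
    the JSON manifest under ``out_dir``."""
    out = Path(out_dir)
    reports_dir = out / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    for report in corpus.reports:
        path = reports_dir / f"{report.patient_id}_{report.report_id}.txt"
        path.write_text(report.to_text(), encoding="utf-8")

    with open(out / "corpus.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CORPUS_FIELDS)
        writer.writeheader()
        for report in corpus.reports:
            writer.writerow(
                {
                    "patient_id": report.patient_id,
                    "report_id": report.report_id,
                    **{s: report.subheadings[s] for s in SECTION_ORDER},
                }
            )

    with open(out / "gold.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=GOLD_FIELDS)
        writer.writeheader()
        for case, report in zip(corpus.cases, corpus.reports):
            per_lesion = [
                c for c in case.expected_lesion_outcomes
                if c is not OutcomeCode.MULTIPLE_BCCS
            ]
            for record, code in zip(case.lesions, per_lesion):
                writer.writerow(
                    {
                        "patient_id": case.patient_id,
                        "report_id": report.report_id,
                        **record.to_row(),
                        "expected_outcome": code.value,
                        "expected_recommendation": case.expected_recommendation.value,
                    }
                )

    (out / "manifest.json").write_text(
        json.dumps(corpus.manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_corpus_csv(path) -> list[RawReport]:
    """Load reports back from a corpus CSV."""
    reports = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            reports.append(
                RawReport(
                    report_id=row["report_id"],
                    patient_id=row["patient_id"],
                    subheadings={s: row[s] for s in SECTION_ORDER},
                )
            )
    return reports


def read_gold_csv(path) -> list[GoldCase]:
    """Load gold cases back from a gold CSV (grouped by patient)."""
    by_patient: dict[str, list[dict]] = {}
    order: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            pid = row["patient_id"]
            if pid not in by_patient:
                by_patient[pid] = []
                order.append(pid)
            by_patient[pid].append(row)
    cases = []
    for pid in order:
        rows = by_patient[pid]
        lesions = [LesionRecord.from_row(r) for r in rows]
        outcomes = [OutcomeCode(r["expected_outcome"]) for r in rows]
        n_bcc = sum(1 for r in lesions if r.diagnosis_class is Diagnosis.BCC)
        if n_bcc >= 2:
            outcomes.append(OutcomeCode.MULTIPLE_BCCS)
        cases.append(
            GoldCase(
                patient_id=pid,
                lesions=lesions,
                expected_lesion_outcomes=outcomes,
                expected_recommendation=Recommendation(
                    rows[0]["expected_recommendation"]
                ),
            )
        )
    return cases
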
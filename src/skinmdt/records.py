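"""Core data containers: raw reports, evidence spans and structured lesions.

Margin semantics follow Royal College of Pathologists reporting for primary
BCC: a histological margin is *clear* when the nearest tumour distance
exceeds 0 mm and *involved* when it is 0 mm.  ``LesionRecord.validate``
enforces that law on every record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Optional


SECTION_ORDER: tuple[str, ...] = (
    "clinical_details",
    "macroscopic",
    "microscopic",
    "conclusion",
)


class Diagnosis(str, Enum):
    BCC = "bcc"
    BENIGN = "benign"
    NON_SPECIFIC = "non_specific"
    OTHER_CANCER = "other_cancer"
    OTHER_IN_SITU = "other_in_situ"
    OTHER_INTERMEDIATE = "other_intermediate"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class ExcisionType(str, Enum):
    PUNCH_BIOPSY = "punch_biopsy"
    INCISION_BIOPSY = "incision_biopsy"
    SHAVE_BIOPSY = "shave_biopsy"
    CURETTAGE = "curettage"
    EXCISION = "excision"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


#: Non-definitive diagnostic sampling procedures (leave tumour behind).
DIAGNOSTIC_BIOPSY_TYPES = frozenset(
    {
        ExcisionType.PUNCH_BIOPSY,
        ExcisionType.INCISION_BIOPSY,
        ExcisionType.SHAVE_BIOPSY,
        ExcisionType.CURETTAGE,
    }
)


class MarginStatus(str, Enum):
    CLEAR = "clear"
    INVOLVED = "involved"
    NOT_STATED = "not_stated"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


class RecordValidationError(ValueError):
    """A structured record violates one of its declared invariants."""


@dataclass
class EvidenceSpan:
    """A verbatim slice of one report section supporting an extracted value.

    Offsets are 0-based, end-exclusive, relative to the section text.
    """

    section: str
    start: int
    end: int
    matched_text: str
    rule_id: str

    def verify_against(self, section_text: str) -> None:
        if not (0 <= self.start < self.end <= len(section_text)):
            raise RecordValidationError(
                f"span offsets [{self.start}, {self.end}) out of bounds for "
                f"section {self.section!r} of length {len(section_text)}"
            )
        if section_text[self.start : self.end] != self.matched_text:
            raise RecordValidationError(
                f"span text mismatch in {self.section!r}: "
                f"{section_text[self.start:self.end]!r} != {self.matched_text!r}"
            )


@dataclass
class RawReport:
    """One histopathology report, organised under canonical subheadings."""

    report_id: str
    patient_id: str
    subheadings: dict[str, str]

    def __post_init__(self) -> None:
        ordered = {s: self.subheadings.get(s, "") for s in SECTION_ORDER}
        self.subheadings = ordered
        if not any(t.strip() for t in ordered.values()):
            raise RecordValidationError(
                f"report {self.report_id!r}: every subheading is empty"
            )

    @property
    def raw_text(self) -> str:
        """Concatenation of the subheadings in canonical order."""
        return "\n".join(self.subheadings[s] for s in SECTION_ORDER)

    def to_text(self) -> str:
        """Render as a plain-text report file with subheading headers."""
        parts = []
        for section in SECTION_ORDER:
            header = section.replace("_", " ").upper()
            parts.append(f"{header}:\n{self.subheadings[section]}")
        return "\n\n".join(parts) + "\n"

    @classmethod
    def from_text(cls, text: str, report_id: str, patient_id: str) -> "RawReport":
        """Parse a plain-text report written by :meth:`to_text`."""
        import re

        headers = {s.replace("_", " ").upper(): s for s in SECTION_ORDER}
        pattern = re.compile(
            r"^(" + "|".join(re.escape(h) for h in headers) + r"):\s*$",
            re.MULTILINE,
        )
        sections: dict[str, str] = {}
        matches = list(pattern.finditer(text))
        for i, m in enumerate(matches):
            start = m.end()
            end = matches[i + 1].start() if i + 1 < len(matches) else len(text)
            sections[headers[m.group(1)]] = text[start:end].strip()
        return cls(report_id=report_id, patient_id=patient_id, subheadings=sections)


@dataclass
class LesionRecord:
    """Structured extraction for a single specimen/lesion."""

    specimen_label: str = "1"
    diagnosis_class: Diagnosis = Diagnosis.NON_SPECIFIC
    bcc_subtype: Optional[str] = None
    excision_type: ExcisionType = ExcisionType.UNKNOWN
    peripheral_margin: MarginStatus = MarginStatus.NOT_STATED
    deep_margin: MarginStatus = MarginStatus.NOT_STATED
    peripheral_margin_mm: Optional[float] = None
    deep_margin_mm: Optional[float] = None
    recurrent: bool = False
    supplemental: bool = False
    evidence: list[EvidenceSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.diagnosis_class = Diagnosis(self.diagnosis_class)
        self.excision_type = ExcisionType(self.excision_type)
        self.peripheral_margin = MarginStatus(self.peripheral_margin)
        self.deep_margin = MarginStatus(self.deep_margin)
        self.validate()

    def validate(self) -> None:
        for name, status, mm in (
            ("peripheral", self.peripheral_margin, self.peripheral_margin_mm),
            ("deep", self.deep_margin, self.deep_margin_mm),
        ):
            if mm is not None:
                if mm < 0:
                    raise RecordValidationError(f"{name} margin distance < 0: {mm}")
                implied = MarginStatus.INVOLVED if mm == 0 else MarginStatus.CLEAR
                if status is not implied:
                    raise RecordValidationError(
                        f"{name} margin {mm} mm implies {implied.value}, "
                        f"got {status.value}"
                    )
            if status is MarginStatus.NOT_STATED and mm is not None:
                raise RecordValidationError(
                    f"{name} margin has a distance but status not_stated"
                )
        if self.diagnosis_class is not Diagnosis.BCC and self.bcc_subtype is not None:
            raise RecordValidationError(
                "bcc_subtype set on a non-BCC diagnosis "
                f"({self.diagnosis_class.value})"
            )

    # --- flat (CSV-friendly) serialisation -------------------------------

    CSV_FIELDS = (
        "specimen_label",
        "diagnosis_class",
        "bcc_subtype",
        "excision_type",
        "peripheral_margin",
        "deep_margin",
        "peripheral_margin_mm",
        "deep_margin_mm",
        "recurrent",
        "supplemental",
    )

    def to_row(self) -> dict:
        d = asdict(self)
        d.pop("evidence")
        for k in ("diagnosis_class", "excision_type", "peripheral_margin", "deep_margin"):
            d[k] = d[k].value if isinstance(d[k], Enum) else d[k]
        d["recurrent"] = str(self.recurrent).lower()
        d["supplemental"] = str(self.supplemental).lower()
        d["bcc_subtype"] = self.bcc_subtype or ""
        for k in ("peripheral_margin_mm", "deep_margin_mm"):
            d[k] = "" if d[k] is None else repr(float(d[k]))
        return d

    @classmethod
    def from_row(cls, row: dict) -> "LesionRecord":
        def _mm(v):
            v = (v or "").strip()
            return None if v == "" else float(v)

        def _bool(v):
            return str(v).strip().lower() in ("true", "1", "yes")

        return cls(
            specimen_label=row.get("specimen_label", "1") or "1",
            diagnosis_class=Diagnosis(row["diagnosis_class"]),
            bcc_subtype=(row.get("bcc_subtype") or None),
            excision_type=ExcisionType(row.get("excision_type") or "unknown"),
            peripheral_margin=MarginStatus(row.get("peripheral_margin") or "not_stated"),
            deep_margin=MarginStatus(row.get("deep_margin") or "not_stated"),
            peripheral_margin_mm=_mm(row.get("peripheral_margin_mm")),
            deep_margin_mm=_mm(row.get("deep_margin_mm")),
            recurrent=_bool(row.get("recurrent", "false")),
            supplemental=_bool(row.get("supplemental", "false")),
        )

    def gold_fields(self) -> tuple:
        """The comparable payload (everything except evidence)."""
        return (
            self.specimen_label,
            self.diagnosis_class,
            self.bcc_subtype,
            self.excision_type,
            self.peripheral_margin,
            self.deep_margin,
            self.peripheral_margin_mm,
            self.deep_margin_mm,
            self.recurrent,
            self.supplemental,
        )
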
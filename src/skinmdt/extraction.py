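"""Rule-based information extraction from histopathology report text.

A transparent gazetteer-plus-rules pipeline: specimen segmentation,
concept tagging (longest match wins), NegEx-style negation scoping, and
field-level extractors for diagnosis, excision type, margin status and
recurrence.  Every non-default field value carries at least one verbatim
evidence span, so any extracted value can be traced back to the exact
characters that produced it.

All matching is case-insensitive after Unicode NFKC normalisation.
Evidence offsets are 0-based, end-exclusive, relative to the section text.
"""

from __future__ import annotations

import csv
import io
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .records import (
    Diagnosis,
    EvidenceSpan,
    ExcisionType,
    LesionRecord,
    MarginStatus,
    RawReport,
    SECTION_ORDER,
)

logger = logging.getLogger(__name__)

GAZETTEER_IDS = ("diagnosis", "excision_type", "margin", "recurrence", "negation_cues")

#: Section preference orders.  Diagnosis never reads clinical details (a
#: clinical impression is not a histological diagnosis); specimen type is
#: described in the macroscopic cut-up; margins live in the microscopic
#: description and the conclusion.
_DIAGNOSIS_SECTIONS = ("conclusion", "microscopic", "macroscopic")
_EXCISION_SECTIONS = ("macroscopic", "microscopic", "conclusion")
_MARGIN_SECTIONS = ("microscopic", "conclusion")

#: Priority among competing non-negated diagnosis concepts within a section.
_DIAGNOSIS_PRIORITY = (
    Diagnosis.OTHER_CANCER,
    Diagnosis.BCC,
    Diagnosis.OTHER_IN_SITU,
    Diagnosis.OTHER_INTERMEDIATE,
    Diagnosis.BENIGN,
)

_SUPPLEMENTAL_CUES = ("re-excision", "re excision", "further excision", "cavity")

_RECURRENCE_SECTIONS = ("clinical_details", "conclusion")

_NEGATION_WINDOW_TOKENS = 6
_NEGATION_TERMINATORS = {"but", "however"}


class GazetteerError(KeyError):
    """Unknown gazetteer identifier or malformed gazetteer file."""


def normalise(text: str) -> str:
    """NFKC-normalise and casefold; preserves length for ASCII input."""
    return unicodedata.normalize("NFKC", text).casefold()


# ---------------------------------------------------------------------------
# Gazetteers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GazetteerEntry:
    term: str
    rule_id: str
    attribute: str
    value: str


class Gazetteer:
    """A curated term list with longest-match tagging."""

    def __init__(self, gazetteer_id: str, entries: Iterable[GazetteerEntry]):
        self.gazetteer_id = gazetteer_id
        self.entries = list(entries)
        if not self.entries:
            raise GazetteerError(f"gazetteer {gazetteer_id!r} is empty")
        self._by_rule = {e.rule_id: e for e in self.entries}
        # one word-bounded, case-insensitive pattern per term
        self._patterns = [
            (
                re.compile(
                    r"(?<![a-z0-9])" + re.escape(normalise(e.term)) + r"(?![a-z0-9])"
                ),
                e,
            )
            for e in self.entries
        ]

    def entry(self, rule_id: str) -> GazetteerEntry:
        return self._by_rule[rule_id]

    def tag(self, text: str, section: str = "") -> list[EvidenceSpan]:
        """Longest-match-wins concept spans, sorted by start offset."""
        norm = normalise(text)
        candidates: list[tuple[int, int, GazetteerEntry]] = []
        for pattern, entry in self._patterns:
            for m in pattern.finditer(norm):
                candidates.append((m.start(), m.end(), entry))
        # prefer longer spans, then earlier ones; suppress overlaps
        candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
        kept: list[tuple[int, int, GazetteerEntry]] = []
        for start, end, entry in candidates:
            if any(start < k_end and k_start < end for k_start, k_end, _ in kept):
                continue
            kept.append((start, end, entry))
        kept.sort(key=lambda c: c[0])
        return [
            EvidenceSpan(
                section=section,
                start=start,
                end=end,
                matched_text=text[start:end],
                rule_id=entry.rule_id,
            )
            for start, end, entry in kept
        ]


def _read_gazetteer_csv(gazetteer_id: str, text: str) -> Gazetteer:
    reader = csv.DictReader(io.StringIO(text))
    entries = [
        GazetteerEntry(
            term=row["term"].strip(),
            rule_id=row["rule_id"].strip(),
            attribute=row["attribute"].strip(),
            value=row["value"].strip(),
        )
        for row in reader
        if row.get("term", "").strip()
    ]
    return Gazetteer(gazetteer_id, entries)


class GazetteerSet:
    """The five default gazetteers, loadable from package data or a directory."""

    def __init__(self, gazetteers: dict[str, Gazetteer]):
        missing = set(GAZETTEER_IDS) - set(gazetteers)
        if missing:
            raise GazetteerError(f"missing gazetteers: {sorted(missing)}")
        self._gazetteers = gazetteers

    def __getitem__(self, gazetteer_id: str) -> Gazetteer:
        try:
            return self._gazetteers[gazetteer_id]
        except KeyError as exc:
            raise GazetteerError(
                f"unknown gazetteer_id {gazetteer_id!r}; "
                f"expected one of {GAZETTEER_IDS}"
            ) from exc

    @classmethod
    def default(cls) -> "GazetteerSet":
        root = resources.files("skinmdt").joinpath("data", "gazetteers")
        gazetteers = {
            gid: _read_gazetteer_csv(gid, root.joinpath(f"{gid}.csv").read_text("utf-8"))
            for gid in GAZETTEER_IDS
        }
        return cls(gazetteers)

    @classmethod
    def from_directory(cls, path) -> "GazetteerSet":
        from pathlib import Path

        root = Path(path)
        gazetteers = {
            gid: _read_gazetteer_csv(gid, (root / f"{gid}.csv").read_text("utf-8"))
            for gid in GAZETTEER_IDS
        }
        return cls(gazetteers)


_DEFAULT_GAZETTEERS: Optional[GazetteerSet] = None


def default_gazetteers() -> GazetteerSet:
    global _DEFAULT_GAZETTEERS
    if _DEFAULT_GAZETTEERS is None:
        _DEFAULT_GAZETTEERS = GazetteerSet.default()
    return _DEFAULT_GAZETTEERS


def tag_concepts(
    text: str, gazetteer_id: str, gazetteers: Optional[GazetteerSet] = None,
    section: str = "",
) -> list[EvidenceSpan]:
    """Tag gazetteer concepts in ``text``; see :meth:`Gazetteer.tag`."""
    gaz = (gazetteers or default_gazetteers())[gazetteer_id]
    return gaz.tag(text, section=section)


# ---------------------------------------------------------------------------
# Negation
# ---------------------------------------------------------------------------

_SENTENCE_BOUNDARY = re.compile(r"[.;!?]")
_TOKEN = re.compile(r"[a-z0-9']+")


def _sentence_bounds(text: str, pos: int) -> tuple[int, int]:
    start = 0
    for m in _SENTENCE_BOUNDARY.finditer(text, 0, pos):
        start = m.end()
    m = _SENTENCE_BOUNDARY.search(text, pos)
    end = m.start() if m else len(text)
    return start, end


def detect_negation(
    span: EvidenceSpan,
    section_text: str,
    gazetteers: Optional[GazetteerSet] = None,
) -> bool:
    """True iff the span sits in the scope of a preceding negation cue.

    Scope: same sentence, cue at most 6 tokens before the span, and not
    interrupted by a contrastive conjunction ("but", "however").
    """
    gaz = (gazetteers or default_gazetteers())["negation_cues"]
    norm = normalise(section_text)
    sent_start, sent_end = _sentence_bounds(norm, span.start)
    sentence = norm[sent_start:sent_end]
    span_local = span.start - sent_start
    for cue in gaz.tag(sentence):
        if cue.end > span_local:
            continue
        between = sentence[cue.end : span_local]
        tokens = _TOKEN.findall(between)
        if len(tokens) > _NEGATION_WINDOW_TOKENS:
            continue
        if any(t in _NEGATION_TERMINATORS for t in tokens):
            continue
        return True
    return False


# ---------------------------------------------------------------------------
# Specimen segmentation
# ---------------------------------------------------------------------------

#: Specimen label markers: "A.", "B)", "Specimen C:", "1)", "2." at a word
#: boundary followed by whitespace.
_LABEL_MARKER = re.compile(
    r"(?:(?<=^)|(?<=[\s\n]))(?:specimen\s+)?([A-J]|[1-9])[.):](?=\s)",
    re.IGNORECASE,
)


@dataclass
class SpecimenSegment:
    """Per-specimen views into each report section.

    ``sections`` maps section name -> (text slice, base offset within the
    full section text); evidence offsets are translated through the base.
    """

    label: str
    sections: dict[str, tuple[str, int]] = field(default_factory=dict)

    def text(self, section: str) -> str:
        return self.sections.get(section, ("", 0))[0]

    def base(self, section: str) -> int:
        return self.sections.get(section, ("", 0))[1]


def segment_specimens(report: RawReport) -> list[SpecimenSegment]:
    """Split each section at specimen-label markers ("A.", "B)", "1)").

    Labelled slices partition the section text (the first slice absorbs any
    preamble).  Reports without markers yield one segment labelled "1".
    Clinical details are shared context and are never split: the whole
    section is attached to every segment.
    """
    per_section_markers: dict[str, list[tuple[int, str]]] = {}
    labels_in_order: list[str] = []
    for section in ("macroscopic", "microscopic", "conclusion"):
        text = report.subheadings.get(section, "")
        markers = [
            (m.start(), m.group(1).upper()) for m in _LABEL_MARKER.finditer(text)
        ]
        per_section_markers[section] = markers
        for _, lab in markers:
            if lab not in labels_in_order:
                labels_in_order.append(lab)

    if not labels_in_order:
        seg = SpecimenSegment(label="1")
        for section in SECTION_ORDER:
            seg.sections[section] = (report.subheadings.get(section, ""), 0)
        return [seg]

    segments = {lab: SpecimenSegment(label=lab) for lab in labels_in_order}
    clinical = report.subheadings.get("clinical_details", "")
    for seg in segments.values():
        seg.sections["clinical_details"] = (clinical, 0)

    for section in ("macroscopic", "microscopic", "conclusion"):
        text = report.subheadings.get(section, "")
        markers = per_section_markers[section]
        if not markers:
            # unlabelled section in a labelled report: give it to the first
            # specimen rather than duplicating it across all of them
            segments[labels_in_order[0]].sections[section] = (text, 0)
            continue
        for i, (pos, lab) in enumerate(markers):
            start = pos if i > 0 else 0
            end = markers[i + 1][0] if i + 1 < len(markers) else len(text)
            segments[lab].sections[section] = (text[start:end], start)
    return list(segments.values())


# ---------------------------------------------------------------------------
# Field extractors
# ---------------------------------------------------------------------------


def _shift(span: EvidenceSpan, base: int) -> EvidenceSpan:
    return EvidenceSpan(
        section=span.section,
        start=span.start + base,
        end=span.end + base,
        matched_text=span.matched_text,
        rule_id=span.rule_id,
    )


def _tag_section(
    segment: SpecimenSegment,
    section: str,
    gazetteer_id: str,
    gazetteers: GazetteerSet,
) -> list[EvidenceSpan]:
    text = segment.text(section)
    if not text:
        return []
    spans = gazetteers[gazetteer_id].tag(text, section=section)
    base = segment.base(section)
    return [_shift(s, base) for s in spans]


def _non_negated(
    spans: list[EvidenceSpan],
    segment: SpecimenSegment,
    section: str,
    gazetteers: GazetteerSet,
) -> list[EvidenceSpan]:
    base = segment.base(section)
    out = []
    for span in spans:
        local = EvidenceSpan(
            span.section, span.start - base, span.end - base,
            span.matched_text, span.rule_id,
        )
        if not detect_negation(local, segment.text(section), gazetteers):
            out.append(span)
    return out


def extract_diagnosis(
    segment: SpecimenSegment, gazetteers: Optional[GazetteerSet] = None
) -> tuple[Diagnosis, Optional[str], list[EvidenceSpan]]:
    """Resolve the histological diagnosis for one specimen.

    The first section (conclusion > microscopic > macroscopic) containing a
    non-negated diagnosis concept decides; within it, concept classes
    compete by malignancy priority.  No concept anywhere -> non_specific.
    """
    gaz = gazetteers or default_gazetteers()
    dx_gaz = gaz["diagnosis"]
    for section in _DIAGNOSIS_SECTIONS:
        spans = _tag_section(segment, section, "diagnosis", gaz)
        spans = _non_negated(spans, segment, section, gaz)
        if not spans:
            continue
        by_class: dict[Diagnosis, list[EvidenceSpan]] = {}
        for span in spans:
            value = dx_gaz.entry(span.rule_id).value
            cls_name, _, subtype = value.partition(":")
            by_class.setdefault(Diagnosis(cls_name), []).append(span)
        for dx in _DIAGNOSIS_PRIORITY:
            if dx in by_class:
                chosen = by_class[dx]
                subtype = None
                if dx is Diagnosis.BCC:
                    for span in chosen:
                        value = dx_gaz.entry(span.rule_id).value
                        _, _, sub = value.partition(":")
                        if sub:
                            subtype = sub
                            break
                return dx, subtype, chosen
    return Diagnosis.NON_SPECIFIC, None, []


def extract_excision_type(
    segment: SpecimenSegment, gazetteers: Optional[GazetteerSet] = None
) -> tuple[ExcisionType, list[EvidenceSpan]]:
    """Specimen type from the macroscopic cut-up (preferred) or elsewhere."""
    gaz = gazetteers or default_gazetteers()
    ex_gaz = gaz["excision_type"]
    for section in _EXCISION_SECTIONS:
        spans = _tag_section(segment, section, "excision_type", gaz)
        if not spans:
            continue
        # biopsy terms outrank the generic "excision"/"ellipse" terms so a
        # phrase like "punch biopsy ... excision margin" resolves to punch
        values = [ExcisionType(ex_gaz.entry(s.rule_id).value) for s in spans]
        for preferred in (
            ExcisionType.PUNCH_BIOPSY,
            ExcisionType.INCISION_BIOPSY,
            ExcisionType.SHAVE_BIOPSY,
            ExcisionType.CURETTAGE,
            ExcisionType.EXCISION,
        ):
            if preferred in values:
                chosen = [s for s, v in zip(spans, values) if v is preferred]
                return preferred, chosen
    return ExcisionType.UNKNOWN, []


#: Numeric margin pattern: "nearest peripheral margin 0.5 mm",
#: "deep margin of 1 mm", "peripheral 2 mm".  The number token is captured
#: loosely so malformed values ("0..5") can be detected and skipped.
_NUMERIC_MARGIN = re.compile(
    r"(?:nearest\s+)?(peripheral|deep)\s*(?:margins?)?\s*"
    r"(?:of|is|measures|:)?\s*"
    r"(\d+(?:[.]+\d+)?)\s*mm",
)

_MALFORMED_NUMBER = re.compile(r"\d+[.][.]+\d+")


def extract_margins(
    segment: SpecimenSegment, gazetteers: Optional[GazetteerSet] = None
) -> tuple[
    MarginStatus, MarginStatus, Optional[float], Optional[float], list[EvidenceSpan]
]:
    """Peripheral and deep margin status (and distances, when stated).

    Evidence tiers, strongest first: numeric distance (> 0 mm is clear,
    0 mm is involved) > margin-specific lexical pattern > generic phrases
    ("completely excised" / "incompletely excised").  Unmentioned margins
    stay not_stated.
    """
    gaz = gazetteers or default_gazetteers()
    mg_gaz = gaz["margin"]
    # per margin: (tier, status, mm, span); higher tier wins, first hit kept
    best: dict[str, tuple[int, MarginStatus, Optional[float], EvidenceSpan]] = {}

    def consider(margin, tier, status, mm, span):
        cur = best.get(margin)
        if cur is None or tier > cur[0]:
            best[margin] = (tier, status, mm, span)

    for section in _MARGIN_SECTIONS:
        text = segment.text(section)
        if not text:
            continue
        base = segment.base(section)
        norm = normalise(text)
        for m in _NUMERIC_MARGIN.finditer(norm):
            number_token = m.group(2)
            if _MALFORMED_NUMBER.fullmatch(number_token):
                logger.warning(
                    "skipping malformed margin distance %r in section %s",
                    number_token, section,
                )
                continue
            mm_value = float(number_token)
            status = MarginStatus.INVOLVED if mm_value == 0 else MarginStatus.CLEAR
            span = EvidenceSpan(
                section=section,
                start=m.start() + base,
                end=m.end() + base,
                matched_text=text[m.start() : m.end()],
                rule_id=f"mg_numeric_{m.group(1)}",
            )
            consider(m.group(1), 2, status, mm_value, span)
        for span in _tag_section(segment, section, "margin", gaz):
            target, _, status_name = mg_gaz.entry(span.rule_id).value.partition(":")
            status = MarginStatus(status_name)
            if target == "both":
                consider("peripheral", 0, status, None, span)
                consider("deep", 0, status, None, span)
            else:
                consider(target, 1, status, None, span)

    evidence: list[EvidenceSpan] = []
    result = {}
    for margin in ("peripheral", "deep"):
        if margin in best:
            _, status, mm, span = best[margin]
            result[margin] = (status, mm)
            if span not in evidence:
                evidence.append(span)
        else:
            result[margin] = (MarginStatus.NOT_STATED, None)
    (p_status, p_mm), (d_status, d_mm) = result["peripheral"], result["deep"]
    return p_status, d_status, p_mm, d_mm, evidence


def extract_recurrence(
    segment: SpecimenSegment,
    clinical_details_text: Optional[str] = None,
    gazetteers: Optional[GazetteerSet] = None,
) -> tuple[bool, list[EvidenceSpan]]:
    """True iff a non-negated recurrence cue appears in the clinical
    details or the conclusion; lesions default to primary."""
    gaz = gazetteers or default_gazetteers()
    evidence: list[EvidenceSpan] = []
    sources: list[tuple[str, str, int]] = []
    if clinical_details_text is not None:
        sources.append(("clinical_details", clinical_details_text, 0))
    else:
        sources.append(
            ("clinical_details", segment.text("clinical_details"),
             segment.base("clinical_details"))
        )
    sources.append(("conclusion", segment.text("conclusion"), segment.base("conclusion")))

    for section, text, base in sources:
        if not text:
            continue
        for span in gaz["recurrence"].tag(text, section=section):
            if detect_negation(span, text, gaz):
                continue
            evidence.append(_shift(span, base))
    return (len(evidence) > 0), evidence


def _is_supplemental(segment: SpecimenSegment, include_clinical: bool = True) -> bool:
    # clinical details are shared context, so in multi-specimen reports the
    # supplemental cue must come from the specimen's own macroscopic slice
    sections = ("macroscopic", "clinical_details") if include_clinical else (
        "macroscopic",
    )
    for section in sections:
        text = normalise(segment.text(section))
        if any(cue in text for cue in _SUPPLEMENTAL_CUES):
            return True
    return False


def assemble_records(
    report: RawReport, gazetteers: Optional[GazetteerSet] = None
) -> list[LesionRecord]:
    """Run the full extraction pipeline over one report.

    Returns one :class:`LesionRecord` per specimen segment; deterministic
    for a fixed report text and gazetteer set.
    """
    gaz = gazetteers or default_gazetteers()
    if not any(t.strip() for t in report.subheadings.values()):
        logger.warning("report %s is empty; no records extracted", report.report_id)
        return []
    records = []
    clinical = report.subheadings.get("clinical_details", "")
    segments = segment_specimens(report)
    multi = len(segments) > 1
    for segment in segments:
        dx, subtype, dx_ev = extract_diagnosis(segment, gaz)
        excision, ex_ev = extract_excision_type(segment, gaz)
        p_status, d_status, p_mm, d_mm, mg_ev = extract_margins(segment, gaz)
        # in multi-specimen reports the shared clinical details cannot be
        # attributed to one lesion; recurrence cues must then be specimen-
        # scoped (conclusion segment)
        recurrent, rc_ev = extract_recurrence(
            segment, clinical_details_text=None if multi else clinical, gazetteers=gaz
        )
        if multi:
            recurrent = any(s.section == "conclusion" for s in rc_ev)
            rc_ev = [s for s in rc_ev if s.section == "conclusion"]
        records.append(
            LesionRecord(
                specimen_label=segment.label,
                diagnosis_class=dx,
                bcc_subtype=subtype if dx is Diagnosis.BCC else None,
                excision_type=excision,
                peripheral_margin=p_status,
                deep_margin=d_status,
                peripheral_margin_mm=p_mm,
                deep_margin_mm=d_mm,
                recurrent=recurrent,
                supplemental=_is_supplemental(segment, include_clinical=not multi),
                evidence=dx_ev + ex_ev + mg_ev + rc_ev,
            )
        )
    return records
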
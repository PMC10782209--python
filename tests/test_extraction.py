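"""Extraction: segmentation, tagging, negation, field extractors,
evidence faithfulness and the noise-0 round trip."""

import pytest

from skinmdt.extraction import (
    GazetteerError,
    assemble_records,
    default_gazetteers,
    detect_negation,
    extract_diagnosis,
    extract_excision_type,
    extract_margins,
    extract_recurrence,
    segment_specimens,
    tag_concepts,
)
from skinmdt.records import (
    Diagnosis,
    EvidenceSpan,
    ExcisionType,
    MarginStatus,
    RawReport,
)


def make_report(clinical="", macro="", micro="", conclusion="", rid="R1", pid="P1"):
    return RawReport(
        report_id=rid,
        patient_id=pid,
        subheadings={
            "clinical_details": clinical,
            "macroscopic": macro,
            "microscopic": micro,
            "conclusion": conclusion,
        },
    )


class TestSegmentation:
    def test_two_specimens_split_on_labels(self):
        report = make_report(
            macro="A. Ellipse of skin 15 x 8 mm. B. Punch biopsy of skin 4 mm.",
            micro="A. Sections show a nodular basal cell carcinoma. "
            "B. Sections show a seborrhoeic keratosis.",
            conclusion="A. Nodular basal cell carcinoma. B. Seborrhoeic keratosis.",
        )
        segments = segment_specimens(report)
        assert [s.label for s in segments] == ["A", "B"]
        assert "Punch biopsy" in segments[1].text("macroscopic")
        assert "Ellipse" not in segments[1].text("macroscopic")

    def test_unlabelled_report_yields_single_segment(self):
        report = make_report(micro="Sections show a basal cell carcinoma.")
        segments = segment_specimens(report)
        assert len(segments) == 1
        assert segments[0].label == "1"

    def test_segments_partition_each_labelled_section(self):
        macro = "A. Ellipse of skin. B. Shave biopsy. C. Curettings of skin."
        report = make_report(macro=macro, conclusion="A. BCC. B. BCC. C. BCC.")
        segments = segment_specimens(report)
        joined = "".join(s.text("macroscopic") for s in segments)
        assert joined == macro
        for s in segments:
            base = s.base("macroscopic")
            assert macro[base : base + len(s.text("macroscopic"))] == s.text(
                "macroscopic"
            )

    def test_empty_section_tolerated(self):
        report = make_report(
            macro="A. Ellipse of skin. B. Punch biopsy.", micro="",
            conclusion="A. BCC. B. BCC.",
        )
        segments = segment_specimens(report)
        assert len(segments) == 2
        assert segments[0].text("microscopic") == ""


class TestTagConcepts:
    def test_subtype_composite_wins_longest_match(self):
        spans = tag_concepts("nodular basal cell carcinoma", "diagnosis")
        assert len(spans) == 1
        assert spans[0].rule_id == "dx_bcc_nodular"
        assert spans[0].matched_text == "nodular basal cell carcinoma"

    def test_abbreviation_entry(self):
        spans = tag_concepts("Residual BCC present", "diagnosis")
        assert [s.rule_id for s in spans] == ["dx_bcc_abbrev"]

    def test_in_situ_outranks_invasive_term(self):
        spans = tag_concepts("squamous cell carcinoma in situ", "diagnosis")
        assert [s.rule_id for s in spans] == ["dx_scc_in_situ"]

    def test_empty_text(self):
        assert tag_concepts("", "diagnosis") == []

    def test_unknown_gazetteer(self):
        with pytest.raises(GazetteerError):
            tag_concepts("text", "nonexistent")

    def test_spans_sorted_and_faithful(self):
        text = "Seborrhoeic keratosis adjacent to a basal cell carcinoma."
        spans = tag_concepts(text, "diagnosis")
        starts = [s.start for s in spans]
        assert starts == sorted(starts)
        for s in spans:
            assert text[s.start : s.end] == s.matched_text


class TestNegation:
    def _span(self, text, fragment):
        start = text.lower().index(fragment.lower())
        return EvidenceSpan(
            section="conclusion",
            start=start,
            end=start + len(fragment),
            matched_text=text[start : start + len(fragment)],
            rule_id="dx_bcc",
        )

    def test_no_evidence_of_negates(self):
        text = "There is no evidence of basal cell carcinoma."
        assert detect_negation(self._span(text, "basal cell carcinoma"), text)

    def test_affirmative_mention_not_negated(self):
        text = "Basal cell carcinoma is present."
        assert not detect_negation(self._span(text, "Basal cell carcinoma"), text)

    def test_scope_terminated_by_conjunction(self):
        text = "No evidence of inflammation but basal cell carcinoma is seen."
        assert not detect_negation(self._span(text, "basal cell carcinoma"), text)

    def test_cue_outside_token_window(self):
        text = (
            "No evidence of spread to lymph nodes or other organ systems; "
            "basal cell carcinoma is seen."
        )
        assert not detect_negation(self._span(text, "basal cell carcinoma"), text)

    def test_cue_in_previous_sentence_out_of_scope(self):
        text = "No residual tumour in specimen A. Basal cell carcinoma in B."
        assert not detect_negation(self._span(text, "Basal cell carcinoma"), text)


def single_segment(**sections):
    return segment_specimens(make_report(**sections))[0]


class TestDiagnosis:
    def test_conclusion_subtype(self):
        seg = single_segment(conclusion="Infiltrative BCC, completely excised.")
        dx, subtype, evidence = extract_diagnosis(seg)
        assert dx is Diagnosis.BCC
        assert subtype == "infiltrative"
        assert evidence

    def test_other_cancer(self):
        seg = single_segment(conclusion="Squamous cell carcinoma.")
        dx, subtype, _ = extract_diagnosis(seg)
        assert dx is Diagnosis.OTHER_CANCER
        assert subtype is None

    def test_no_concept_is_non_specific(self):
        seg = single_segment(conclusion="Scar tissue only.")
        dx, subtype, evidence = extract_diagnosis(seg)
        assert dx is Diagnosis.NON_SPECIFIC
        assert evidence == []

    def test_conclusion_outranks_microscopic(self):
        seg = single_segment(
            micro="Appearances suspicious for squamous cell carcinoma.",
            conclusion="Nodular basal cell carcinoma.",
        )
        dx, subtype, _ = extract_diagnosis(seg)
        assert dx is Diagnosis.BCC

    def test_negated_bcc_falls_back_to_benign(self):
        seg = single_segment(
            conclusion="Seborrhoeic keratosis. No evidence of basal cell carcinoma."
        )
        dx, _, _ = extract_diagnosis(seg)
        assert dx is Diagnosis.BENIGN

    def test_clinical_details_never_used(self):
        seg = single_segment(clinical="Known recurrent BCC of the temple.")
        dx, _, _ = extract_diagnosis(seg)
        assert dx is Diagnosis.NON_SPECIFIC


class TestExcisionType:
    @pytest.mark.parametrize(
        "macro,expected",
        [
            ("Punch biopsy of skin 4 mm.", ExcisionType.PUNCH_BIOPSY),
            ("Ellipse of skin 15 x 8 mm.", ExcisionType.EXCISION),
            ("Wide local excision of skin.", ExcisionType.EXCISION),
            ("Curettings of skin.", ExcisionType.CURETTAGE),
            ("Superficial shave biopsy.", ExcisionType.SHAVE_BIOPSY),
            ("Incisional biopsy from the cheek.", ExcisionType.INCISION_BIOPSY),
            ("Received in formalin.", ExcisionType.UNKNOWN),
        ],
    )
    def test_macroscopic_terms(self, macro, expected):
        excision, _ = extract_excision_type(single_segment(macro=macro))
        assert excision is expected

    def test_biopsy_outranks_excision_wording_in_same_section(self):
        excision, _ = extract_excision_type(
            single_segment(macro="Punch biopsy of skin; excision margin marked.")
        )
        assert excision is ExcisionType.PUNCH_BIOPSY


class TestMargins:
    def test_numeric_clear_margins(self):
        seg = single_segment(
            micro="Nearest peripheral margin 0.5 mm, deep margin 1 mm."
        )
        p, d, pmm, dmm, _ = extract_margins(seg)
        assert (p, d) == (MarginStatus.CLEAR, MarginStatus.CLEAR)
        assert (pmm, dmm) == (0.5, 1.0)

    def test_lexical_deep_involvement_only(self):
        seg = single_segment(micro="The tumour extends to the deep margin.")
        p, d, pmm, dmm, _ = extract_margins(seg)
        assert p is MarginStatus.NOT_STATED
        assert d is MarginStatus.INVOLVED
        assert (pmm, dmm) == (None, None)

    def test_zero_distance_means_involved(self):
        seg = single_segment(micro="Deep margin 0 mm.")
        _, d, _, dmm, _ = extract_margins(seg)
        assert d is MarginStatus.INVOLVED
        assert dmm == 0.0

    def test_generic_incomplete_sets_both(self):
        seg = single_segment(conclusion="BCC, incompletely excised.")
        p, d, _, _, _ = extract_margins(seg)
        assert (p, d) == (MarginStatus.INVOLVED, MarginStatus.INVOLVED)

    def test_numeric_outranks_generic_lexical(self):
        seg = single_segment(
            micro="Peripheral margin 1.2 mm; deep margin 0 mm.",
            conclusion="BCC, incompletely excised.",
        )
        p, d, pmm, dmm, _ = extract_margins(seg)
        assert (p, d) == (MarginStatus.CLEAR, MarginStatus.INVOLVED)
        assert (pmm, dmm) == (1.2, 0.0)

    def test_malformed_distance_skipped(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="skinmdt.extraction"):
            seg = single_segment(micro="Peripheral margin 0..5 mm.")
            p, _, pmm, _, _ = extract_margins(seg)
        assert p is MarginStatus.NOT_STATED
        assert pmm is None
        assert any("malformed" in r.message for r in caplog.records)

    def test_unmentioned_margins_not_stated(self):
        seg = single_segment(micro="Sections show a basal cell carcinoma.")
        p, d, pmm, dmm, evidence = extract_margins(seg)
        assert (p, d) == (MarginStatus.NOT_STATED, MarginStatus.NOT_STATED)
        assert evidence == []


class TestRecurrence:
    def test_clinical_cue(self):
        seg = single_segment(clinical="Recurrent BCC left temple.")
        recurrent, evidence = extract_recurrence(seg)
        assert recurrent and evidence

    def test_negated_cue_ignored(self):
        seg = single_segment(clinical="No evidence of recurrence.")
        recurrent, _ = extract_recurrence(seg)
        assert not recurrent

    def test_default_primary(self):
        seg = single_segment(conclusion="Nodular basal cell carcinoma.")
        recurrent, _ = extract_recurrence(seg)
        assert not recurrent


class TestAssembleRecords:
    def test_single_specimen_complete_excision(self):
        report = make_report(
            macro="Ellipse of skin 15 x 8 mm.",
            micro="Sections show a nodular basal cell carcinoma. The lesion is "
            "completely excised; nearest peripheral margin 0.5 mm, deep "
            "margin 1 mm.",
            conclusion="Nodular basal cell carcinoma, completely excised.",
        )
        (record,) = assemble_records(report)
        assert record.diagnosis_class is Diagnosis.BCC
        assert record.bcc_subtype == "nodular"
        assert record.excision_type is ExcisionType.EXCISION
        assert record.peripheral_margin is MarginStatus.CLEAR
        assert record.deep_margin is MarginStatus.CLEAR
        assert not record.recurrent and not record.supplemental

    def test_two_specimens_get_distinct_records(self):
        report = make_report(
            macro="A. Ellipse of skin 15 x 8 mm. B. Punch biopsy of skin 4 mm.",
            micro="A. Sections show a nodular basal cell carcinoma. "
            "B. Sections show a seborrhoeic keratosis.",
            conclusion="A. Nodular basal cell carcinoma, completely excised. "
            "B. Seborrhoeic keratosis.",
        )
        records = assemble_records(report)
        assert [r.specimen_label for r in records] == ["A", "B"]
        assert records[0].diagnosis_class is Diagnosis.BCC
        assert records[1].diagnosis_class is Diagnosis.BENIGN
        assert records[1].excision_type is ExcisionType.PUNCH_BIOPSY

    def test_clinical_details_only_report_degenerates_safely(self):
        report = make_report(clinical="Lesion on the left cheek for excision.")
        (record,) = assemble_records(report)
        assert record.diagnosis_class is Diagnosis.NON_SPECIFIC
        assert record.excision_type is ExcisionType.UNKNOWN

    def test_supplemental_cue_flags_record(self):
        report = make_report(
            macro="Re-excision specimen from the temple scar: ellipse of skin "
            "18 x 9 mm.",
            conclusion="Residual nodular basal cell carcinoma, completely excised.",
        )
        (record,) = assemble_records(report)
        assert record.supplemental

    def test_determinism(self, clean_corpus):
        report = clean_corpus.reports[0]
        first = assemble_records(report)
        second = assemble_records(report)
        assert [r.gold_fields() for r in first] == [r.gold_fields() for r in second]


class TestCorpusRoundTrip:
    def test_noise_free_extraction_recovers_every_gold_field(self, clean_corpus):
        """On a noise-0 corpus the extractor must reproduce every gold
        lesion field exactly (full template sweep across all rule rows)."""
        for case, report in zip(clean_corpus.cases, clean_corpus.reports):
            records = assemble_records(report)
            assert len(records) == len(case.lesions), report.raw_text
            for gold, extracted in zip(case.lesions, records):
                assert extracted.gold_fields() == gold.gold_fields(), report.raw_text

    def test_evidence_spans_are_verbatim(self, noisy_corpus):
        for report in noisy_corpus.reports:
            for record in assemble_records(report):
                for span in record.evidence:
                    span.verify_against(report.subheadings[span.section])

    def test_every_non_default_field_has_evidence(self, clean_corpus):
        from skinmdt.records import LesionRecord

        defaults = LesionRecord()
        for report in clean_corpus.reports:
            for record in assemble_records(report):
                interesting = (
                    record.diagnosis_class is not defaults.diagnosis_class
                    or record.excision_type is not defaults.excision_type
                    or record.peripheral_margin is not defaults.peripheral_margin
                    or record.deep_margin is not defaults.deep_margin
                    or record.recurrent
                )
                if interesting:
                    assert record.evidence, record
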
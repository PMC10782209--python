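"""Decision engine: the eleven rule rows, aggregation precedence,
totality over the attribute lattice, and letter rendering."""

import itertools

import pytest

from skinmdt.decision import (
    DecisionInputError,
    LetterTemplateError,
    aggregate_recommendation,
    classify_lesion_outcome,
    generate_letter,
)
from skinmdt.labels import (
    OUTCOME_TO_RECOMMENDATION,
    OutcomeCode,
    Recommendation,
)
from skinmdt.records import (
    Diagnosis,
    ExcisionType,
    LesionRecord,
    MarginStatus,
)

from oracles import oracle_patient_recommendation


def bcc(**kwargs):
    defaults = dict(
        diagnosis_class=Diagnosis.BCC,
        bcc_subtype="nodular",
        excision_type=ExcisionType.EXCISION,
    )
    defaults.update(kwargs)
    return LesionRecord(**defaults)


class TestRuleRows:
    """One check per row of the guideline rule table."""

    @pytest.mark.parametrize(
        "record,expected_code,expected_rec",
        [
            (  # completely excised single BCC
                bcc(peripheral_margin="clear", deep_margin="clear",
                    peripheral_margin_mm=1.0, deep_margin_mm=2.0),
                OutcomeCode.COMPLETE_SINGLE_BCC,
                Recommendation.NO_FOLLOW_UP,
            ),
            (  # incomplete: peripheral
                bcc(peripheral_margin="involved", peripheral_margin_mm=0.0),
                OutcomeCode.INCOMPLETE_BCC,
                Recommendation.RE_EXCISION,
            ),
            (  # incomplete: deep
                bcc(deep_margin="involved"),
                OutcomeCode.INCOMPLETE_BCC,
                Recommendation.RE_EXCISION,
            ),
            (  # incomplete: both
                bcc(peripheral_margin="involved", deep_margin="involved"),
                OutcomeCode.INCOMPLETE_BCC,
                Recommendation.RE_EXCISION,
            ),
            (  # recurrent BCC
                bcc(peripheral_margin="clear", deep_margin="clear", recurrent=True),
                OutcomeCode.RECURRENT_BCC,
                Recommendation.FOLLOW_UP_5Y,
            ),
            (  # supplemental, peripheral positive
                bcc(peripheral_margin="involved", supplemental=True),
                OutcomeCode.SUPPLEMENTAL_PERIPHERAL_POSITIVE,
                Recommendation.RE_EXCISION,
            ),
            (  # supplemental, peripheral negative
                bcc(peripheral_margin="clear", deep_margin="clear",
                    supplemental=True),
                OutcomeCode.SUPPLEMENTAL_PERIPHERAL_NEGATIVE,
                Recommendation.NO_FOLLOW_UP,
            ),
            (  # supplemental, deep positive
                bcc(peripheral_margin="clear", deep_margin="involved",
                    supplemental=True),
                OutcomeCode.SUPPLEMENTAL_DEEP_POSITIVE,
                Recommendation.RE_EXCISION,
            ),
            (  # supplemental, deep negative (only deep reported)
                bcc(deep_margin="clear", supplemental=True),
                OutcomeCode.SUPPLEMENTAL_DEEP_NEGATIVE,
                Recommendation.NO_FOLLOW_UP,
            ),
            (  # diagnostic biopsy of a BCC
                bcc(excision_type="punch_biopsy"),
                OutcomeCode.DIAGNOSTIC_BIOPSY_BCC,
                Recommendation.FURTHER_SURGERY,
            ),
            (  # benign, any margin outcome
                LesionRecord(diagnosis_class="benign",
                             peripheral_margin="involved",
                             deep_margin="clear"),
                OutcomeCode.BENIGN_OR_NON_SPECIFIC,
                Recommendation.NO_FOLLOW_UP,
            ),
            (  # other malignancy / in situ / intermediate
                LesionRecord(diagnosis_class="other_cancer"),
                OutcomeCode.OTHER_CANCER_IN_SITU_INTERMEDIATE,
                Recommendation.REVIEW_REQUIRED,
            ),
            (
                LesionRecord(diagnosis_class="other_in_situ"),
                OutcomeCode.OTHER_CANCER_IN_SITU_INTERMEDIATE,
                Recommendation.REVIEW_REQUIRED,
            ),
            (
                LesionRecord(diagnosis_class="other_intermediate"),
                OutcomeCode.OTHER_CANCER_IN_SITU_INTERMEDIATE,
                Recommendation.REVIEW_REQUIRED,
            ),
        ],
    )
    def test_row_maps_to_expected_outcome(self, record, expected_code, expected_rec):
        outcome = classify_lesion_outcome(record)
        assert outcome.code is expected_code
        assert outcome.recommendation is expected_rec

    def test_biopsy_rule_outranks_margins_and_recurrence(self):
        record = bcc(
            excision_type="curettage", peripheral_margin="involved", recurrent=True
        )
        assert classify_lesion_outcome(record).code is OutcomeCode.DIAGNOSTIC_BIOPSY_BCC

    def test_recurrent_rule_outranks_incomplete(self):
        record = bcc(peripheral_margin="involved", recurrent=True)
        assert classify_lesion_outcome(record).code is OutcomeCode.RECURRENT_BCC

    def test_supplemental_override_argument(self):
        record = bcc(peripheral_margin="clear", deep_margin="clear")
        assert (
            classify_lesion_outcome(record, is_supplemental=True).code
            is OutcomeCode.SUPPLEMENTAL_PERIPHERAL_NEGATIVE
        )


class TestTotality:
    def test_every_lattice_point_maps_to_exactly_one_outcome(self):
        """Exhaustive sweep over the discretised single-lesion attribute
        space: classification is total and every outcome maps to one of
        the five recommendations."""
        seen = set()
        for dx, ex, p, d, rec, supp in itertools.product(
            Diagnosis, ExcisionType, MarginStatus, MarginStatus,
            (False, True), (False, True),
        ):
            record = LesionRecord(
                diagnosis_class=dx,
                bcc_subtype="nodular" if dx is Diagnosis.BCC else None,
                excision_type=ex,
                peripheral_margin=p,
                deep_margin=d,
                recurrent=rec,
                supplemental=supp,
            )
            outcome = classify_lesion_outcome(record)
            seen.add(outcome.code)
            assert outcome.recommendation in Recommendation
        # every row except the patient-level multiple-BCC row is reachable
        assert seen == set(OutcomeCode) - {OutcomeCode.MULTIPLE_BCCS}

    def test_hard_class_contract(self):
        """Decisions carry classes only -- no probability or score field."""
        decision = aggregate_recommendation([bcc(peripheral_margin="clear",
                                                 deep_margin="clear")])
        payload = vars(decision)
        assert set(payload) == {
            "patient_id", "lesion_outcomes", "recommendation", "rationale"
        }
        assert isinstance(decision.recommendation, Recommendation)


class TestAggregation:
    def test_two_complete_bccs_trigger_surveillance(self):
        records = [
            bcc(specimen_label="A", peripheral_margin="clear", deep_margin="clear"),
            bcc(specimen_label="B", peripheral_margin="clear", deep_margin="clear"),
        ]
        decision = aggregate_recommendation(records)
        assert decision.recommendation is Recommendation.FOLLOW_UP_5Y
        assert "rule_multiple_bccs" in decision.rationale

    def test_single_bcc_plus_benign_is_discharged(self):
        records = [
            bcc(specimen_label="A", peripheral_margin="clear", deep_margin="clear"),
            LesionRecord(specimen_label="B", diagnosis_class="benign"),
        ]
        decision = aggregate_recommendation(records)
        assert decision.recommendation is Recommendation.NO_FOLLOW_UP

    def test_recurrent_plus_incomplete_escalates_to_re_excision(self):
        records = [
            bcc(specimen_label="A", peripheral_margin="clear", deep_margin="clear",
                recurrent=True),
            bcc(specimen_label="B", peripheral_margin="involved"),
        ]
        decision = aggregate_recommendation(records)
        assert decision.recommendation is Recommendation.RE_EXCISION

    def test_empty_record_list_rejected(self):
        with pytest.raises(DecisionInputError):
            aggregate_recommendation([])

    def test_custom_precedence_changes_tie_resolution(self):
        records = [
            bcc(specimen_label="A", recurrent=True, peripheral_margin="clear",
                deep_margin="clear"),
            bcc(specimen_label="B", peripheral_margin="involved"),
        ]
        flipped = (
            Recommendation.REVIEW_REQUIRED,
            Recommendation.FURTHER_SURGERY,
            Recommendation.FOLLOW_UP_5Y,  # surveillance now outranks re-excision
            Recommendation.RE_EXCISION,
            Recommendation.NO_FOLLOW_UP,
        )
        decision = aggregate_recommendation(records, precedence=flipped)
        assert decision.recommendation is Recommendation.FOLLOW_UP_5Y

    def test_invalid_precedence_rejected(self):
        with pytest.raises(DecisionInputError):
            aggregate_recommendation(
                [bcc()], precedence=[Recommendation.NO_FOLLOW_UP]
            )

    def test_agrees_with_bruteforce_oracle_on_random_pairs(self):
        """Spot check against the independent rule-table oracle (the
        exhaustive sweep lives in the acceptance suite)."""
        import numpy as np

        rng = np.random.default_rng(5)
        dxs = list(Diagnosis)
        exs = list(ExcisionType)
        statuses = [MarginStatus.CLEAR, MarginStatus.INVOLVED,
                    MarginStatus.NOT_STATED]
        for _ in range(300):
            n = int(rng.integers(1, 4))
            records = []
            for i in range(n):
                dx = dxs[int(rng.integers(len(dxs)))]
                records.append(
                    LesionRecord(
                        specimen_label=str(i + 1),
                        diagnosis_class=dx,
                        bcc_subtype="nodular" if dx is Diagnosis.BCC else None,
                        excision_type=exs[int(rng.integers(len(exs)))],
                        peripheral_margin=statuses[int(rng.integers(3))],
                        deep_margin=statuses[int(rng.integers(3))],
                        recurrent=bool(rng.integers(2)),
                        supplemental=bool(rng.integers(2)),
                    )
                )
            decision = aggregate_recommendation(records)
            assert decision.recommendation.value == oracle_patient_recommendation(
                records
            )


class TestFixtureFidelity:
    def test_structured_cases_classified_with_full_agreement(self, structured_cases):
        assert len(structured_cases) >= 100
        for case in structured_cases:
            for lesion, expected in zip(case.lesions, case.expected_outcomes):
                assert classify_lesion_outcome(lesion).code is expected, case.case_id
            decision = aggregate_recommendation(case.lesions, patient_id=case.case_id)
            assert decision.recommendation is case.expected_recommendation

    def test_fixture_covers_all_rule_rows(self, structured_cases):
        covered = set()
        for case in structured_cases:
            covered.update(case.expected_outcomes)
            if sum(
                1 for l in case.lesions if l.diagnosis_class is Diagnosis.BCC
            ) >= 2:
                covered.add(OutcomeCode.MULTIPLE_BCCS)
        assert covered == set(OutcomeCode)


class TestLetters:
    def _decision(self):
        return aggregate_recommendation(
            [bcc(peripheral_margin="involved")], patient_id="P0001"
        )

    def test_letter_contains_recommendation_and_enclosures(self):
        letter = generate_letter(
            self._decision(),
            {"patient_name": "A. Patient", "clinic_name": "Dermatology"},
            records=[bcc(peripheral_margin="involved")],
        )
        assert Recommendation.RE_EXCISION.value in letter
        assert "BAD patient information sheet" in letter
        assert "Melanoma UK patient information sheet" in letter
        assert "$" not in letter  # no unresolved placeholders

    def test_missing_display_field_is_reported(self):
        with pytest.raises(LetterTemplateError, match="clinic_name"):
            generate_letter(self._decision(), {"patient_name": "A. Patient"})

    def test_rendering_is_deterministic(self):
        fields = {"patient_name": "A. Patient", "clinic_name": "Dermatology"}
        assert generate_letter(self._decision(), fields) == generate_letter(
            self._decision(), fields
        )

    def test_unknown_template_rejected(self):
        with pytest.raises(LetterTemplateError):
            generate_letter(self._decision(), {}, template_id="nonexistent")
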
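"""Extract structured lesion records from one two-specimen report and show
the verbatim evidence spans behind each value.

Specimen A is a completely excised nodular BCC (margins in mm); specimen B
is a benign lesion sampled by punch biopsy. Each extracted field is backed
by the exact characters that produced it, which is what makes the rule
system auditable.
"""

from skinmdt import RawReport, assemble_records

report = RawReport(
    report_id="R1",
    patient_id="P1",
    subheadings={
        "clinical_details": "Two lesions for excision, left cheek and nose.",
        "macroscopic": "A. Ellipse of skin 15 x 8 mm. B. Punch biopsy of skin 4 mm.",
        "microscopic": (
            "A. Sections show a nodular basal cell carcinoma. The lesion is "
            "completely excised; nearest peripheral margin 0.5 mm, deep margin "
            "1 mm. B. Sections show a seborrhoeic keratosis. No evidence of "
            "basal cell carcinoma."
        ),
        "conclusion": (
            "A. Nodular basal cell carcinoma, completely excised. "
            "B. Seborrhoeic keratosis."
        ),
    },
)

for record in assemble_records(report):
    print(
        f"specimen {record.specimen_label}: {record.diagnosis_class.value}"
        + (f"/{record.bcc_subtype}" if record.bcc_subtype else "")
        + f", {record.excision_type.value}, peripheral={record.peripheral_margin.value}"
        f" ({record.peripheral_margin_mm} mm), deep={record.deep_margin.value}"
        f" ({record.deep_margin_mm} mm)"
    )
    for span in record.evidence:
        print(f"    [{span.rule_id}] {span.section}[{span.start}:{span.end}] "
              f"= {span.matched_text!r}")
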
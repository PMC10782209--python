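Dear $patient_name,

You recently had a skin lesion removed or sampled, and the tissue has now
been examined by a pathologist. This letter explains what was found and what
we recommend next.

What was found:
$diagnosis_lines

Our recommendation:
$recommendation

If you have any questions about this letter, or if you notice any change in
the treated area or any new skin lesion, please contact the department using
the details above. Please bring this letter to any future appointment.

Enclosed with this letter you will find a BAD patient information sheet
explaining the diagnosis, and a Melanoma UK patient information sheet on
self-examination of your skin.

Yours sincerely,

$clinic_name
(Reference: $patient_id)
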
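"""Sample-size planning for a diagnostic sensitivity study (Buderer).

Two entry points: derive the case count from the expected sensitivity,
confidence and precision; or fix the case count and derive how many
controls the assumed prevalence implies. At 5% prevalence every case drags
in 19 controls, which is why low-prevalence validation studies are large.
"""

from skinmdt import SampleSizeInputs, controls_for_cases, sensitivity_sample_size

plan = sensitivity_sample_size(
    SampleSizeInputs(
        expected_sensitivity=0.95,
        confidence_level=0.95,
        precision_delta=0.10,
        prevalence=0.05,
    )
)
print(
    f"derived from precision: {plan.n_cases} cases, {plan.n_controls} controls, "
    f"{plan.n_total} total"
)

fixed = controls_for_cases(40, 0.05)
print(
    f"fixed 40 cases at prevalence 0.05: {fixed.n_controls} controls, "
    f"{fixed.n_total} total"
)
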
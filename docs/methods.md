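# Methods

## The decision problem

After primary surgery for a suspected basal cell carcinoma (BCC), UK
guideline-based management is a function of a handful of histological
facts: what the lesion was (BCC, benign, or another malignancy), how it
was sampled (definitive excision vs diagnostic biopsy), whether the
excision margins are clear, and whether the lesion is a recurrence. The
package models this as a two-stage pipeline — information extraction from
the report text, then a deterministic rule table — and evaluates the
composite as a five-class classifier against an expert reference.

## Extraction model

Reports are assumed to be organised under four canonical subheadings
(clinical details, macroscopic, microscopic, conclusion), as produced by
UK laboratory information systems. The extractor is deliberately a small,
transparent rule system rather than a learned model:

* **Segmentation.** Specimen markers ("A.", "B)", "Specimen C:", "1)")
  split the macroscopic/microscopic/conclusion sections; the slices
  partition each section, the first slice absorbing any preamble. Reports
  without markers form a single segment labelled "1". Clinical details are
  shared context and are never split.
* **Tagging.** Five editable CSV gazetteers (diagnosis, excision type,
  margin phrases, recurrence cues, negation cues) are matched
  case-insensitively after Unicode NFKC normalisation, longest match wins,
  overlapping shorter matches suppressed. Composite entries ("infiltrative
  basal cell carcinoma") carry the BCC subtype.
* **Negation.** NegEx-style: a cue ("no evidence of", "no residual",
  "negative for", "not seen", "free of") negates a concept in the same
  sentence when at most 6 tokens precede it and no contrastive conjunction
  ("but", "however") intervenes. The window and terminator set are
  conventional choices; report language is formulaic enough that scope
  ambiguity is rare.
* **Section priority.** Diagnosis: conclusion > microscopic > macroscopic,
  never clinical details (a clinical impression is not a histological
  diagnosis; a clinical-details-only report therefore extracts as
  non-specific). Excision type: macroscopic first, where the specimen is
  described. Margins: microscopic and conclusion.
* **Margins.** Numeric patterns ("nearest peripheral margin 0.5 mm",
  "deep margin 0 mm") outrank margin-specific lexical patterns ("extends
  to the deep margin"), which outrank generic phrases ("completely /
  incompletely excised"). A distance of 0 mm means involved, > 0 mm
  clear — the Royal College of Pathologists convention — and the
  (status, distance) consistency law is enforced on every record.
  Malformed distances ("0..5 mm") are skipped with a warning rather than
  guessed; an unmentioned margin stays `not_stated`, never imputed.
* **Evidence.** Every non-default field value carries verbatim spans
  (section, 0-based end-exclusive offsets, matched text, rule id), so any
  output can be audited back to its characters.

This is intentionally a minimal rule set sized to what the decision engine
needs, not a general pathology IE system; the full clinical-grade
ancestors of such pipelines run to dozens of gazetteers and hundreds of
rule files.

## Decision engine

Per lesion, eleven rule rows are evaluated in a fixed, documented order
(first match wins): other malignancy / in-situ / intermediate → free-text
review; benign or non-specific (any margin outcome) → no follow-up; BCC on
a diagnostic sampling biopsy → further excisional, destructive or
non-surgical treatment; supplemental (re-excision/cavity) specimens →
outcome by margin polarity; recurrent BCC → 5-year surveillance;
incomplete excision (either margin) → offer of re-excision; completely
excised BCC → no follow-up. The last rule is total for BCC excisions, so
classification is total over the attribute lattice (verified by exhaustive
enumeration). Two or more BCC lesions in one decision episode additionally
fire the multiple-BCC surveillance rule; the episode is one report (or one
patient's batch), since no guideline time window exists for "multiple".

Placing the recurrence rule before the incomplete-excision rule follows
the documented row order; a lesion that is both recurrent and incomplete
therefore resolves to surveillance at the lesion level, while at the
patient level the precedence below still escalates mixed cases to
re-excision.

Patient aggregation takes the highest-precedence recommendation among
fired outcomes. The default precedence — review > further surgery >
re-excision > surveillance > no follow-up — ranks by escalating need for
human intervention and is configurable, because guidelines do not define
one for conflicting rows.

Supplemental specimens (re-excisions of a previously treated site,
recognised by "re-excision" / "further excision" / "cavity" in the
specimen description) get their own margin-polarity rows. When both
margins are reported, an involved peripheral margin takes priority over
deep in naming the outcome row; a clear-margins specimen resolves to the
peripheral-negative row unless only the deep margin was reported. A BCC
with unknown excision type is treated as an excision, which is
conservative against over-referral to further surgery.

Outputs are hard classes only — no probabilities or scores exist anywhere
in the decision path, so threshold/ROC analysis is out of scope by
construction.

Letters are rendered from a `string.Template` with the recommendation
label verbatim, one diagnosis line per lesion, and the two standard
enclosures (BAD information sheet; Melanoma UK self-examination sheet);
rendering fails loudly on any missing display field.

## Synthetic corpus

No clinical corpus ships with the package; the generator emulates one.

* **Class mixture.** Default weights are the reference-arm marginals of
  the published 1045-lesion validation table (146 / 31 / 770 / 45 / 53),
  preserving the class imbalance that motivates micro-averaging. Each
  patient draws a target class, then a case consistent with it: e.g. a
  5-year-surveillance patient is either a recurrent BCC or carries two or
  more BCCs.
* **Lesion counts** default to 1–4 per patient (0.80/0.14/0.04/0.02); no
  published distribution exists, so this was fixed once at a clinically
  plausible shape.
* **Rendering.** Every gold attribute is realised by one of at least three
  phrasings per attribute; multi-specimen reports are labelled "A.", "B.",
  …. Margin distances are drawn in 0.3–5.0 mm for clear margins and are
  exactly 0 mm for numerically involved ones.
* **Noise** (probability per sentence) applies label-preserving operators
  only: hedging prefixes, British/American respellings whose variants the
  gazetteers know, mild synonym swaps, and benign distractor sentences
  (including negated-malignancy phrasings). Noise therefore perturbs
  lexical difficulty but never deletes or contradicts a gold attribute —
  which is why even noisy corpora extract perfectly and why passing these
  tests bounds only template-shaped language, not real-world reporting
  variance (OCR errors, free-form prose, missing subheadings are out of
  scope).
* **Determinism.** Each patient uses an RNG stream seeded by
  `(master_seed, patient_index)`, so a corpus is a pure function of its
  config and partial regeneration is stable; identical configs produce
  byte-identical corpora.

Gold labels are assigned at construction time from the rule table, and a
round-trip property (engine over gold lesions reproduces the expected
recommendation; extraction over noise-0 text reproduces every gold field)
is enforced in tests.

## Evaluation

The confusion matrix stores prediction rows × reference columns, axes in
the lexicographic order of the canonical label strings. One-vs-rest
counts per class: TP = diagonal cell, FN = rest of reference column,
FP = rest of prediction row, TN = remainder. Micro accuracy pools counts
(trace/total); macro values are unweighted means over classes. A ratio
with a zero denominator is NaN, excluded from macro means with the
exclusion count reported — never coerced to 0 or 1 — so sparse classes do
not bias aggregates. Published figures for this problem report the pooled
trace/total number as the overall accuracy and unweighted per-class means
for the rest; both conventions are implemented under their standard names
and both are always reported. Stored values are full precision; rounding
(2 dp, half-up) happens only in formatted reports.

Cohen's kappa is (po − pe)/(1 − pe) with pe either estimated from the two
raters' marginals (standard) or caller-fixed, since published analyses
sometimes assume a fixed chance-agreement probability.

Sample-size planning uses the Buderer sensitivity formula with z the
two-sided normal quantile ("significance level 0.95" is read as 95%
confidence, z ≈ 1.96); n_cases is floored at 1, and a control-from-cases
entry point derives `n_total = ⌈n_cases/prevalence⌉` when the case count
is fixed externally. A cap of 1e9 participants guards degenerate
prevalences.

## Numerical and testing choices

* Exhaustive decision checks discretise each attribute to its decision-
  relevant values (3 diagnosis classes, 2 excision types, 2 margin states
  per margin, recurrent, supplemental → 96 lesion types); every multiset
  of ≤ 3 lesions (156 848 patients) is compared against an independently
  written brute-force rule-table oracle.
* One-vs-rest metrics are cross-checked against a pair-expansion oracle on
  1000 random 5-class matrices to 1e-12, and kappa against scikit-learn.
* Synthetic evaluations use 120–300 patients in tests and 200 for the
  end-to-end round trip — sizes chosen to exercise every template branch
  many times over while keeping the suite quick.
* The packaged structured-case fixture (103 cases, 117 lesions, all eleven
  rule rows) was hand-labelled from the rule table independently of the
  engine; `scripts/acceptance.py` recomputes the engine's agreement with
  it at run time.

## Known limitations

* The extractor's vocabulary is sized to the synthetic templates plus
  common report language; real reports will need gazetteer growth (the
  CSVs are editable without code changes).
* Negation handling is pre-span only; post-posed negation ("carcinoma is
  not seen") relies on the "not seen" cue landing pre-span in rephrasings
  and is not generally handled.
* Multi-specimen reports with unlabelled sections attribute that section
  to the first specimen; shared clinical details cannot be attributed per
  lesion, so in multi-specimen reports recurrence and supplemental cues
  must be specimen-scoped.
* Prior-history context (e.g. previous melanoma) is outside the rule
  table, as are probability-scaled outputs and any terminology-server
  integration; the cohort filter uses simulated SNOMED-style codes.
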
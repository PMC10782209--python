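"""Multiclass evaluation: confusion matrix, one-vs-rest metrics,
micro/macro aggregation, Cohen's kappa and sample-size planning.

Conventions
-----------
* Confusion-matrix rows are predictions, columns are the reference
  (expert-clinician) classes; axes follow the lexicographic order of the
  canonical recommendation labels.
* Each class is evaluated one-vs-rest: its diagonal cell is TP, the rest
  of its reference column FN, the rest of its prediction row FP, and
  everything else TN.
* Micro accuracy pools counts (trace/total).  Macro values are unweighted
  means over classes; a per-class ratio with a zero denominator is NaN and
  is excluded from the macro mean (the exclusion count is reported).
* Stored metric values are full precision; rounding (2 dp, half-up) is
  applied only when formatting reports.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .labels import CLASS_LABELS


class EvaluationError(ValueError):
    """Invalid evaluation input (labels, totals, shapes)."""


class PlanningError(ValueError):
    """Sample-size planning produced an unusable design."""


# ---------------------------------------------------------------------------
# Confusion matrix
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """K x K counts with rows = prediction, columns = reference."""

    class_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise EvaluationError(
                f"counts shape {self.counts.shape} != ({k}, {k})"
            )
        if (self.counts < 0).any():
            raise EvaluationError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def reference_totals(self) -> np.ndarray:
        """Column sums (reference-class marginals)."""
        return self.counts.sum(axis=0)

    def prediction_totals(self) -> np.ndarray:
        """Row sums (prediction-class marginals)."""
        return self.counts.sum(axis=1)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["prediction\\reference", *self.class_labels])
        for label, row in zip(self.class_labels, self.counts):
            writer.writerow([label, *row.tolist()])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "ConfusionMatrix":
        rows = list(csv.reader(io.StringIO(text)))
        labels = rows[0][1:]
        counts = []
        for row in rows[1 : 1 + len(labels)]:
            if row[0] != labels[len(counts)]:
                raise EvaluationError(
                    f"row label {row[0]!r} does not match column order"
                )
            counts.append([int(v) for v in row[1:]])
        return cls(class_labels=labels, counts=np.array(counts))


def build_confusion_matrix(
    pairs: Iterable[tuple[str, str]], class_labels: Sequence[str] = CLASS_LABELS
) -> ConfusionMatrix:
    """Count (reference, prediction) pairs into a confusion matrix."""
    labels = list(class_labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for reference, prediction in pairs:
        if reference not in index:
            raise EvaluationError(f"unknown reference label: {reference!r}")
        if prediction not in index:
            raise EvaluationError(f"unknown predicted label: {prediction!r}")
        counts[index[prediction], index[reference]] += 1
    return ConfusionMatrix(class_labels=labels, counts=counts)


def pairs_from_matrix(matrix: ConfusionMatrix) -> list[tuple[str, str]]:
    """Expand a confusion matrix back into (reference, prediction) pairs."""
    pairs = []
    for i, pred in enumerate(matrix.class_labels):
        for j, ref in enumerate(matrix.class_labels):
            pairs.extend([(ref, pred)] * int(matrix.counts[i, j]))
    return pairs


# ---------------------------------------------------------------------------
# One-vs-rest metrics
# ---------------------------------------------------------------------------


@dataclass
class OvRMetrics:
    """Binary (one-vs-rest) counts and ratios for a single class.

    Undefined ratios (zero denominator) are NaN, never coerced to 0 or 1.
    """

    class_label: str
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)
    accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        def ratio(num, den):
            return num / den if den > 0 else math.nan

        total = self.tp + self.fp + self.fn + self.tn
        self.sensitivity = ratio(self.tp, self.tp + self.fn)
        self.specificity = ratio(self.tn, self.tn + self.fp)
        self.ppv = ratio(self.tp, self.tp + self.fp)
        self.npv = ratio(self.tn, self.tn + self.fn)
        self.accuracy = ratio(self.tp + self.tn, total)


def one_vs_rest_metrics(matrix: ConfusionMatrix) -> list[OvRMetrics]:
    """Per-class one-vs-rest counts and ratios."""
    total = matrix.total
    if total == 0:
        raise EvaluationError("cannot compute metrics on an empty matrix")
    ref_totals = matrix.reference_totals()
    pred_totals = matrix.prediction_totals()
    out = []
    for i, label in enumerate(matrix.class_labels):
        tp = int(matrix.counts[i, i])
        fn = int(ref_totals[i]) - tp
        fp = int(pred_totals[i]) - tp
        tn = total - tp - fn - fp
        out.append(OvRMetrics(class_label=label, tp=tp, fp=fp, fn=fn, tn=tn))
    return out


@dataclass
class AggregateMetrics:
    micro_accuracy: float
    macro_sensitivity: float
    macro_specificity: float
    macro_ppv: float
    macro_npv: float
    per_class: list[OvRMetrics]
    n_excluded: dict[str, int] = field(default_factory=dict)


def aggregate_metrics(
    per_class: list[OvRMetrics], matrix: ConfusionMatrix
) -> AggregateMetrics:
    """Micro accuracy (trace/total) plus unweighted macro means."""
    if not per_class:
        raise EvaluationError("per_class metrics must be nonempty")
    if [m.class_label for m in per_class] != list(matrix.class_labels):
        raise EvaluationError("per-class metrics do not match matrix classes")
    if sum(m.tp for m in per_class) != matrix.trace:
        raise EvaluationError("per-class TP counts inconsistent with matrix")

    def macro(name):
        values = [getattr(m, name) for m in per_class]
        defined = [v for v in values if not math.isnan(v)]
        excluded[name] = len(values) - len(defined)
        return sum(defined) / len(defined) if defined else math.nan

    excluded: dict[str, int] = {}
    return AggregateMetrics(
        micro_accuracy=matrix.trace / matrix.total,
        macro_sensitivity=macro("sensitivity"),
        macro_specificity=macro("specificity"),
        macro_ppv=macro("ppv"),
        macro_npv=macro("npv"),
        per_class=per_class,
        n_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------


def cohens_kappa(
    pairs: Sequence[tuple[str, str]],
    chance_model: str = "marginal",
    pe: Optional[float] = None,
) -> float:
    """Chance-corrected agreement between two raters: (po - pe)/(1 - pe).

    ``chance_model="marginal"`` estimates expected agreement from the two
    raters' marginal distributions (the standard Cohen estimator);
    ``chance_model="fixed"`` uses the caller-supplied ``pe``.
    """
    if not pairs:
        raise EvaluationError("kappa requires at least one pair")
    n = len(pairs)
    po = sum(1 for a, b in pairs if a == b) / n
    if chance_model == "marginal":
        categories = sorted({a for a, _ in pairs} | {b for _, b in pairs})
        p1 = {c: sum(1 for a, _ in pairs if a == c) / n for c in categories}
        p2 = {c: sum(1 for _, b in pairs if b == c) / n for c in categories}
        pe_value = sum(p1[c] * p2[c] for c in categories)
    elif chance_model == "fixed":
        if pe is None or not 0.0 <= pe < 1.0:
            raise EvaluationError("fixed chance model requires pe in [0, 1)")
        pe_value = pe
    else:
        raise EvaluationError(f"unknown chance_model {chance_model!r}")
    if pe_value >= 1.0:
        raise EvaluationError("expected agreement pe = 1 leaves kappa undefined")
    return (po - pe_value) / (1.0 - pe_value)


# ---------------------------------------------------------------------------
# Sample-size planning (Buderer)
# ---------------------------------------------------------------------------

_N_TOTAL_CAP = 10**9


@dataclass
class SampleSizeInputs:
    expected_sensitivity: float
    confidence_level: float
    precision_delta: float
    prevalence: float

    def __post_init__(self) -> None:
        for name in (
            "expected_sensitivity",
            "confidence_level",
            "precision_delta",
            "prevalence",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise PlanningError(f"{name} must lie strictly in (0, 1); got {v}")


@dataclass
class SampleSizePlan:
    n_cases: int
    n_controls: int
    n_total: int


def _controls(n_cases: int, prevalence: float) -> SampleSizePlan:
    n_total = math.ceil(n_cases / prevalence)
    if n_total > _N_TOTAL_CAP:
        raise PlanningError(
            f"prevalence {prevalence} needs {n_total} participants "
            f"(cap {_N_TOTAL_CAP})"
        )
    return SampleSizePlan(
        n_cases=n_cases, n_controls=n_total - n_cases, n_total=n_total
    )


def sensitivity_sample_size(inputs: SampleSizeInputs) -> SampleSizePlan:
    """Buderer sample size for estimating a sensitivity.

    ``n_cases = ceil(z^2 * SN(1-SN) / delta^2)`` with ``z`` the two-sided
    normal quantile at the confidence level; controls follow from the
    prevalence via ``n_total = ceil(n_cases / prevalence)``.
    """
    z = norm.ppf(1.0 - (1.0 - inputs.confidence_level) / 2.0)
    sn = inputs.expected_sensitivity
    n_cases = math.ceil(z * z * sn * (1.0 - sn) / inputs.precision_delta**2)
    n_cases = max(n_cases, 1)
    return _controls(n_cases, inputs.prevalence)


def controls_for_cases(n_cases: int, prevalence: float) -> SampleSizePlan:
    """Alternate entry point: fix the case count, derive controls."""
    if n_cases < 1:
        raise PlanningError("n_cases must be >= 1")
    if not 0.0 < prevalence < 1.0:
        raise PlanningError("prevalence must lie strictly in (0, 1)")
    return _controls(n_cases, prevalence)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def round2(value: float) -> float:
    """Half-up rounding to 2 decimal places, for presentation only."""
    if math.isnan(value):
        return math.nan
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))


def _metrics_dict(agg: AggregateMetrics) -> dict:
    def clean(v):
        return None if (isinstance(v, float) and math.isnan(v)) else v

    return {
        "micro_accuracy": clean(agg.micro_accuracy),
        "macro_sensitivity": clean(agg.macro_sensitivity),
        "macro_specificity": clean(agg.macro_specificity),
        "macro_ppv": clean(agg.macro_ppv),
        "macro_npv": clean(agg.macro_npv),
        "n_excluded": agg.n_excluded,
        "per_class": [
            {
                "class_label": m.class_label,
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "tn": m.tn,
                "sensitivity": clean(m.sensitivity),
                "specificity": clean(m.specificity),
                "ppv": clean(m.ppv),
                "npv": clean(m.npv),
                "accuracy": clean(m.accuracy),
            }
            for m in agg.per_class
        ],
    }


def format_metrics_table(agg: AggregateMetrics) -> str:
    """Human-readable per-class table at the printed precision (2 dp)."""
    def fmt(v):
        return "--" if math.isnan(v) else f"{round2(v):.2f}"

    lines = [
        f"{'class':<60} {'sens':>6} {'spec':>6} {'ppv':>6} {'npv':>6} {'acc':>6}"
    ]
    for m in agg.per_class:
        label = (m.class_label[:57] + "...") if len(m.class_label) > 60 else m.class_label
        lines.append(
            f"{label:<60} {fmt(m.sensitivity):>6} {fmt(m.specificity):>6} "
            f"{fmt(m.ppv):>6} {fmt(m.npv):>6} {fmt(m.accuracy):>6}"
        )
    lines.append("")
    lines.append(f"micro accuracy     {fmt(agg.micro_accuracy)}")
    lines.append(f"macro sensitivity  {fmt(agg.macro_sensitivity)}")
    lines.append(f"macro specificity  {fmt(agg.macro_specificity)}")
    lines.append(f"macro ppv          {fmt(agg.macro_ppv)}")
    lines.append(f"macro npv          {fmt(agg.macro_npv)}")
    return "\n".join(lines) + "\n"


@dataclass
class EvaluationReport:
    matrix: ConfusionMatrix
    metrics: AggregateMetrics
    table: str


def evaluate_run(
    gold_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_labels: Sequence[str] = CLASS_LABELS,
    out_dir=None,
) -> EvaluationReport:
    """Confusion matrix -> one-vs-rest -> aggregates, optionally serialised.

    Writes ``confusion_matrix.csv``, ``metrics.json`` (full precision) and
    ``metrics.txt`` (2 dp) when ``out_dir`` is given.
    """
    if len(gold_labels) != len(predicted_labels):
        raise EvaluationError(
            f"label lists differ in length: {len(gold_labels)} vs "
            f"{len(predicted_labels)}"
        )
    matrix = build_confusion_matrix(
        list(zip(gold_labels, predicted_labels)), class_labels
    )
    per_class = one_vs_rest_metrics(matrix)
    agg = aggregate_metrics(per_class, matrix)
    table = format_metrics_table(agg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "confusion_matrix.csv").write_text(matrix.to_csv(), encoding="utf-8")
        (out / "metrics.json").write_text(
            json.dumps(_metrics_dict(agg), indent=2) + "\n", encoding="utf-8"
        )
        (out / "metrics.txt").write_text(table, encoding="utf-8")
    return EvaluationReport(matrix=matrix, metrics=agg, table=table)


# ---------------------------------------------------------------------------
# Packaged validation-table fixture
# ---------------------------------------------------------------------------


def load_published_matrix() -> ConfusionMatrix:
    """The packaged 5x5 validation confusion matrix (prediction rows vs
    expert-reference columns, 1045 lesions)."""
    text = (
        resources.files("skinmdt")
        .joinpath("data", "table2_confusion_matrix.csv")
        .read_text("utf-8")
    )
    return ConfusionMatrix.from_csv(text)
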
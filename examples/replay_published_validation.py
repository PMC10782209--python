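"""Replay the packaged 5x5 validation confusion matrix (1045 lesions,
prediction rows vs expert-reference columns) through the evaluation layer.

Prints per-class one-vs-rest sensitivity/specificity plus the pooled
(micro) accuracy and unweighted (macro) means. The micro accuracy is the
fraction of lesions where the engine and the expert clinicians issued the
same recommendation; per-class sensitivity is the fraction of each
expert-assigned class the engine recovered.
"""

from skinmdt import aggregate_metrics, load_published_matrix, one_vs_rest_metrics
from skinmdt.evaluation import format_metrics_table

matrix = load_published_matrix()
per_class = one_vs_rest_metrics(matrix)
aggregates = aggregate_metrics(per_class, matrix)

print(f"lesions evaluated: {matrix.total}")
print(format_metrics_table(aggregates))
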
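"""Annotation sampling and confusion-matrix validation.

A random 10% of classified posts is exported for manual annotation; once
re-imported, the annotations are compared with model output. Here the
"annotations" are the generator's ground-truth labels, and the model is
an oracle classifier with planted per-class error rates — so the metrics
have known expected values (sensitivity = 1 - error rate per class).
"""

from vaxsent import CorpusConfig, generate_corpus, sample_for_annotation
from vaxsent.ensemble import OracleClassifier
from vaxsent.validation import class_metrics, confusion_matrix, metrics_report

records, labels = generate_corpus(CorpusConfig(n_posts=5000, seed=11))
truth = {t.post_id: int(t.label) for t in labels}

sample = sample_for_annotation(records, fraction=0.10, seed=11)
print(f"annotation sample: {len(sample)} of {len(records)} posts")

rates = {-1: 0.10, 0: 0.20, 1: 0.05}  # planted per-class error rates
clf = OracleClassifier(
    {r.text: truth[r.id] for r in records}, error_rates=rates, seed=11
)
pairs = [(truth[r.id], int(clf(r.text).label)) for r in sample]
cm = confusion_matrix([t for t, _ in pairs], [p for _, p in pairs])
print(metrics_report(cm))

m = class_metrics(cm)
for cls, rate in rates.items():
    print(f"class {cls:+d}: sensitivity {m.sensitivity[cls]:.3f} "
          f"(planted {1 - rate:.2f})")
# Estimated sensitivities track the planted 1 - error_rate values up to
# binomial sampling noise in the 10% sample.
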
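"""Recognize the type of a micro-expression from centroid displacements.

Fits the per-class bivariate Gaussian models on a synthetic training set and
classifies held-out events from a new subject, printing the per-class
log-probability scores.
"""

from microexp import (PipelineConfig, classify_expression,
                      train_recognizer_on_dataset)
from microexp.pipeline import _SequenceCache
from microexp.synthetic import generate_dataset

config = PipelineConfig()

train = generate_dataset(n_subjects=5, sequences_per_subject=5, seed=2)
model = train_recognizer_on_dataset(train, config)
print("fitted pooled displacement pairs per class:", model.counts)

# a new subject the models have never seen
test = generate_dataset(n_subjects=2, sequences_per_subject=4, seed=77)
test_cache = _SequenceCache(test, config)
correct = total = 0
for rec in test_cache.records:
    for _, row in rec.annotations.iterrows():
        feature = test_cache.displacement(rec, int(row["apex"]))
        result = classify_expression(feature, model)
        total += 1
        correct += result.predicted == row["label"]
        scores = ", ".join(f"{c}: {v:.1f}" for c, v in result.scores.items())
        print(f"{rec.sequence_id} apex {int(row['apex'])}: true "
              f"{row['label']:9s} -> predicted {result.predicted:9s} "
              f"(log-probabilities {scores})")
print(f"accuracy on unseen subjects: {correct}/{total}")
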
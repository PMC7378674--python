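"""Train the LVQ classifier on a phantom cohort and score a held-out one.

Generates 10 normal + 10 suspected training phantoms and an equally
balanced test cohort, fits one prototype per class, and prints the
per-image distance table and the diagnostic metrics.
"""

import numpy as np

import zonelvq as z


def features_of(records):
    X, labels, counts = [], [], []
    for rec in records:
        c = z.partition_and_count(z.binarize(rec.image))
        counts.append(c)
        X.append(z.extract_features(c))
        labels.append(rec.label)
    return np.vstack(X), labels, counts


train_recs = z.generate_cohort(10, 10, seed=20)
test_recs = z.generate_cohort(10, 10, seed=21)

Xtr, ytr, _ = features_of(train_recs)
Xte, yte, counts_te = features_of(test_recs)

model = z.fit(z.TrainingSet(Xtr, ytr))  # alpha=0.05, dec_alpha=0.9, <=100 epochs
print(f"trained for {len(model.training_log)} epochs; "
      f"final mismatches: {model.training_log[-1]['errors']}")

table, cm, metrics = z.evaluate_run(model, Xte, yte, zone_counts=counts_te)
print(table.head(6).to_string(index=False))
print(f"\nTP={cm.tp} TN={cm.tn} FP={cm.fp} FN={cm.fn}")
print(f"accuracy {metrics.accuracy:.1f}%  sensitivity {metrics.sensitivity:.1f}%  "
      f"specificity {metrics.specificity:.1f}%")

# Each row shows the Euclidean distance from the image's 64-feature vector
# to the normal and suspected prototypes; the smaller distance wins, and
# suspected predictions carry the localized image side.
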
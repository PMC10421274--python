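"""Train the attention classifier on a planted-signal dataset and evaluate it.

Generates 160 synthetic molecules whose activity is statistically linked to
intramolecular hydrogen-bond capability, trains the scaled-down model
(2 encoder blocks, 4 heads, d_model 64, 10 epochs), and reports held-out-test
metrics plus the confusion matrix.
"""

import numpy as np

from mathqsar import FixtureSpec, ModelConfig, assign_labels, confusion_and_metrics
from mathqsar.featurizer import FeaturizerConfig
from mathqsar.fixtures import generate_bioactivity_table
from mathqsar.training import featurize_records, train_model

spec = FixtureSpec(n_molecules=160, hbond_signal_strength=0.9, noise=0.1, seed=21)
records = assign_labels(generate_bioactivity_table(spec))
fc = FeaturizerConfig()
descs, labels, _ = featurize_records(records, fc)

rng = np.random.default_rng(0)
order = rng.permutation(len(descs))
n_test = len(descs) // 5
test_idx, train_idx = order[:n_test], order[n_test:]

model, log = train_model(
    [descs[i] for i in train_idx], labels[train_idx],
    ModelConfig.scaled_down(), fc, seed=0,
)
print(f"training loss: {log.losses[0]:.3f} (epoch 1) -> {log.losses[-1]:.3f} "
      f"(epoch {len(log.losses)})")

probs = model.predict_proba([descs[i] for i in test_idx])
report = confusion_and_metrics(labels[test_idx], probs, 0.5)
print(f"test molecules: {report.n}")
print(report.confusion_table())
for name in ("roc_auc", "precision", "recall", "f1", "specificity"):
    v = getattr(report, name)
    print(f"{name:12s} {v:.3f}" if v is not None else f"{name:12s} undefined")
print("ROC AUC above 0.5 means the model ranks active compounds over "
      "inactive ones better than chance; here the signal to learn is the "
      "planted hydrogen-bond/activity association.")
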
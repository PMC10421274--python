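"""Sweep the hydrogen-bond distance threshold.

Re-featurizes a planted-signal dataset at several distance cut-offs
(conformers are embedded once; contacts are re-filtered per threshold), plus
the Boolean presence-matrix mode, and cross-validates the classifier at each
setting. Detection here measures the donor-to-acceptor heavy-atom
separation, which for these scaffolds spans roughly 2.5-3.0 A, so the grid
actually gates contacts in and out; wider cut-offs admit weaker contacts.
"""

from mathqsar import FixtureSpec, ModelConfig, assign_labels, run_sweep
from mathqsar.featurizer import FeaturizerConfig
from mathqsar.fixtures import generate_bioactivity_table

spec = FixtureSpec(n_molecules=80, hbond_signal_strength=0.9, noise=0.1, seed=31)
records = assign_labels(generate_bioactivity_table(spec))

table = run_sweep(
    records,
    thresholds=[2.6, 2.75, 3.0],
    include_boolean=True,
    featurizer_config=FeaturizerConfig(distance_on="donor_acceptor"),
    model_config=ModelConfig.scaled_down(epochs=5),
    seed=0,
    k=3,
)
cols = ["setting", "dthreshold", "n", "roc_auc", "precision", "recall", "f1", "specificity"]
print(table[cols].round(3).to_string(index=False))
best = table.loc[table["roc_auc"].idxmax(), "setting"]
print(f"best ROC AUC setting: {best}")
print("Each row is a 3-fold cross-validation of the same model with the "
      "hydrogen-bond channel rebuilt at that distance cut-off.")
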
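# mathqsar

Hydrogen-bond-augmented molecular self-attention for QSAR bioactivity
classification.

## The problem

Quantitative structure–activity relationship (QSAR) models predict whether a
compound is biologically **active** against a target — here framed as binary
classification of active (IC50 ≤ 1000 nM) versus inactive (IC50 ≥ 10,000 nM)
compounds, the setting used for screening estrogen receptor alpha (ERα)
inhibitor candidates in breast-cancer drug discovery. Transformer models over
molecular graphs perform well on this task when the self-attention is told
about molecular structure; this package additionally feeds it
**intramolecular hydrogen bonds**, which shape the conformation a ligand
adopts when binding its receptor.

It is a library for Python users (see `examples/`) with a thin `math-qsar`
command-line wrapper for the standard workflows.

## The model

For one attention head with projections W<sup>Q</sup>, W<sup>K</sup>,
W<sup>V</sup> over hidden atom states H, standard scaled-dot-product
attention is

    A = softmax(Q Kᵀ / √d_k) V,   Q = H W^Q,  K = H W^K,  V = H W^V.

The molecule self-attention used here mixes those learned weights with fixed
structure matrices before applying them to V:

    A = ( λ_a · softmax(Q Kᵀ / √d_k) + λ_d · g(D) + λ_g · A_adj + λ_h · H_bond ) V

where A_adj ∈ {0,1}^(N×N) is the covalent adjacency matrix, D the pairwise
heavy-atom distance matrix from a 3D conformer, g a row-softmax of −D (nearer
atoms get larger weight), and H_bond ∈ {0,1}^(N×N) marks intramolecular
hydrogen-bond contacts: a hydrogen covalently bound to an N/O/S donor lying
within a distance threshold (default 3.0 Å) of an N/O/S acceptor, projected
onto the donor heavy atom. Setting λ_h = 0 with a zero contact matrix
recovers the structure-aware baseline without hydrogen-bond information, so
the ablation is one configuration flag.

The encoder stacks N such multi-head blocks with residual connections, layer
normalization and a position-wise feed-forward net, then masked-mean-pools
over atoms into a logistic classification head giving P(active). Full-scale
defaults are d_model = 1024, N = 8 blocks, 16 heads, batch 64, 100 epochs,
Adam; `ModelConfig.scaled_down()` (2 blocks, 4 heads, d_model 64, 10 epochs)
runs on a laptop CPU in seconds and is used throughout the tests and
examples.

The package also implements the surrounding workflow: SMILES featurization
(RDKit conformers + canonical atom ordering), bioactivity-table preparation
(salt stripping, deduplication, IC50 → class labels, pIC50 = 9 − log10
IC50/nM, 80/20 split), stratified k-fold cross-validation with the
confusion-matrix metric suite (precision, recall/TPR, specificity, FPR, F1,
ROC AUC), a distance-threshold sweep over the 2.2–4.0 Å hydrogen-bond range,
and a synthetic-data generator whose activity labels are planted on
hydrogen-bond capability so every component is testable offline.

## Worked example

```bash
python examples/featurize_molecule.py
```

```
molecule: CC(C)(C(=O)Nc1nccs1)C1c2ccccc2Oc2cc(O)ccc21
heavy atoms: 26
node feature matrix: (26, 27)
adjacency matrix:    (26, 26), 29 bonds
distance matrix:     (26, 26), max pair separation 11.02 A

molecule: NC(=O)c1ccccc1O
hydrogen bonds at 3.0 A: 1
  donor atom 0 -> acceptor atom 2  (H...acceptor 1.87 A)
```

The first molecule (a hydroxy-xanthenyl propanamide) produces the 26×26
descriptor matrices consumed by the attention blocks. Salicylamide's ortho
hydroxyl donates a 1.87 Å hydrogen bond to its amide carbonyl; that contact
becomes a symmetric pair of 1-entries in the H_bond channel.

Training on the planted-signal fixture
(`python examples/train_and_evaluate.py`) prints the loss curve, the
confusion matrix and the metric suite, e.g. ROC AUC 0.754 on a 32-molecule
held-out set after 10 epochs — better-than-chance ranking driven by the
hydrogen-bond/activity association the generator planted.
`examples/prepare_dataset.py` and `examples/threshold_sweep.py` demonstrate
the cleaning pipeline and the threshold-sweep experiment.

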
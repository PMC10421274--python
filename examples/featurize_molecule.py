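"""Featurize molecules: graph matrices and intramolecular hydrogen bonds.

Builds the descriptor bundle — node features, covalent adjacency, 3D
conformer distances, and hydrogen-bond contacts — for a 26-heavy-atom
hydroxy-xanthenyl propanamide and for salicylamide, whose ortho hydroxyl
donates an intramolecular hydrogen bond to the amide carbonyl.
"""

from mathqsar import FeaturizerConfig, featurize

XANTHENE = "CC(C)(C(=O)Nc1nccs1)C1c2ccccc2Oc2cc(O)ccc21"
SALICYLAMIDE = "NC(=O)c1ccccc1O"

desc = featurize(XANTHENE)
print(f"molecule: {desc.smiles}")
print(f"heavy atoms: {desc.n_atoms}")
print(f"node feature matrix: {desc.node_features.shape}")
print(f"adjacency matrix:    {desc.adjacency.shape}, {int(desc.adjacency.sum())//2} bonds")
print(f"distance matrix:     {desc.distance.shape}, "
      f"max pair separation {desc.distance.max():.2f} A")

desc = featurize(SALICYLAMIDE, FeaturizerConfig(dthreshold=3.0))
print(f"\nmolecule: {desc.smiles}")
print(f"hydrogen bonds at 3.0 A: {len(desc.hbond_triples)}")
for t in desc.hbond_triples:
    print(f"  donor atom {t.donor_heavy_idx} -> acceptor atom "
          f"{t.acceptor_heavy_idx}  (H...acceptor {t.distance:.2f} A)")
print("The symmetric {0,1} contact matrix feeds the attention model as an "
      "extra structural channel alongside adjacency and distance.")
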
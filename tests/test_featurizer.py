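"""Featurizer: parsing, conformers, matrices, H-bond detection."""

import numpy as np
import pytest

from mathqsar.errors import MissingConformerError, ParseError, SanitizeError
from mathqsar.featurizer import (
    NUM_NODE_FEATURES,
    AtomGraph,
    AtomRecord,
    DescriptorSet,
    FeaturizerConfig,
    HBondTriple,
    build_adjacency,
    build_distance_matrix,
    detect_hbonds,
    embed_conformer,
    featurize,
    hbond_matrix,
    parse_smiles,
)

from conftest import SALICYLALDEHYDE, XANTHENE_SMILES


# ---- parsing ----------------------------------------------------------------


def test_parse_ethanol_is_a_three_atom_path():
    g = parse_smiles("CCO")
    assert g.n_atoms == 3
    assert len(g.bonds) == 2
    degrees = sorted(sum((i == k) + (j == k) for i, j in g.bonds) for k in range(3))
    assert degrees == [1, 1, 2]
    assert sorted(a.symbol for a in g.atoms) == ["C", "C", "O"]


def test_parse_single_atom():
    g = parse_smiles("C")
    assert g.n_atoms == 1 and g.bonds == []


def test_parse_worked_example_has_26_heavy_atoms():
    # hydroxy-xanthenyl thiazolyl-propanamide: known 26-heavy-atom structure
    assert parse_smiles(XANTHENE_SMILES).n_atoms == 26


@pytest.mark.parametrize("bad", ["C(C", "xyz123", ""])
def test_parse_errors_on_invalid_smiles(bad):
    with pytest.raises(ParseError):
        parse_smiles(bad)


def test_parse_errors_on_impossible_valence():
    with pytest.raises(SanitizeError):
        parse_smiles("C(C)(C)(C)(C)C")  # pentavalent carbon


def test_parse_is_canonical_across_input_orderings():
    a, b = parse_smiles("OCC"), parse_smiles("CCO")
    assert a.smiles == b.smiles
    assert a.bonds == b.bonds
    assert [r.symbol for r in a.atoms] == [r.symbol for r in b.atoms]


# ---- conformers -------------------------------------------------------------


def test_embed_ethanol_adds_hydrogens_and_is_deterministic():
    g = parse_smiles("CCO")
    e1 = embed_conformer(g, seed=42)
    e2 = embed_conformer(g, seed=42)
    assert e1.coords3d.shape == (9, 3)  # 3 heavy + 6 H
    np.testing.assert_array_equal(e1.coords3d, e2.coords3d)


def test_embed_methane_hydrogen_count():
    e = embed_conformer(parse_smiles("C"), seed=1)
    assert e.coords3d.shape == (5, 3)


def test_embedded_heavy_atoms_do_not_clash():
    e = embed_conformer(parse_smiles(XANTHENE_SMILES), seed=7)
    d = build_distance_matrix(e)
    off_diag = d[~np.eye(d.shape[0], dtype=bool)]
    assert off_diag.min() > 0.9


# ---- adjacency and distance -------------------------------------------------


def _bare_graph(symbols, bonds, coords=None, full_elements=None, full_bonds=None):
    """Hand-built graph; heavy_index_map maps explicit-atom index -> heavy index."""
    atoms = [AtomRecord(s, 0, 0, False, False, 0) for s in symbols]
    full = full_elements or symbols
    heavy_map = None
    if coords is not None:
        heavy_map = {
            full_i: heavy_i
            for heavy_i, full_i in enumerate(
                i for i, el in enumerate(full) if el != "H"
            )
        }
    return AtomGraph(
        atoms=atoms, bonds=bonds, smiles="",
        coords3d=None if coords is None else np.asarray(coords, dtype=float),
        full_elements=full,
        full_bonds=full_bonds if full_bonds is not None else bonds,
        heavy_index_map=heavy_map,
    )


def test_adjacency_of_hand_built_path():
    g = _bare_graph(["C", "C", "O"], [(0, 1), (1, 2)])
    np.testing.assert_array_equal(
        build_adjacency(g), [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
    )


def test_adjacency_single_atom():
    np.testing.assert_array_equal(build_adjacency(_bare_graph(["C"], [])), [[0.0]])


def test_adjacency_worked_example_shape():
    assert build_adjacency(parse_smiles(XANTHENE_SMILES)).shape == (26, 26)


def test_distance_matrix_hand_geometry():
    g = _bare_graph(["C", "C"], [(0, 1)], coords=[[0, 0, 0], [0, 0, 1.5]])
    np.testing.assert_allclose(build_distance_matrix(g), [[0, 1.5], [1.5, 0]])


def test_distance_matrix_single_atom():
    g = _bare_graph(["C"], [], coords=[[1.0, 2.0, 3.0]])
    np.testing.assert_array_equal(build_distance_matrix(g), [[0.0]])


def test_distance_matrix_matches_brute_force_oracle():
    e = embed_conformer(parse_smiles(SALICYLALDEHYDE), seed=42)
    d = build_distance_matrix(e)
    heavy = sorted(e.heavy_index_map, key=e.heavy_index_map.__getitem__)
    for i, fi in enumerate(heavy):
        for j, fj in enumerate(heavy):
            expected = sum((e.coords3d[fi][k] - e.coords3d[fj][k]) ** 2 for k in range(3)) ** 0.5
            assert abs(d[i, j] - expected) < 1e-9


def test_distance_matrix_requires_conformer():
    with pytest.raises(MissingConformerError):
        build_distance_matrix(parse_smiles("CCO"))


# ---- hydrogen bonds ---------------------------------------------------------


def fabricated_oh_o_graph():
    """Two hydroxyls: H1 at 1.84 Å from O2; H2 far from O1."""
    return _bare_graph(
        ["O", "O"], [],
        coords=[[0, 0, 0], [0.96, 0, 0], [2.8, 0, 0], [3.76, 0, 0]],
        full_elements=["O", "H", "O", "H"],
        full_bonds=[(0, 1), (2, 3)],
    )


def test_fabricated_geometry_one_triple_at_22_none_at_15():
    g = fabricated_oh_o_graph()
    triples = detect_hbonds(g, 2.2)
    assert len(triples) == 1
    t = triples[0]
    assert (t.donor_heavy_idx, t.acceptor_heavy_idx) == (0, 1)
    assert abs(t.distance - 1.84) < 1e-12
    assert detect_hbonds(g, 1.5) == []


def test_methane_has_no_hbonds():
    e = embed_conformer(parse_smiles("C"), seed=1)
    assert detect_hbonds(e, 10.0) == []


def test_detect_matches_exhaustive_pairwise_oracle():
    """Independent scan over all (H, N/O/S) pairs with the same exclusions."""
    e = embed_conformer(parse_smiles(XANTHENE_SMILES), seed=7)
    thr = 3.5
    got = detect_hbonds(e, thr)

    els, coords = e.full_elements, e.coords3d
    nbrs = {i: set() for i in range(len(els))}
    for i, j in e.full_bonds:
        nbrs[i].add(j)
        nbrs[j].add(i)
    expected = []
    for h in range(len(els)):
        if els[h] != "H":
            continue
        donor = next(iter(nbrs[h]))
        if els[donor] not in {"N", "O", "S"}:
            continue
        for acc in range(len(els)):
            if els[acc] not in {"N", "O", "S"} or acc == donor:
                continue
            if acc in nbrs[donor] or (nbrs[donor] & nbrs[acc]):
                continue
            dist = float(np.linalg.norm(coords[h] - coords[acc]))
            if dist <= thr:
                expected.append((donor, acc, dist))
    assert len(got) == len(expected)
    for t, (d, a, dist) in zip(got, sorted(expected)):
        assert (t.donor_heavy_idx, t.acceptor_heavy_idx) == (d, a)
        assert abs(t.distance - dist) < 1e-12


def test_threshold_monotonicity_across_sweep_grid():
    e = embed_conformer(parse_smiles(SALICYLALDEHYDE), seed=42)
    grid = [2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0]
    prev = set()
    for t in grid:
        cur = {(x.donor_heavy_idx, x.acceptor_heavy_idx, x.distance) for x in detect_hbonds(e, t)}
        assert prev <= cur
        prev = cur


def test_detect_rejects_nonpositive_threshold():
    with pytest.raises(ValueError):
        detect_hbonds(fabricated_oh_o_graph(), 0.0)


def test_detect_requires_conformer():
    with pytest.raises(MissingConformerError):
        detect_hbonds(parse_smiles("CCO"), 2.2)


def test_loose_donor_mode_is_a_superset():
    e = embed_conformer(parse_smiles(SALICYLALDEHYDE), seed=42)
    strict = {
        (t.donor_heavy_idx, t.acceptor_heavy_idx) for t in detect_hbonds(e, 4.0)
    }
    loose = {
        (t.donor_heavy_idx, t.acceptor_heavy_idx)
        for t in detect_hbonds(e, 4.0, strict_donors=False)
    }
    assert strict <= loose


def test_donor_acceptor_distance_mode():
    # heavy-atom separation is 2.8 Å in both directions, so each hydroxyl
    # donates one triple (unlike H···acceptor mode, where only H1 is close)
    g = fabricated_oh_o_graph()
    triples = detect_hbonds(g, 3.0, distance_on="donor_acceptor")
    assert [(t.donor_heavy_idx, t.acceptor_heavy_idx) for t in triples] == [(0, 1), (1, 0)]
    assert all(abs(t.distance - 2.8) < 1e-12 for t in triples)


def test_hbond_matrix_semantics():
    np.testing.assert_array_equal(hbond_matrix([], 3), np.zeros((3, 3)))
    m = hbond_matrix([HBondTriple(0, 2, 1.9)], 3)
    assert m[0, 2] == m[2, 0] == 1 and m.sum() == 2
    dup = hbond_matrix([HBondTriple(0, 2, 1.9), HBondTriple(0, 2, 2.0)], 3)
    np.testing.assert_array_equal(dup, m)
    with pytest.raises(IndexError):
        hbond_matrix([HBondTriple(0, 5, 1.0)], 3)


# ---- full featurization -----------------------------------------------------


def test_featurize_ethanol_no_intramolecular_hbond():
    d = featurize("CCO", FeaturizerConfig(dthreshold=2.2))
    assert d.n_atoms == 3
    assert d.hbond_bool.sum() == 0 and d.hbond_triples == []
    assert d.node_features.shape == (3, NUM_NODE_FEATURES)


def test_featurize_worked_example_all_matrices_26():
    d = featurize(XANTHENE_SMILES)
    assert d.adjacency.shape == d.distance.shape == d.hbond_bool.shape == (26, 26)
    assert d.node_features.shape[0] == 26


def test_featurize_propagates_parse_error():
    with pytest.raises(ParseError):
        featurize("not-a-smiles((")


def test_featurize_symmetry_and_consistency(signal_dataset):
    _, descs, _ = signal_dataset
    for d in descs[:25]:
        np.testing.assert_array_equal(d.adjacency, d.adjacency.T)
        np.testing.assert_array_equal(d.hbond_bool, d.hbond_bool.T)
        np.testing.assert_allclose(d.distance, d.distance.T, atol=1e-12)
        assert np.all(np.diag(d.adjacency) == 0)
        assert np.all(np.diag(d.hbond_bool) == 0)
        assert np.all(np.diag(d.distance) == 0)
        pairs = {
            frozenset((t.donor_heavy_idx, t.acceptor_heavy_idx)) for t in d.hbond_triples
        }
        assert d.hbond_bool.sum() == 2 * len(pairs)
        # single-conformer distances obey the triangle inequality
        n = d.n_atoms
        dm = d.distance
        assert np.all(dm[:, :, None] <= dm[:, None, :] + dm[None, :, :] + 1e-9)


def test_featurize_is_bit_stable():
    a = featurize(SALICYLALDEHYDE)
    b = featurize(SALICYLALDEHYDE)
    np.testing.assert_array_equal(a.distance, b.distance)
    np.testing.assert_array_equal(a.node_features, b.node_features)
    assert a.hbond_triples == b.hbond_triples


def test_descriptorset_roundtrip(tmp_path):
    d = featurize(SALICYLALDEHYDE)
    prefix = str(tmp_path / "mol")
    d.save(prefix)
    r = DescriptorSet.load(prefix)
    np.testing.assert_array_equal(d.adjacency, r.adjacency)
    np.testing.assert_array_equal(d.distance, r.distance)
    assert d.hbond_triples == r.hbond_triples and d.smiles == r.smiles
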
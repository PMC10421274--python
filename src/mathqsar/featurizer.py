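"""SMILES → molecular-graph descriptors.

Turns a molecule into the matrix bundle consumed by the hydrogen-bond-augmented
attention model: per-atom feature vectors, the covalent adjacency matrix A, the
3D inter-atomic (heavy-atom) distance matrix D, and intramolecular hydrogen-bond
information both as (donor, acceptor, distance) triples and as a {0,1} contact
matrix shape-compatible with A and D.

All matrices are indexed over heavy atoms in RDKit canonical-rank order, so a
given SMILES always produces the same matrices. Hydrogens are made explicit
only for conformer generation and H-bond detection; the detected contacts are
projected onto the hydrogen's covalently bound donor heavy atom.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from scipy.sparse.csgraph import shortest_path

from .errors import (
    EmbedError,
    MissingConformerError,
    ParseError,
    SanitizeError,
)

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: one-hot element vocabulary for node features; anything else maps to "other"
ELEMENT_VOCAB = ("B", "N", "C", "O", "F", "P", "S", "Cl", "Br", "I")

#: elements eligible as hydrogen-bond donors (heavy atom bound to H) and acceptors
HBOND_ELEMENTS = frozenset({"N", "O", "S"})

#: node-feature width: 11 element + 6 degree + 5 attached-H + 3 charge + ring + aromatic
NUM_NODE_FEATURES = len(ELEMENT_VOCAB) + 1 + 6 + 5 + 3 + 2


@dataclass(frozen=True)
class AtomRecord:
    """Per-heavy-atom attributes used to build node feature vectors."""

    symbol: str
    formal_charge: int
    degree: int
    aromatic: bool
    in_ring: bool
    n_hs: int


@dataclass
class AtomGraph:
    """Heavy-atom molecular graph, optionally carrying one 3D conformer.

    ``atoms``/``bonds`` index heavy atoms only, in canonical order. After
    :func:`embed_conformer`, ``coords3d`` holds coordinates for *all* atoms of
    the explicit-hydrogen molecule (heavy atoms first, hydrogens appended),
    ``full_elements``/``full_bonds`` describe that explicit-H topology, and
    ``heavy_index_map`` maps explicit-H atom indices to heavy-graph indices.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]]
    smiles: str
    coords3d: Optional[np.ndarray] = None
    full_elements: Optional[list[str]] = None
    full_bonds: Optional[list[tuple[int, int]]] = None
    heavy_index_map: Optional[dict[int, int]] = None
    mol: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def has_conformer(self) -> bool:
        return self.coords3d is not None


@dataclass(frozen=True, order=True)
class HBondTriple:
    """One intramolecular hydrogen-bond contact on heavy-atom indices.

    ``distance`` is the hydrogen-to-acceptor Euclidean separation in Å (or the
    donor-to-acceptor separation when detection ran in donor–acceptor mode).
    """

    donor_heavy_idx: int
    acceptor_heavy_idx: int
    distance: float


@dataclass
class DescriptorSet:
    """The full per-molecule descriptor bundle with consistent heavy-atom count."""

    node_features: np.ndarray
    adjacency: np.ndarray
    distance: np.ndarray
    hbond_bool: np.ndarray
    hbond_triples: list[HBondTriple]
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return self.adjacency.shape[0]

    def save(self, prefix: str) -> None:
        """Write matrices to ``<prefix>.npz`` and triples to ``<prefix>.json``."""
        np.savez_compressed(
            f"{prefix}.npz",
            node_features=self.node_features,
            adjacency=self.adjacency,
            distance=self.distance,
            hbond_bool=self.hbond_bool,
        )
        with open(f"{prefix}.json", "w") as fh:
            json.dump(
                {
                    "smiles": self.smiles,
                    "hbond_triples": [
                        [t.donor_heavy_idx, t.acceptor_heavy_idx, t.distance]
                        for t in self.hbond_triples
                    ],
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, prefix: str) -> "DescriptorSet":
        arrays = np.load(f"{prefix}.npz")
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        triples = [HBondTriple(int(d), int(a), float(x)) for d, a, x in meta["hbond_triples"]]
        return cls(
            node_features=arrays["node_features"],
            adjacency=arrays["adjacency"],
            distance=arrays["distance"],
            hbond_bool=arrays["hbond_bool"],
            hbond_triples=triples,
            smiles=meta["smiles"],
        )


@dataclass
class FeaturizerConfig:
    """Featurization settings.

    dthreshold
        Maximum H···acceptor distance (Å) for a contact to count as an
        intramolecular hydrogen bond. Default 3.0 Å, the upper edge of the
        moderate (mostly electrostatic) hydrogen-bond regime.
    mode
        ``"distance"`` uses ``dthreshold`` directly; ``"boolean"`` requests the
        presence-matrix variant and always detects at the default 3.0 Å.
    seed
        Random seed for distance-geometry conformer embedding.
    strict_donors
        When True, only hydrogens covalently bound to N/O/S count as donors
        (the default). When False, any hydrogen is a candidate donor.
    exclude_13
        Drop donor/acceptor pairs that share a covalent neighbour; 1,2-pairs
        (donor bonded to acceptor) are always dropped.
    distance_on
        ``"h_acceptor"`` measures H···acceptor; ``"donor_acceptor"`` measures
        the donor-heavy-atom to acceptor separation instead.
    """

    dthreshold: float = 3.0
    mode: str = "distance"
    seed: int = 42
    strict_donors: bool = True
    exclude_13: bool = True
    distance_on: str = "h_acceptor"
    embed_retries: int = 5
    fallback_bond_length: float = 1.5

    def effective_threshold(self) -> float:
        return 3.0 if self.mode == "boolean" else self.dthreshold


def parse_smiles(smiles: str) -> AtomGraph:
    """Parse and sanitize a SMILES string into a canonical heavy-atom graph.

    Atoms are renumbered to RDKit canonical-rank order so that descriptor
    matrices are reproducible regardless of how the input SMILES was written.

    Raises
    ------
    ParseError
        For syntactically invalid SMILES.
    SanitizeError
        For chemically invalid input (e.g. impossible valence).
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several exception types here
        raise SanitizeError(f"sanitization failed for {smiles!r}: {exc}") from exc
    order = tuple(
        int(i)
        for i in np.argsort(
            np.asarray(Chem.CanonicalRankAtoms(mol, breakTies=True), dtype=int)
        )
    )
    mol = Chem.RenumberAtoms(mol, order)
    atoms = [
        AtomRecord(
            symbol=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            degree=a.GetDegree(),
            aromatic=a.GetIsAromatic(),
            in_ring=a.IsInRing(),
            n_hs=a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = sorted(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    return AtomGraph(atoms=atoms, bonds=bonds, smiles=Chem.MolToSmiles(mol), mol=mol)


def embed_conformer(graph: AtomGraph, seed: int = 42, retries: int = 5) -> AtomGraph:
    """Attach one 3D conformer (explicit hydrogens, force-field relaxed).

    Uses ETKDG distance-geometry embedding with the given seed followed by MMFF
    relaxation (UFF if MMFF parameters are unavailable). On failure the seed is
    incremented up to ``retries`` times before :class:`EmbedError` is raised.
    Deterministic for a fixed (graph, seed).
    """
    if graph.mol is None:
        raise ValueError("AtomGraph carries no RDKit molecule; use parse_smiles first")
    molh = Chem.AddHs(graph.mol)
    conf_id = -1
    for attempt in range(retries):
        params = AllChem.ETKDGv3()
        params.randomSeed = seed + attempt
        conf_id = AllChem.EmbedMolecule(molh, params)
        if conf_id == 0:
            break
    if conf_id != 0:
        raise EmbedError(f"conformer embedding failed for {graph.smiles!r} after {retries} seeds")
    try:
        if AllChem.MMFFHasAllMoleculeParams(molh):
            AllChem.MMFFOptimizeMolecule(molh)
        else:
            AllChem.UFFOptimizeMolecule(molh)
    except Exception:
        logger.warning("force-field relaxation failed for %s; using raw embedding", graph.smiles)
    coords = np.array(molh.GetConformer().GetPositions(), dtype=float)
    elements = [a.GetSymbol() for a in molh.GetAtoms()]
    full_bonds = sorted(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in molh.GetBonds()
    )
    # AddHs appends hydrogens after the heavy atoms, preserving heavy indices
    heavy_map = {i: i for i in range(graph.n_atoms)}
    return replace(
        graph,
        coords3d=coords,
        full_elements=elements,
        full_bonds=full_bonds,
        heavy_index_map=heavy_map,
    )


def build_adjacency(graph: AtomGraph) -> np.ndarray:
    """Symmetric {0,1} covalent-bond matrix over heavy atoms, zero diagonal."""
    n = graph.n_atoms
    a = np.zeros((n, n), dtype=float)
    for i, j in graph.bonds:
        a[i, j] = a[j, i] = 1.0
    return a


def build_distance_matrix(graph: AtomGraph) -> np.ndarray:
    """Pairwise Euclidean heavy-atom distances (Å) from the attached conformer."""
    if not graph.has_conformer:
        raise MissingConformerError("no 3D coordinates; call embed_conformer first")
    heavy_full = sorted(graph.heavy_index_map, key=graph.heavy_index_map.__getitem__)
    pos = graph.coords3d[heavy_full]
    diff = pos[:, None, :] - pos[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _neighbour_sets(n: int, bonds: Sequence[tuple[int, int]]) -> list[set[int]]:
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for i, j in bonds:
        nbrs[i].add(j)
        nbrs[j].add(i)
    return nbrs


def detect_hbonds(
    graph: AtomGraph,
    dthreshold: float,
    *,
    strict_donors: bool = True,
    exclude_13: bool = True,
    distance_on: str = "h_acceptor",
) -> list[HBondTriple]:
    """Enumerate intramolecular hydrogen-bond contacts under a distance cut-off.

    A contact is a hydrogen covalently bound to a donor heavy atom (restricted
    to N/O/S unless ``strict_donors=False``) lying within ``dthreshold`` Å of an
    N/O/S acceptor. The acceptor must differ from the donor, must not be bonded
    to it (1,2-contacts), and by default must not share a covalent neighbour
    with it (1,3-contacts); such pairs reflect covalent geometry rather than
    hydrogen bonding. Only the distance criterion is applied — no angle term.

    Triples are reported on heavy-atom indices and sorted by
    (donor, acceptor, distance).
    """
    if dthreshold <= 0:
        raise ValueError(f"dthreshold must be positive, got {dthreshold}")
    if not graph.has_conformer:
        raise MissingConformerError("H-bond detection needs an embedded conformer")
    if distance_on not in ("h_acceptor", "donor_acceptor"):
        raise ValueError(f"unknown distance_on mode: {distance_on!r}")

    elements = graph.full_elements
    coords = graph.coords3d
    nbrs = _neighbour_sets(len(elements), graph.full_bonds)
    heavy_map = graph.heavy_index_map

    triples: list[HBondTriple] = []
    for h_idx, el in enumerate(elements):
        if el != "H":
            continue
        donors = [n for n in nbrs[h_idx] if elements[n] != "H"]
        if not donors:
            continue
        donor = donors[0]
        if strict_donors and elements[donor] not in HBOND_ELEMENTS:
            continue
        if donor not in heavy_map:
            continue
        for acc, acc_el in enumerate(elements):
            if acc_el not in HBOND_ELEMENTS or acc == donor or acc == h_idx:
                continue
            if acc in nbrs[h_idx] or acc in nbrs[donor]:
                continue
            if exclude_13 and (nbrs[donor] & nbrs[acc]):
                continue
            if acc not in heavy_map:
                continue
            ref = h_idx if distance_on == "h_acceptor" else donor
            dist = float(np.linalg.norm(coords[ref] - coords[acc]))
            if 0.0 < dist <= dthreshold:
                triples.append(
                    HBondTriple(heavy_map[donor], heavy_map[acc], dist)
                )
    triples.sort()
    return triples


def hbond_matrix(triples: Sequence[HBondTriple], natoms: int) -> np.ndarray:
    """Project H-bond triples onto a symmetric {0,1} heavy-atom contact matrix."""
    m = np.zeros((natoms, natoms), dtype=float)
    for t in triples:
        i, j = t.donor_heavy_idx, t.acceptor_heavy_idx
        if not (0 <= i < natoms and 0 <= j < natoms):
            raise IndexError(f"triple index ({i},{j}) out of range for natoms={natoms}")
        m[i, j] = m[j, i] = 1.0
    np.fill_diagonal(m, 0.0)
    return m


def node_feature_vector(atom: AtomRecord) -> np.ndarray:
    """Encode one atom: element, degree, attached-H count, charge, ring, aromatic."""
    v = np.zeros(NUM_NODE_FEATURES)
    try:
        v[ELEMENT_VOCAB.index(atom.symbol)] = 1.0
    except ValueError:
        v[len(ELEMENT_VOCAB)] = 1.0
    off = len(ELEMENT_VOCAB) + 1
    v[off + min(atom.degree, 5)] = 1.0
    off += 6
    v[off + min(atom.n_hs, 4)] = 1.0
    off += 5
    v[off + min(max(atom.formal_charge, -1), 1) + 1] = 1.0
    off += 3
    v[off] = float(atom.in_ring)
    v[off + 1] = float(atom.aromatic)
    return v


def build_node_features(graph: AtomGraph) -> np.ndarray:
    return np.stack([node_feature_vector(a) for a in graph.atoms])


def _topological_fallback_distance(graph: AtomGraph, bond_length: float) -> np.ndarray:
    adj = build_adjacency(graph)
    d = shortest_path(adj, method="D", unweighted=True)
    d[~np.isfinite(d)] = graph.n_atoms  # disconnected fragments: cap at N bonds
    return d * bond_length


def featurize(smiles: str, config: FeaturizerConfig | None = None) -> DescriptorSet:
    """SMILES → full descriptor bundle (node features, A, D, H-bond matrix + triples).

    When conformer embedding fails for every retry seed the distance matrix
    falls back to topological shortest-path distances scaled by
    ``config.fallback_bond_length`` Å per bond, and H-bond detection is
    disabled for that molecule (logged).
    """
    config = config or FeaturizerConfig()
    graph = parse_smiles(smiles)
    threshold = config.effective_threshold()
    try:
        graph = embed_conformer(graph, seed=config.seed, retries=config.embed_retries)
        distance = build_distance_matrix(graph)
        triples = detect_hbonds(
            graph,
            threshold,
            strict_donors=config.strict_donors,
            exclude_13=config.exclude_13,
            distance_on=config.distance_on,
        )
    except EmbedError:
        logger.warning(
            "embedding failed for %s; topological distance fallback, H-bonds disabled",
            graph.smiles,
        )
        distance = _topological_fallback_distance(graph, config.fallback_bond_length)
        triples = []
    return DescriptorSet(
        node_features=build_node_features(graph),
        adjacency=build_adjacency(graph),
        distance=distance,
        hbond_bool=hbond_matrix(triples, graph.n_atoms),
        hbond_triples=triples,
        smiles=graph.smiles,
    )
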
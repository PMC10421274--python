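"""Self-contained synthetic bioactivity datasets with a planted
hydrogen-bond/activity association.

Molecules are enumerated from two hand-curated template families:

* family ``A`` — ortho donor/acceptor scaffolds (salicylaldehyde-,
  salicylamide-, 2-nitrophenol-like cores with ring substituents) capable of
  an intramolecular hydrogen bond; every admitted member is verified by
  running the package's own detector on its embedded conformer (≥1 contact at
  3.0 Å, default seed), because some conformers embed with the donor rotated
  away from the acceptor;
* family ``B`` — positional isomers of the same cores with the donor moved
  para or meta to the acceptor, geometrically unable to close the
  intramolecular contact; every admitted member is verified to yield zero
  contacts at 3.0 Å. Because the families are isomer-matched and share one
  substituent set, they differ in hydrogen-bond geometry rather than in
  elemental composition.

Activity labels are planted on the family: an A-scaffold is assigned an
"active" IC50 with probability ``hbond_signal_strength`` (a B-scaffold with
the complementary probability), then flipped with probability ``noise``.
IC50 values are sampled log-uniformly — bioactivity spans orders of
magnitude — and kept 5% away from the 1000/10000 nM class boundaries so
labels are unambiguous; deliberately planted intermediates land in between.
The CSV writer can also plant missing-value rows, duplicate rows and
dot-disconnected salt forms so every cleaning rule can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .featurizer import FeaturizerConfig, detect_hbonds, embed_conformer, parse_smiles

# {R} marks the variable ring position; "" removes it.
# Family B cores are positional isomers of family A cores (donor hydroxyl /
# amide moved para or meta to the acceptor), so the two families are
# compositionally matched and differ in H-bond geometry, not formula.
_CORES_A = (
    "O=Cc1ccc({R})cc1O",
    "CC(=O)c1ccc({R})cc1O",
    "OC(=O)c1ccc({R})cc1O",
    "NC(=O)c1ccc({R})cc1O",
    "COC(=O)c1ccc({R})cc1O",
    "O=[N+]([O-])c1ccc({R})cc1O",
    "CNC(=O)c1ccc({R})cc1O",
    "O=Cc1cc({R})ccc1O",
    "OC(=O)c1cc({R})ccc1O",
    "NC(=O)c1cc({R})ccc1O",
    "O=[N+]([O-])c1cc({R})ccc1O",
    "CNC(=O)c1cc({R})ccc1O",
    "CCNC(=O)c1ccc({R})cc1O",
    "CC(=O)c1cc({R})ccc1O",
    "Nc1ccc({R})cc1C=O",
    "COC(=O)c1cc({R})ccc1O",
)
_CORES_B = (
    "O=Cc1ccc(O)c({R})c1",
    "CC(=O)c1ccc(O)c({R})c1",
    "OC(=O)c1ccc(O)c({R})c1",
    "NC(=O)c1ccc(O)c({R})c1",
    "COC(=O)c1ccc(O)c({R})c1",
    "O=[N+]([O-])c1ccc(O)c({R})c1",
    "CNC(=O)c1ccc(O)c({R})c1",
    "O=Cc1cc({R})cc(O)c1",
    "OC(=O)c1cc({R})cc(O)c1",
    "NC(=O)c1cc({R})cc(O)c1",
    "O=[N+]([O-])c1cc({R})cc(O)c1",
    "CNC(=O)c1cc({R})cc(O)c1",
    "CCNC(=O)c1ccc(O)c({R})c1",
    "CC(=O)c1cc({R})cc(O)c1",
    "Nc1ccc(C=O)c({R})c1",
    "COC(=O)c1cc({R})cc(O)c1",
)
# substituents carry no N/O/S acceptor, so they cannot create new contacts
_SUBSTITUENTS = ("[H]", "C", "F", "Cl", "Br", "CC", "C(C)C", "CCC", "C(C)(C)C", "C=C")

_VERIFY_THRESHOLD = 3.0  # Å, family-A admission check


@dataclass
class FixtureSpec:
    """Parameters of the synthetic dataset.

    ``hbond_signal_strength`` is the probability that an H-bond-capable
    scaffold receives an "active" IC50 (and a donor-free scaffold an
    "inactive" one); ``noise`` flips the planted assignment.
    """

    n_molecules: int = 200
    active_fraction: float = 0.5
    hbond_signal_strength: float = 0.9
    seed: int = 7
    noise: float = 0.1
    n_missing: int = 0
    n_duplicates: int = 0
    n_salts: int = 0
    n_intermediates: int = 0

    def __post_init__(self) -> None:
        for name in ("active_fraction", "hbond_signal_strength", "noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_molecules < 4:
            raise ValueError("n_molecules must be at least 4")


def _enumerate(cores: tuple[str, ...]) -> list[str]:
    """Distinct canonical SMILES from core × substituent products (fixed order)."""
    out, seen = [], set()
    for core in cores:
        for sub in _SUBSTITUENTS:
            smi = core.replace("({R})", "" if sub == "[H]" else f"({sub})")
            try:
                can = parse_smiles(smi).smiles
            except Exception:
                continue
            if can not in seen:
                seen.add(can)
                out.append(can)
    return out


def _hbond_status(smiles: str, seed: int = 42) -> Optional[bool]:
    """True/False: embeddable with/without a contact at 3.0 Å; None: unusable."""
    try:
        graph = embed_conformer(parse_smiles(smiles), seed=seed)
    except Exception:
        return None
    return bool(detect_hbonds(graph, _VERIFY_THRESHOLD))


def generate_pool_with_families(spec: FixtureSpec) -> list[tuple[str, str]]:
    """Deterministic pool of (canonical_smiles, family) pairs.

    Family-A candidates are admitted only if the detector finds a contact at
    3.0 Å on the default-seed conformer; family-B candidates only if it finds
    none.
    """
    rng = np.random.default_rng(spec.seed)
    n_a = round(spec.n_molecules * spec.active_fraction)
    n_b = spec.n_molecules - n_a

    cand_a = _enumerate(_CORES_A)
    cand_b = _enumerate(_CORES_B)
    rng.shuffle(cand_a)
    rng.shuffle(cand_b)

    pool: list[tuple[str, str]] = []
    for cands, family, need in ((cand_a, "A", n_a), (cand_b, "B", n_b)):
        taken = 0
        for smi in cands:
            if taken >= need:
                break
            ok = _hbond_status(smi) is (family == "A")
            if ok:
                pool.append((smi, family))
                taken += 1
        if taken < need:
            raise ValueError(
                f"template family {family} exhausted: {taken}/{need} verified molecules"
            )
    order = rng.permutation(len(pool))
    return [pool[i] for i in order]


def generate_molecule_pool(spec: FixtureSpec) -> list[str]:
    """Distinct, parseable, embeddable SMILES (see module docstring)."""
    return [smi for smi, _ in generate_pool_with_families(spec)]


def _sample_ic50(rng: np.random.Generator, active: bool) -> float:
    # log-uniform, held 5% clear of the 1000/10000 nM label boundaries
    lo, hi = (10.0, 950.0) if active else (10500.0, 1e6)
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def generate_bioactivity_table(spec: FixtureSpec) -> pd.DataFrame:
    """Assay-export-style table with the planted family/activity association.

    Columns: canonical_smiles, standard_value (IC50, nM), standard_units,
    family (ground truth, for auditing). Planted defect rows (missing values,
    duplicates, salts, intermediates) are appended after the clean rows.
    """
    rng = np.random.default_rng(spec.seed + 1)
    # intermediates need their own molecules (a reused SMILES would be removed
    # as a duplicate instead of by the intermediate-exclusion rule)
    from dataclasses import replace as _replace

    pool = generate_pool_with_families(
        _replace(spec, n_molecules=spec.n_molecules + spec.n_intermediates)
    )
    inter_pool = pool[spec.n_molecules:]
    pool = pool[: spec.n_molecules]
    rows = []
    for smi, family in pool:
        p_active = spec.hbond_signal_strength if family == "A" else 1 - spec.hbond_signal_strength
        active = bool(rng.random() < p_active)
        if rng.random() < spec.noise:
            active = not active
        rows.append(
            {
                "canonical_smiles": smi,
                "standard_value": _sample_ic50(rng, active),
                "standard_units": "nM",
                "family": family,
            }
        )
    base = rows[: len(rows)]
    for i in range(spec.n_missing):
        src = base[i % len(base)]
        rows.append({**src, "standard_value": np.nan})
    for i in range(spec.n_duplicates):
        rows.append(dict(base[i % len(base)]))
    for i in range(spec.n_salts):
        src = dict(base[(i + 1) % len(base)])
        src["canonical_smiles"] = src["canonical_smiles"] + ".Cl"
        src["standard_value"] = _sample_ic50(rng, True)
        rows.append(src)
    for smi, family in inter_pool:
        rows.append(
            {
                "canonical_smiles": smi,
                "standard_value": float(10 ** rng.uniform(np.log10(1050.0), np.log10(9500.0))),
                "standard_units": "nM",
                "family": family,
            }
        )
    return pd.DataFrame(rows)


def generate_bioactivity_csv(spec: FixtureSpec, path: str) -> pd.DataFrame:
    """Write the fixture table to ``path`` (CSV) and return it."""
    df = generate_bioactivity_table(spec)
    df.to_csv(path, index=False)
    return df
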
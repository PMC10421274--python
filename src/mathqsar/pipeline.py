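"""Bioactivity-table preparation: clean, deduplicate, label, split.

Ingests an export-style CSV of assay records (canonical SMILES + IC50 in nM),
strips salts to the largest organic fragment, drops records without a
measured IC50 and optionally those matching an annotation blocklist (e.g.
agonist assays), deduplicates on canonical SMILES, assigns activity classes
from IC50 — active ≤ 1000 nM, inactive ≥ 10000 nM, intermediate in between —
converts to pIC50 = 9 − log10(IC50/nM), and emits a random train/test split
with intermediates excluded.

Stage-by-stage record counts are logged so a run can be audited against the
source database snapshot it came from.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .errors import MissingColumnError

logger = logging.getLogger(__name__)

ACTIVE_MAX_NM = 1000.0
INACTIVE_MIN_NM = 10000.0


@dataclass
class LabeledCompound:
    """One compound with its activity annotation."""

    canonical_smiles: str
    ic50_nm: float
    label: str  # "active" | "inactive" | "intermediate"
    pic50: float


@dataclass
class CleanOptions:
    """Cleaning behaviour. ``annotation_col``/``blocklist`` drop rows whose
    annotation field contains any blocklisted substring (case-insensitive) —
    a column-driven approximation of curating out agonist/binder-only assays."""

    strip_salts: bool = True
    drop_missing_value: bool = True
    annotation_col: Optional[str] = None
    blocklist: tuple[str, ...] = ("agonist", "binding agent")


def load_bioactivity_csv(
    path: str,
    smiles_col: str = "canonical_smiles",
    value_col: str = "standard_value",
) -> pd.DataFrame:
    """Read an assay CSV, preserving row order and missing values."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path} contains no records")
    for col in (smiles_col, value_col):
        if col not in df.columns:
            raise MissingColumnError(f"column {col!r} not found in {path}")
    if "standard_units" in df.columns:
        units = df["standard_units"].dropna().unique()
        bad = [u for u in units if str(u).strip() not in ("nM", "")]
        if bad:
            raise ValueError(f"expected IC50 units of nM, found {bad}")
    return df


def largest_fragment(smiles: str) -> str:
    """Strip salts/solvates: keep the largest dot-disconnected fragment.

    Largest by heavy-atom count; ties broken by molecular weight, then by
    lexicographic canonical SMILES.
    """
    if "." not in smiles:
        return smiles
    frags = []
    for part in smiles.split("."):
        mol = Chem.MolFromSmiles(part)
        if mol is None:
            continue
        frags.append(
            (
                mol.GetNumAtoms(),
                Descriptors.MolWt(mol),
                Chem.MolToSmiles(mol),
            )
        )
    if not frags:
        return smiles
    frags.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return frags[0][2]


def clean_compounds(
    df: pd.DataFrame,
    options: CleanOptions | None = None,
    smiles_col: str = "canonical_smiles",
    value_col: str = "standard_value",
) -> pd.DataFrame:
    """Apply the cleaning rules; logs the count removed per rule."""
    options = options or CleanOptions()
    out = df.copy()
    if options.drop_missing_value:
        before = len(out)
        values = pd.to_numeric(out[value_col], errors="coerce")
        out = out[values.notna()].copy()
        out[value_col] = pd.to_numeric(out[value_col])
        logger.info("dropped %d records with missing IC50", before - len(out))
    if options.annotation_col and options.annotation_col in out.columns:
        before = len(out)
        ann = out[options.annotation_col].fillna("").astype(str).str.lower()
        hit = ann.apply(lambda s: any(b in s for b in options.blocklist))
        out = out[~hit]
        logger.info("dropped %d blocklisted records", before - len(out))
    if options.strip_salts:
        n_salts = out[smiles_col].astype(str).str.contains(r"\.", regex=True).sum()
        out[smiles_col] = out[smiles_col].astype(str).map(largest_fragment)
        logger.info("stripped %d salt/multi-fragment SMILES", n_salts)
    return out.reset_index(drop=True)


def canonicalize(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def dedupe_smiles(df: pd.DataFrame, smiles_col: str = "canonical_smiles") -> pd.DataFrame:
    """Keep the first record per canonical SMILES (stable order).

    Rows whose SMILES cannot be parsed are dropped (they cannot be
    canonicalized, featurized, or meaningfully compared).
    """
    out = df.copy()
    out[smiles_col] = out[smiles_col].astype(str).map(canonicalize)
    n_bad = out[smiles_col].isna().sum()
    if n_bad:
        logger.info("dropped %d unparsable SMILES", n_bad)
    out = out[out[smiles_col].notna()]
    before = len(out)
    out = out.drop_duplicates(subset=smiles_col, keep="first")
    logger.info("removed %d duplicate canonical SMILES", before - len(out))
    return out.reset_index(drop=True)


def to_pic50(ic50_nm: float) -> float:
    """pIC50 = −log10(IC50 in mol/L) = 9 − log10(IC50 in nM)."""
    if ic50_nm <= 0 or not math.isfinite(ic50_nm):
        raise ValueError(f"IC50 must be positive and finite, got {ic50_nm}")
    return 9.0 - math.log10(ic50_nm)


def label_for(ic50_nm: float) -> str:
    if ic50_nm <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nm}")
    if ic50_nm <= ACTIVE_MAX_NM:
        return "active"
    if ic50_nm >= INACTIVE_MIN_NM:
        return "inactive"
    return "intermediate"


def assign_labels(
    df: pd.DataFrame,
    smiles_col: str = "canonical_smiles",
    value_col: str = "standard_value",
) -> list[LabeledCompound]:
    """Attach activity class and pIC50 to every record (intermediates kept, flagged)."""
    out = []
    for _, row in df.iterrows():
        ic50 = float(row[value_col])
        out.append(
            LabeledCompound(
                canonical_smiles=str(row[smiles_col]),
                ic50_nm=ic50,
                label=label_for(ic50),
                pic50=to_pic50(ic50),
            )
        )
    return out


def split_dataset(
    records: Sequence[LabeledCompound],
    test_fraction: float = 0.2,
    seed: int = 42,
) -> tuple[list[LabeledCompound], list[LabeledCompound]]:
    """Random train/test split; intermediates are excluded before splitting."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0,1), got {test_fraction}")
    binary = [r for r in records if r.label != "intermediate"]
    if len(binary) < 2:
        raise ValueError("need at least 2 non-intermediate records to split")
    n_test = max(1, round(test_fraction * len(binary)))
    if n_test >= len(binary):
        raise ValueError("test fraction leaves an empty training partition")
    order = np.random.default_rng(seed).permutation(len(binary))
    test_idx = set(order[:n_test].tolist())
    train = [binary[i] for i in range(len(binary)) if i not in test_idx]
    test = [binary[i] for i in range(len(binary)) if i in test_idx]
    for name, part in (("train", train), ("test", test)):
        n_act = sum(r.label == "active" for r in part)
        logger.info("%s: %d records (%d active / %d inactive)", name, len(part), n_act, len(part) - n_act)
    return train, test


def prepare(
    path: str,
    out_path: Optional[str] = None,
    options: CleanOptions | None = None,
    test_fraction: float = 0.2,
    seed: int = 42,
    smiles_col: str = "canonical_smiles",
    value_col: str = "standard_value",
) -> pd.DataFrame:
    """Full pipeline: load → clean → dedupe → label → pIC50 → split.

    Returns (and optionally writes) a table with columns canonical_smiles,
    ic50_nm, pic50, label, split; intermediates carry split="excluded".
    """
    df = load_bioactivity_csv(path, smiles_col, value_col)
    logger.info("loaded %d records", len(df))
    df = clean_compounds(df, options, smiles_col, value_col)
    df = dedupe_smiles(df, smiles_col)
    records = assign_labels(df, smiles_col, value_col)
    train, test = split_dataset(records, test_fraction, seed)
    train_set = {r.canonical_smiles for r in train}
    test_set = {r.canonical_smiles for r in test}
    rows = []
    for r in records:
        split = (
            "train" if r.canonical_smiles in train_set
            else "test" if r.canonical_smiles in test_set
            else "excluded"
        )
        rows.append(
            {
                "canonical_smiles": r.canonical_smiles,
                "ic50_nm": r.ic50_nm,
                "pic50": r.pic50,
                "label": r.label,
                "split": split,
            }
        )
    out = pd.DataFrame(rows)
    if out_path:
        out.to_csv(out_path, index=False)
    return out
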
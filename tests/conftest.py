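"""Shared fixtures: a small verified molecule pool and the planted-signal
dataset used by the learning and determinism checks. Everything is generated
programmatically; the expensive 200-molecule dataset is built once per
session."""

import numpy as np
import pytest

from mathqsar.featurizer import FeaturizerConfig
from mathqsar.fixtures import FixtureSpec, generate_bioactivity_table
from mathqsar.pipeline import assign_labels
from mathqsar.training import featurize_records

XANTHENE_SMILES = "CC(C)(C(=O)Nc1nccs1)C1c2ccccc2Oc2cc(O)ccc21"
SALICYLALDEHYDE = "O=Cc1ccccc1O"
SALICYLAMIDE = "NC(=O)c1ccccc1O"


@pytest.fixture(scope="session")
def featurizer_config():
    return FeaturizerConfig()


@pytest.fixture(scope="session")
def signal_dataset(featurizer_config):
    """200-molecule planted-signal dataset: (records, descriptors, labels)."""
    spec = FixtureSpec(n_molecules=200, hbond_signal_strength=0.9, noise=0.1, seed=7)
    records = assign_labels(generate_bioactivity_table(spec))
    descs, labels, kept = featurize_records(records, featurizer_config)
    assert len(descs) == 200
    return kept, descs, labels


@pytest.fixture(scope="session")
def small_dataset(signal_dataset):
    """60-molecule class-balanced subset for fast training tests."""
    records, descs, labels = signal_dataset
    pos = [i for i, l in enumerate(labels) if l == 1][:30]
    neg = [i for i, l in enumerate(labels) if l == 0][:30]
    idx = pos + neg
    return (
        [records[i] for i in idx],
        [descs[i] for i in idx],
        np.asarray([labels[i] for i in idx]),
    )
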
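"""Shared fixtures.

The session-scoped synthetic world and its pretrained model are the expensive
fixtures; every test needing a trained perturbation core reuses the same one.
"""

from __future__ import annotations

import numpy as np
import pytest

from csg2a import (
    generate_responses,
    generate_triples,
    generate_world,
    pretrain,
)
from csg2a.estimators import response_arrays


@pytest.fixture(scope="session")
def world():
    """The reference synthetic universe: 50 genes, 20 drugs in 4 classes, 30 cells."""
    return generate_world(seed=0)


@pytest.fixture(scope="session")
def world_data(world):
    """3000 pretraining triples with (cell, drug) labels, split 2500/500."""
    triples, labels = generate_triples(world, 3000)
    rng = np.random.default_rng(123)
    perm = rng.permutation(len(triples))
    return {
        "triples": triples,
        "labels": labels,
        "train_idx": perm[500:],
        "test_idx": perm[:500],
    }


@pytest.fixture(scope="session")
def true_adjacency(world):
    return (np.abs(world.weights) > 0).astype(float)


@pytest.fixture(scope="session")
def pretrained(world, world_data, true_adjacency):
    """Perturbation network pretrained on the held-in triples of the world."""
    train = [world_data["triples"][i] for i in world_data["train_idx"]]
    return pretrain(train, ppi=true_adjacency, gene_ids=world.gene_ids, seed=0)


@pytest.fixture(scope="session")
def response_data(world):
    """Viability grid resolved to model inputs, split 480/120."""
    records = generate_responses(world)
    basal = world.basal_matrix()
    g0, conds, y = response_arrays(records, basal)
    rng = np.random.default_rng(99)
    perm = rng.permutation(len(records))
    test, train = perm[:120], perm[120:]
    return {
        "records": records,
        "basal": basal,
        "X_train": (g0[train], [conds[i] for i in train]),
        "y_train": y[train],
        "X_test": (g0[test], [conds[i] for i in test]),
        "y_test": y[test],
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)
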
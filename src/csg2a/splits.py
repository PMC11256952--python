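"""Cross-validation partitioning for drug-response records.

Four schemes of increasing difficulty are supported:

mixed
    plain record-level k-fold; the same cells and drugs may appear on both
    sides of a fold.
cell_blind
    entire cell lines are held out; measures generalisation to unseen cells.
drug_blind
    entire compounds are held out; the cold-start drug setting.
disjoint
    cells and drugs are both partitioned; a fold's test set holds records
    whose cell AND drug are both unseen, records mixing held-out and retained
    entities are dropped from that fold entirely so neither side leaks.

All schemes are deterministic in (k, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import DrugResponseRecord

SCHEMES = ("mixed", "cell_blind", "drug_blind", "disjoint")


@dataclass(frozen=True)
class PartitionScheme:
    name: str
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCHEMES:
            raise ValueError(f"unknown scheme {self.name!r}; choose from {SCHEMES}")
        if self.k < 2:
            raise ValueError("fold count k must be >= 2")


def _grouped_folds(ids: Sequence[str], k: int, rng: np.random.Generator) -> list[set[str]]:
    unique = sorted(set(ids))
    if len(unique) < k:
        raise ValueError(f"need at least {k} distinct entities, got {len(unique)}")
    order = rng.permutation(len(unique))
    return [set(np.array(unique, dtype=object)[chunk]) for chunk in np.array_split(order, k)]


def make_partitions(
    records: Sequence[DrugResponseRecord], scheme: PartitionScheme
) -> list[tuple[list[int], list[int]]]:
    """Build k (train_indices, test_indices) folds under the given scheme."""
    n = len(records)
    if n < scheme.k:
        raise ValueError("fewer records than folds")
    rng = np.random.default_rng(scheme.seed)
    cells = [r.cell_id for r in records]
    drugs = [r.compound_id for r in records]

    if scheme.name == "mixed":
        order = rng.permutation(n)
        folds = []
        for chunk in np.array_split(order, scheme.k):
            test = set(int(i) for i in chunk)
            folds.append(
                (sorted(i for i in range(n) if i not in test), sorted(test))
            )
        return folds

    if scheme.name == "cell_blind":
        groups = _grouped_folds(cells, scheme.k, rng)
        return [
            (
                sorted(i for i in range(n) if cells[i] not in held),
                sorted(i for i in range(n) if cells[i] in held),
            )
            for held in groups
        ]

    if scheme.name == "drug_blind":
        groups = _grouped_folds(drugs, scheme.k, rng)
        return [
            (
                sorted(i for i in range(n) if drugs[i] not in held),
                sorted(i for i in range(n) if drugs[i] in held),
            )
            for held in groups
        ]

    # disjoint: hold out cell group f and drug group f jointly; records pairing
    # a held-out entity with a retained one belong to neither side of fold f.
    cell_groups = _grouped_folds(cells, scheme.k, rng)
    drug_groups = _grouped_folds(drugs, scheme.k, rng)
    folds = []
    for held_cells, held_drugs in zip(cell_groups, drug_groups):
        train, test = [], []
        for i in range(n):
            c_held = cells[i] in held_cells
            d_held = drugs[i] in held_drugs
            if c_held and d_held:
                test.append(i)
            elif not c_held and not d_held:
                train.append(i)
        folds.append((train, test))
    return folds


def save_folds(
    folds: Sequence[tuple[Sequence[int], Sequence[int]]],
    scheme: PartitionScheme,
    path: str | Path,
) -> None:
    payload = {
        "scheme": scheme.name,
        "k": scheme.k,
        "seed": scheme.seed,
        "folds": [
            {"train": [int(i) for i in tr], "test": [int(i) for i in te]}
            for tr, te in folds
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)


def load_folds(path: str | Path) -> tuple[PartitionScheme, list[tuple[list[int], list[int]]]]:
    with open(path) as fh:
        payload = json.load(fh)
    scheme = PartitionScheme(payload["scheme"], payload["k"], payload["seed"])
    return scheme, [(f["train"], f["test"]) for f in payload["folds"]]
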
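"""A seed-reproducible synthetic perturbation universe.

The generator emulates the statistical structure the model assumes, at desk
scale: a sparse signed gene–gene interaction network; drugs grouped into
mechanism-of-action classes, each class perturbing a shared connected subset
of network edges (individual drugs jitter that mask slightly); cell lines
with per-gene location/scale basal expression; dose/time modulation of the
perturbation strength; and cell viability coupled to how strongly essential
genes are perturbed.

Perturbation is single-step linear propagation on normalised profiles,

    gc = g0 + s(d, t) · M_drug · g0 + ε,   s(d, t) = (d/100)·min(t/72, 1),

where ``M_drug`` is the drug's signed masked weight matrix and ε is i.i.d.
Gaussian noise — the simplest structure the attention-as-weights model can
represent exactly, which is what makes recovery tests meaningful.  Viability
follows ``log IC50 = β0 − β1·⟨e, |Δ|⟩ + η`` with essentiality vector e and Δ
the noiseless perturbation at the reference condition (10 µM, 72 h), so
stronger essential-gene perturbation means a more sensitive (lower) log IC50.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import ChemicalCondition, DEFAULT_DOSE_UM, DEFAULT_TIME_H
from .io import (
    DrugResponseRecord,
    ExpressionMatrix,
    robust_zscore,
    write_expression_matrix,
    write_response_table,
)

#: valid small-molecule SMILES assigned to synthetic drugs (structure carries
#: drug identity for the fingerprint encoder; no chemical realism intended)
DRUG_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",       # ibuprofen
    "OC(=O)c1ccccc1O",                  # salicylic acid
    "c1ccc2c(c1)cccc2O",                # naphthol
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",       # procainamide
    "CN1CCC[C@H]1c1cccnc1",             # nicotine
    "OCC1OC(O)C(O)C(O)C1O",             # glucose
    "CC(N)Cc1ccccc1",                   # amphetamine
    "NC(=O)c1ccc[nH]1",                 # pyrrole amide
    "Oc1ccc(cc1)C=CC(=O)O",             # coumaric acid
    "COc1cc(C=O)ccc1O",                 # vanillin
    "CC1=CC(=O)C=CC1=O",                # methylquinone
    "Nc1ccc(cc1)S(N)(=O)=O",            # sulfanilamide
    "OC(=O)C=Cc1ccccc1",                # cinnamic acid
    "CC(C)(C)NCC(O)c1ccc(O)c(O)c1",     # isoproterenol
    "Clc1ccc(cc1)C(c1ccccc1)N1CCCC1",   # aryl pyrrolidine
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",     # naproxen
    "OC(=O)c1cc(O)c(O)c(O)c1",          # gallic acid
    "Nc1ncnc2[nH]cnc12",                # adenine
    "O=c1[nH]cnc2[nH]cnc12",            # hypoxanthine
    "Cc1ccc(cc1)S(=O)(=O)N",            # tosylamide
    "OCc1ccccc1",                       # benzyl alcohol
    "NCCc1ccc(O)c(O)c1",                # dopamine
    "OC(=O)CCc1ccccc1",                 # phenylpropionic acid
    "CN(C)CCc1c[nH]c2ccccc12",          # dimethyltryptamine
    "COc1ccccc1OCC(O)CN",               # aryloxypropanolamine
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",    # melatonin
    "OC(=O)c1ccncc1",                   # isonicotinic acid
    "Clc1ccccc1Cl",                     # dichlorobenzene
    "Oc1ccc2ccccc2c1O",                 # dihydroxynaphthalene
    "CCOC(=O)c1ccc(N)cc1",              # benzocaine
    "CSCCC(N)C(=O)O",                   # methionine
    "NC(Cc1ccc(O)cc1)C(=O)O",           # tyrosine
    "OC(=O)C1CCCN1",                    # proline
    "Nc1ccc(cc1)C(=O)O",                # PABA
    "CC(C)NCC(O)COc1ccccc1",            # propranolol fragment
    "OCC(O)C(O)C(O)C(O)CO",             # sorbitol
    "Cc1ncc(CO)c(C=O)c1O",              # pyridoxal
    "NCCCCC(N)C(=O)O",                  # lysine
    "OC(=O)Cc1c[nH]c2ccccc12",          # indoleacetic acid
    "COc1cc2c(cc1OC)CCN(C)C2",          # tetrahydroisoquinoline
    "CC(O)c1ccccc1",                    # phenylethanol
    "Oc1cccc2cccnc12",                  # hydroxyquinoline
    "CN1CCN(CC1)c1ccccc1",              # phenylpiperazine
    "OC(=O)c1cccc(c1)C(=O)O",           # isophthalic acid
    "CCCCCCCCC(=O)O",                   # nonanoic acid
]


@dataclass
class SimDrug:
    drug_id: str
    smiles: str
    moa_class: int
    mask: frozenset  # of (i, j) edges, i < j


@dataclass
class SyntheticWorld:
    gene_ids: list[str]
    network_edges: list[tuple[int, int]]
    weights: np.ndarray  # symmetric signed (N, N), nonzero only on edges
    drugs: list[SimDrug]
    cell_ids: list[str]
    basal_z: np.ndarray  # (n_cells, N) robust-z basal profiles
    gene_loc: np.ndarray
    gene_scale: np.ndarray
    essentiality: np.ndarray
    noise_sd: float
    beta0: float
    beta1: float
    viability_sd: float
    seed: int
    _drug_index: dict = field(default_factory=dict, repr=False)
    _cell_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._drug_index = {d.drug_id: d for d in self.drugs}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def drug(self, drug_id: str) -> SimDrug:
        if drug_id not in self._drug_index:
            raise KeyError(f"unknown drug {drug_id!r}")
        return self._drug_index[drug_id]

    def basal(self, cell_id: str) -> np.ndarray:
        if cell_id not in self._cell_index:
            raise KeyError(f"unknown cell {cell_id!r}")
        return self.basal_z[self._cell_index[cell_id]]

    def basal_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(list(self.cell_ids), list(self.gene_ids), self.basal_z.copy())

    def drug_matrix(self, drug_id: str) -> np.ndarray:
        """The drug's signed masked weight matrix M."""
        m = np.zeros_like(self.weights)
        for i, j in self.drug(drug_id).mask:
            m[i, j] = m[j, i] = self.weights[i, j]
        return m

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(np.array(self.network_edges).tobytes())
        h.update(self.weights.tobytes())
        h.update(self.basal_z.tobytes())
        h.update(self.essentiality.tobytes())
        for d in self.drugs:
            h.update(d.drug_id.encode())
            h.update(d.smiles.encode())
            h.update(str(d.moa_class).encode())
            h.update(str(sorted(d.mask)).encode())
        return h.hexdigest()


def _connected_edge_subset(
    edges: Sequence[tuple[int, int]], n_pick: int, rng: np.random.Generator
) -> frozenset:
    """Grow a random connected edge subset by frontier expansion."""
    remaining = set(edges)
    start = tuple(edges[rng.integers(len(edges))])
    chosen = {start}
    remaining.discard(start)
    nodes = set(start)
    while len(chosen) < n_pick and remaining:
        frontier = sorted(e for e in remaining if e[0] in nodes or e[1] in nodes)
        if frontier:
            e = frontier[rng.integers(len(frontier))]
        else:  # disconnected component; jump
            pool = sorted(remaining)
            e = pool[rng.integers(len(pool))]
        chosen.add(e)
        remaining.discard(e)
        nodes.update(e)
    return frozenset(chosen)


def _jitter_mask(
    mask: frozenset,
    all_edges: Sequence[tuple[int, int]],
    rate: float,
    rng: np.random.Generator,
) -> frozenset:
    """Drop each mask edge w.p. ``rate`` and add as many fresh network edges."""
    kept = [e for e in sorted(mask) if rng.random() >= rate]
    n_add = len(mask) - len(kept)
    pool = sorted(set(all_edges) - mask)
    if n_add and pool:
        picks = rng.choice(len(pool), size=min(n_add, len(pool)), replace=False)
        kept.extend(pool[i] for i in picks)
    return frozenset(kept)


def generate_world(
    n_genes: int = 50,
    n_drugs: int = 20,
    n_classes: int = 4,
    n_cells: int = 30,
    edge_density: float = 0.1,
    noise_sd: float = 0.05,
    seed: int = 0,
    mask_fraction: float = 0.3,
    jitter_rate: float = 0.05,
    beta0: float = 3.0,
    beta1: float = 1.0,
    viability_sd: float = 0.3,
) -> SyntheticWorld:
    """Sample a complete synthetic universe, deterministic per seed."""
    if n_genes < 3 or n_drugs < 1 or n_cells < 2:
        raise ValueError("degenerate world size")
    if n_classes > n_drugs:
        raise ValueError("n_classes cannot exceed n_drugs")
    if not (0 < edge_density < 1):
        raise ValueError("edge_density must be in (0, 1)")
    if n_drugs > len(DRUG_SMILES):
        raise ValueError(f"at most {len(DRUG_SMILES)} drugs supported")
    rng = np.random.default_rng(seed)

    # network: sample each unordered pair independently, signed edge weights
    iu, ju = np.triu_indices(n_genes, 1)
    present = rng.random(iu.size) < edge_density
    edges = [(int(i), int(j)) for i, j in zip(iu[present], ju[present])]
    if len(edges) < max(4, n_classes):
        raise ValueError("network too sparse; raise edge_density or n_genes")
    weights = np.zeros((n_genes, n_genes))
    mags = rng.uniform(0.3, 0.8, len(edges))
    signs = rng.choice([-1.0, 1.0], len(edges))
    for (i, j), w in zip(edges, mags * signs):
        weights[i, j] = weights[j, i] = w

    # class masks: random connected edge subsets; drugs jitter their class mask
    n_mask = max(3, int(round(mask_fraction * len(edges))))
    class_masks = [_connected_edge_subset(edges, n_mask, rng) for _ in range(n_classes)]
    smiles_pick = rng.permutation(len(DRUG_SMILES))[:n_drugs]
    drugs = []
    for d in range(n_drugs):
        cls = d % n_classes
        drugs.append(
            SimDrug(
                drug_id=f"D{d:03d}",
                smiles=DRUG_SMILES[smiles_pick[d]],
                moa_class=cls,
                mask=_jitter_mask(class_masks[cls], edges, jitter_rate, rng),
            )
        )

    # cells: per-gene location/scale model, then robust-z across the panel
    gene_loc = rng.normal(0.0, 1.0, n_genes)
    gene_scale = rng.uniform(0.3, 0.7, n_genes)
    raw = gene_loc + gene_scale * rng.normal(size=(n_cells, n_genes))
    cell_ids = [f"C{c:03d}" for c in range(n_cells)]
    gene_ids = [f"G{g:03d}" for g in range(n_genes)]
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        basal_z = robust_zscore(
            ExpressionMatrix(cell_ids, gene_ids, raw)
        ).values

    essentiality = rng.uniform(0.0, 1.0, n_genes)
    return SyntheticWorld(
        gene_ids=gene_ids,
        network_edges=edges,
        weights=weights,
        drugs=drugs,
        cell_ids=cell_ids,
        basal_z=basal_z,
        gene_loc=gene_loc,
        gene_scale=gene_scale,
        essentiality=essentiality,
        noise_sd=noise_sd,
        beta0=beta0,
        beta1=beta1,
        viability_sd=viability_sd,
        seed=seed,
    )


def dose_time_strength(dose_uM: float, time_h: float) -> float:
    """Perturbation strength s(d, t) = (d/100)·min(t/72, 1)."""
    return (dose_uM / 100.0) * min(time_h / 72.0, 1.0)


def simulate_perturbation(
    world: SyntheticWorld,
    cell_id: str,
    drug_id: str,
    dose_uM: float = DEFAULT_DOSE_UM,
    time_h: float = DEFAULT_TIME_H,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One treated measurement: (g0, gc) with gc = g0 + s·M·g0 + ε."""
    g0 = world.basal(cell_id)
    m = world.drug_matrix(drug_id)
    s = dose_time_strength(dose_uM, time_h)
    gc = g0 + s * (m @ g0)
    if world.noise_sd > 0:
        rng = rng or np.random.default_rng(world.seed)
        gc = gc + rng.normal(0.0, world.noise_sd, world.n_genes)
    return g0.copy(), gc


def simulate_viability(
    world: SyntheticWorld,
    cell_id: str,
    drug_id: str,
    rng: np.random.Generator | None = None,
) -> float:
    """log IC50 = β0 − β1·⟨e, |Δ|⟩ + η at the reference condition."""
    g0 = world.basal(cell_id)
    delta = dose_time_strength(DEFAULT_DOSE_UM, DEFAULT_TIME_H) * (
        world.drug_matrix(drug_id) @ g0
    )
    value = world.beta0 - world.beta1 * float(world.essentiality @ np.abs(delta))
    if world.viability_sd > 0:
        rng = rng or np.random.default_rng(world.seed)
        value += float(rng.normal(0.0, world.viability_sd))
    return value


PRETRAIN_DOSES = (5.0, 10.0, 25.0, 50.0, 100.0)
PRETRAIN_TIMES = (24.0, 48.0, 72.0)


def generate_triples(
    world: SyntheticWorld, n_triples: int = 3000, seed: int | None = None
) -> tuple[list[tuple[np.ndarray, np.ndarray, ChemicalCondition]], list[tuple[str, str]]]:
    """Random (g0, gc, condition) pretraining triples plus (cell, drug) labels."""
    rng = np.random.default_rng(world.seed if seed is None else seed)
    triples, labels = [], []
    for _ in range(n_triples):
        cell = world.cell_ids[rng.integers(len(world.cell_ids))]
        drug = world.drugs[rng.integers(len(world.drugs))]
        dose = float(PRETRAIN_DOSES[rng.integers(len(PRETRAIN_DOSES))])
        time = float(PRETRAIN_TIMES[rng.integers(len(PRETRAIN_TIMES))])
        g0, gc = simulate_perturbation(world, cell, drug.drug_id, dose, time, rng)
        triples.append((g0, gc, ChemicalCondition(drug.smiles, dose, time)))
        labels.append((cell, drug.drug_id))
    return triples, labels


def generate_responses(
    world: SyntheticWorld, seed: int | None = None
) -> list[DrugResponseRecord]:
    """Full cell × drug viability grid."""
    rng = np.random.default_rng((world.seed if seed is None else seed) + 1)
    records = []
    for cell in world.cell_ids:
        for drug in world.drugs:
            records.append(
                DrugResponseRecord(
                    cell_id=cell,
                    compound_id=drug.drug_id,
                    smiles=drug.smiles,
                    log_ic50=simulate_viability(world, cell, drug.drug_id, rng),
                )
            )
    return records


def affine_shifted_basal(
    world: SyntheticWorld,
    seed: int = 0,
    loc_sd: float = 2.0,
    scale_range: tuple[float, float] = (0.5, 1.5),
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Basal profiles pushed through a known per-gene affine map a + b·x.

    Emulates a dataset living in a different expression space than the
    pretraining panel; returns (shifted matrix, a, b) so scaling-layer
    recovery can be scored against the true shift parameters.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, loc_sd, world.n_genes)
    b = rng.uniform(*scale_range, world.n_genes)
    shifted = a[None, :] + b[None, :] * world.basal_z
    return (
        ExpressionMatrix(list(world.cell_ids), list(world.gene_ids), shifted),
        a,
        b,
    )


def emit_world(
    world: SyntheticWorld,
    outdir: str | Path,
    n_triples: int = 3000,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the world as plain-text files consumable by the CLI.

    basal.tsv / perturbed.tsv hold one row per pretraining triple (aligned);
    compounds.csv the matching per-sample conditions; cells.tsv the per-cell
    basal panel; responses.csv the viability grid; edges.txt the true network
    in STRING-like format (scores above the default confidence threshold, so
    the prior reconstruction keeps exactly the true edges).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    triples, labels = generate_triples(world, n_triples, seed)
    sample_ids = [f"T{i:05d}" for i in range(len(triples))]
    g0 = np.stack([t[0] for t in triples])
    gc = np.stack([t[1] for t in triples])
    paths = {}
    paths["basal"] = outdir / "basal.tsv"
    write_expression_matrix(
        ExpressionMatrix(sample_ids, list(world.gene_ids), g0), paths["basal"]
    )
    paths["perturbed"] = outdir / "perturbed.tsv"
    write_expression_matrix(
        ExpressionMatrix(sample_ids, list(world.gene_ids), gc), paths["perturbed"]
    )
    paths["compounds"] = outdir / "compounds.csv"
    with open(paths["compounds"], "w") as fh:
        fh.write("sample_id,compound_id,smiles,dose_uM,time_h\n")
        for sid, (t, (cell, drug)) in zip(sample_ids, zip(triples, labels)):
            cond = t[2]
            fh.write(f"{sid},{drug},{cond.smiles},{repr(cond.dose_uM)},{repr(cond.time_h)}\n")
    paths["cells"] = outdir / "cells.tsv"
    write_expression_matrix(world.basal_matrix(), paths["cells"])
    paths["responses"] = outdir / "responses.csv"
    write_response_table(generate_responses(world, seed), paths["responses"])
    paths["edges"] = outdir / "edges.txt"
    with open(paths["edges"], "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for i, j in world.network_edges:
            fh.write(f"{world.gene_ids[i]} {world.gene_ids[j]} 950\n")
    return paths
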
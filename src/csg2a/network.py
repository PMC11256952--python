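"""The condition-specific gene–gene attention network.

The model predicts a chemically perturbed expression profile gc from a basal
profile g0 under a treatment condition c = (g0, S, d, t).  Its defining move is
to compute neural-network weights *from the condition itself*:

1. the chemical condition encoder maps (S, d, t) to a gene-aligned vector D
   (structure fingerprint projected through a bias-free MLP, dose and time
   each expanded to two dimensions by learned weights after rescaling);
2. every gene i gets its own expansion weights, giving the gene-level
   condition representation ``Q[i] = g0[i]·W_gene[i] + D[i]·W_comp[i]`` in a
   hidden space of width h;
3. raw dot products ``A_QC[i, j] = Q[i]·Q[j]`` form a symmetric gene–gene
   attention matrix — no softmax and no 1/√h scaling, because the matrix is
   used directly as linear-layer weights and is summed with a binary
   protein-interaction prior, ``A = A_QC + A_PPI``, whose additive semantics a
   normalisation would destroy (an optional 1/√h flag exists for
   experimentation);
4. the perturbed profile is ``gc = W_final · dropout(act(A · g0))`` with no
   bias term anywhere.

Everything here is NumPy with analytic gradients; the batched backward pass is
validated against finite differences in the test suite.  One attention matrix
is materialised per sample and recomputed every forward pass (the weights are
a function of the input, so caching across samples would be wrong); at the
L1000 scale of 978 landmark genes that is ~1M entries per sample, which fits
commodity CPUs with modest batch sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .chem import ChemicalCondition, StructureEncoder, resolve_structure_encoder
from .io import PPIAdjacency


# --------------------------------------------------------------------------
# activations

def _relu(x):
    return np.maximum(x, 0.0)


def _drelu(pre, out):
    return (pre > 0).astype(np.float64)


def _identity(x):
    return x


def _done(pre, out):
    return np.ones_like(pre)


def _dtanh(pre, out):
    return 1.0 - out * out


ACTIVATIONS = {
    "relu": (_relu, _drelu),
    "identity": (_identity, _done),
    "tanh": (np.tanh, _dtanh),
}


# --------------------------------------------------------------------------
# parameters

#: ordered names of all trainable tensors
TENSOR_NAMES = ("W_dose", "W_time", "W_cce1", "W_cce2", "W_gene", "W_comp", "W_final")


@dataclass
class Csg2aParams:
    """All trainable tensors plus the architecture configuration.

    No tensor carries a bias: bias-free layers keep the map between
    transcriptomic spaces purely multiplicative, which is what lets a single
    learned affine rescaling of the inputs re-align a frozen network with a
    new dataset at fine-tuning time.
    """

    tensors: dict[str, np.ndarray]
    n_genes: int
    n_hidden: int = 64
    fp_bits: int = 128
    fp_radius: int = 2
    cce_hidden: int = 512
    activation: str = "tanh"
    dropout: float = 0.1
    scale_attention: bool = False
    attention: bool = True

    def __post_init__(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        m, c, n, h = self.fp_bits, self.cce_hidden, self.n_genes, self.n_hidden
        expected = {
            "W_dose": (2,),
            "W_time": (2,),
            "W_cce1": (m + 4, c),
            "W_cce2": (c, n),
            "W_gene": (n, h),
            "W_comp": (n, h),
            "W_final": (n, n),
        }
        for name, shape in expected.items():
            if name not in self.tensors:
                raise ValueError(f"missing tensor {name}")
            if self.tensors[name].shape != shape:
                raise ValueError(
                    f"tensor {name} has shape {self.tensors[name].shape}, expected {shape}"
                )

    def copy(self) -> "Csg2aParams":
        cfg = self.config()
        return Csg2aParams({k: v.copy() for k, v in self.tensors.items()}, **cfg)

    def config(self) -> dict:
        d = asdict(self)
        d.pop("tensors")
        return d

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for name in TENSOR_NAMES:
            h.update(name.encode())
            h.update(self.tensors[name].tobytes())
        return h.hexdigest()


def init_csg2a_params(
    n_genes: int,
    n_hidden: int = 64,
    fp_bits: int = 128,
    fp_radius: int = 2,
    cce_hidden: int = 512,
    activation: str = "tanh",
    dropout: float = 0.1,
    scale_attention: bool = False,
    attention: bool = True,
    rng: np.random.Generator | None = None,
) -> Csg2aParams:
    """Random initialisation.

    Expansion weights use std 1/√h so raw dot-product attention entries start
    with magnitudes comparable to the binary interaction prior; the final
    linear layer starts near the identity so the untrained network already
    approximates gc ≈ act(A·g0), which stabilises early training.
    """
    rng = rng or np.random.default_rng(0)
    m, c, n, h = fp_bits, cce_hidden, n_genes, n_hidden
    tensors = {
        "W_dose": rng.normal(0.0, 0.5, 2),
        "W_time": rng.normal(0.0, 0.5, 2),
        "W_cce1": rng.normal(0.0, np.sqrt(2.0 / (m + 4)), (m + 4, c)),
        "W_cce2": rng.normal(0.0, np.sqrt(1.0 / c), (c, n)),
        "W_gene": rng.normal(0.0, 1.0 / np.sqrt(h), (n, h)),
        "W_comp": rng.normal(0.0, 1.0 / np.sqrt(h), (n, h)),
        "W_final": np.eye(n) + rng.normal(0.0, 0.01, (n, n)),
    }
    return Csg2aParams(
        tensors,
        n_genes=n_genes,
        n_hidden=n_hidden,
        fp_bits=fp_bits,
        fp_radius=fp_radius,
        cce_hidden=cce_hidden,
        activation=activation,
        dropout=dropout,
        scale_attention=scale_attention,
        attention=attention,
    )


@dataclass
class AttentionMatrix:
    """A gene × gene attention matrix with its provenance kind.

    ``kind`` is "QC" for the raw dot-product scores, "PPI" for the prior and
    "CSG2A" for their sum (the matrix actually used as network weights).
    """

    A: np.ndarray
    kind: str = "CSG2A"
    gene_ids: list[str] | None = None


def _as_array(x) -> np.ndarray:
    if isinstance(x, AttentionMatrix):
        return x.A
    if isinstance(x, PPIAdjacency):
        return x.matrix
    return np.asarray(x, dtype=np.float64)


# --------------------------------------------------------------------------
# condition features and encoder forward

def condition_features(
    conds: Sequence[ChemicalCondition], encoder: StructureEncoder
) -> dict[str, np.ndarray]:
    """Deterministic per-condition inputs: fingerprints and scaled dose/time."""
    fps = np.stack([encoder.encode(c.smiles) for c in conds])
    scaled = np.array([c.scaled() for c in conds])
    return {"FP": fps, "d": scaled[:, 0], "t": scaled[:, 1]}


def _cce_forward(params: Csg2aParams, feats: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    act, _ = ACTIVATIONS[params.activation]
    t = params.tensors
    X = np.concatenate(
        [
            feats["FP"],
            feats["d"][:, None] * t["W_dose"][None, :],
            feats["t"][:, None] * t["W_time"][None, :],
        ],
        axis=1,
    )
    H_pre = X @ t["W_cce1"]
    H = act(H_pre)
    D = H @ t["W_cce2"]
    return {"X": X, "H_pre": H_pre, "H": H, "D": D}


def condition_concat(
    cond: ChemicalCondition, params: Csg2aParams, encoder: StructureEncoder | None = None
) -> np.ndarray:
    """The pre-MLP concatenation [fingerprint, d′·W_dose, t′·W_time]."""
    encoder = encoder or resolve_structure_encoder(
        {"type": "fingerprint", "bits": params.fp_bits, "radius": params.fp_radius}
    )
    feats = condition_features([cond], encoder)
    return _cce_forward(params, feats)["X"][0]


def encode_condition(
    cond: ChemicalCondition | Sequence[ChemicalCondition],
    params: Csg2aParams,
    encoder: StructureEncoder | None = None,
) -> np.ndarray:
    """The gene-aligned chemical condition representation D (length Ngene)."""
    single = isinstance(cond, ChemicalCondition)
    conds = [cond] if single else list(cond)
    encoder = encoder or resolve_structure_encoder(
        {"type": "fingerprint", "bits": params.fp_bits, "radius": params.fp_radius}
    )
    feats = condition_features(conds, encoder)
    if feats["FP"].shape[1] != params.fp_bits:
        raise ValueError(
            f"encoder produces {feats['FP'].shape[1]} features, model expects {params.fp_bits}"
        )
    D = _cce_forward(params, feats)["D"]
    return D[0] if single else D


# --------------------------------------------------------------------------
# public single-sample operations

def gene_condition_representation(
    g0: np.ndarray, D: np.ndarray, params: Csg2aParams
) -> np.ndarray:
    """Per-gene expansion Q[i] = g0[i]·W_gene[i] + D[i]·W_comp[i] (Ngene × h)."""
    g0 = np.asarray(g0, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64)
    n = params.n_genes
    if g0.shape != (n,) or D.shape != (n,):
        raise ValueError(f"expected vectors of length {n}, got {g0.shape} and {D.shape}")
    t = params.tensors
    return g0[:, None] * t["W_gene"] + D[:, None] * t["W_comp"]


def attention_scores(Q: np.ndarray, scale: bool = False) -> np.ndarray:
    """Raw dot-product attention A[i, j] = Q[i]·Q[j]; symmetric by construction."""
    Q = np.asarray(Q, dtype=np.float64)
    if not np.isfinite(Q).all():
        raise ValueError("non-finite condition representation")
    A = Q @ Q.T
    if scale:
        A = A / np.sqrt(Q.shape[1])
    return A


def combine_with_prior(A_qc, A_ppi) -> np.ndarray:
    """Fuse the data-driven scores with the interaction prior: A_QC + A_PPI."""
    qc_genes = A_qc.gene_ids if isinstance(A_qc, AttentionMatrix) else None
    ppi_genes = A_ppi.gene_ids if isinstance(A_ppi, PPIAdjacency) else None
    if qc_genes is not None and ppi_genes is not None and list(qc_genes) != list(ppi_genes):
        raise ValueError("attention and prior gene orderings differ")
    a, p = _as_array(A_qc), _as_array(A_ppi)
    if a.shape != p.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {p.shape}")
    return a + p


def forward_perturbation(
    g0: np.ndarray,
    A,
    params: Csg2aParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Run the attention-as-weights network: W_final·dropout(act(A·g0))."""
    act, _ = ACTIVATIONS[params.activation]
    g0 = np.asarray(g0, dtype=np.float64)
    A = _as_array(A)
    z = A @ g0
    if not np.isfinite(z).all():
        raise FloatingPointError("non-finite values after the attention linear stage")
    a = act(z)
    if training and params.dropout > 0:
        rng = rng or np.random.default_rng(0)
        keep = 1.0 - params.dropout
        a = a * (rng.random(a.shape) < keep) / keep
    gc = params.tensors["W_final"] @ a
    if not np.isfinite(gc).all():
        raise FloatingPointError("non-finite values after the final linear stage")
    return gc


def predict_perturbed_profile(
    g0: np.ndarray,
    cond: ChemicalCondition,
    a_ppi,
    params: Csg2aParams,
    encoder: StructureEncoder | None = None,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, AttentionMatrix]:
    """Full composite gc = p(θ|c)(g0); also returns the attention matrix used."""
    D = encode_condition(cond, params, encoder)
    if params.attention:
        Q = gene_condition_representation(np.asarray(g0, dtype=np.float64), D, params)
        A_qc = attention_scores(Q, scale=params.scale_attention)
        A = combine_with_prior(A_qc, a_ppi if a_ppi is not None else np.zeros_like(A_qc))
        gc = forward_perturbation(g0, A, params, training=training, rng=rng)
        gene_ids = a_ppi.gene_ids if isinstance(a_ppi, PPIAdjacency) else None
        return gc, AttentionMatrix(A, "CSG2A", gene_ids)
    # plain additive core: no attention, z = g0 + D
    act, _ = ACTIVATIONS[params.activation]
    a = act(np.asarray(g0, dtype=np.float64) + D)
    if training and params.dropout > 0:
        rng = rng or np.random.default_rng(0)
        keep = 1.0 - params.dropout
        a = a * (rng.random(a.shape) < keep) / keep
    gc = params.tensors["W_final"] @ a
    return gc, AttentionMatrix(np.zeros((params.n_genes,) * 2), "CSG2A", None)


# --------------------------------------------------------------------------
# batched forward/backward used by training

def forward_batch(
    params: Csg2aParams,
    g0: np.ndarray,
    feats: dict[str, np.ndarray],
    a_ppi: np.ndarray | None,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Vectorised forward pass over a batch; returns (gc, cache for backward)."""
    act, _ = ACTIVATIONS[params.activation]
    t = params.tensors
    cache = _cce_forward(params, feats)
    D = cache["D"]
    g0 = np.asarray(g0, dtype=np.float64)
    cache.update({"g0": g0, "feats": feats})

    if params.attention:
        Q = g0[:, :, None] * t["W_gene"][None] + D[:, :, None] * t["W_comp"][None]
        A = np.matmul(Q, Q.transpose(0, 2, 1))
        if params.scale_attention:
            A = A / np.sqrt(params.n_hidden)
        if a_ppi is not None:
            A = A + a_ppi[None]
        z = np.matmul(A, g0[:, :, None])[:, :, 0]
        cache.update({"Q": Q, "A": A})
    else:
        z = g0 + D
    a_pre = act(z)
    if training and params.dropout > 0:
        rng = rng or np.random.default_rng(0)
        keep = 1.0 - params.dropout
        mask = (rng.random(a_pre.shape) < keep) / keep
    else:
        mask = np.ones_like(a_pre)
    a = a_pre * mask
    gc = a @ t["W_final"].T
    cache.update({"z": z, "a_pre": a_pre, "mask": mask, "a": a})
    return gc, cache


def backward_batch(
    params: Csg2aParams,
    cache: dict,
    d_gc: np.ndarray,
    d_D_extra: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Analytic gradients for a batch.

    Returns (grads keyed like ``params.tensors``, gradient w.r.t. the basal
    input g0).  ``d_D_extra`` lets a downstream consumer of the condition
    representation (the response head) inject its gradient contribution.
    """
    _, dact = ACTIVATIONS[params.activation]
    t = params.tensors
    g0, feats = cache["g0"], cache["feats"]
    m = params.fp_bits

    grads: dict[str, np.ndarray] = {}
    grads["W_final"] = d_gc.T @ cache["a"]
    da = d_gc @ t["W_final"]
    dz = da * cache["mask"] * dact(cache["z"], cache["a_pre"])

    if params.attention:
        Q = cache["Q"]
        dA = dz[:, :, None] * g0[:, None, :]
        dg0 = np.matmul(cache["A"].transpose(0, 2, 1), dz[:, :, None])[:, :, 0]
        if params.scale_attention:
            dA = dA / np.sqrt(params.n_hidden)
        dQ = np.matmul(dA + dA.transpose(0, 2, 1), Q)
        grads["W_gene"] = np.einsum("bi,bih->ih", g0, dQ)
        grads["W_comp"] = np.einsum("bi,bih->ih", cache["D"], dQ)
        dD = np.einsum("bih,ih->bi", dQ, t["W_comp"])
        dg0 += np.einsum("bih,ih->bi", dQ, t["W_gene"])
    else:
        dg0 = dz.copy()
        dD = dz.copy()
        grads["W_gene"] = np.zeros_like(t["W_gene"])
        grads["W_comp"] = np.zeros_like(t["W_comp"])

    if d_D_extra is not None:
        dD = dD + d_D_extra

    grads["W_cce2"] = cache["H"].T @ dD
    dH = dD @ t["W_cce2"].T
    dH_pre = dH * dact(cache["H_pre"], cache["H"])
    grads["W_cce1"] = cache["X"].T @ dH_pre
    dX = dH_pre @ t["W_cce1"].T
    grads["W_dose"] = (feats["d"][:, None] * dX[:, m : m + 2]).sum(axis=0)
    grads["W_time"] = (feats["t"][:, None] * dX[:, m + 2 : m + 4]).sum(axis=0)
    return grads, dg0


# --------------------------------------------------------------------------
# checkpointing

def save_checkpoint(
    path: str | Path,
    params: Csg2aParams,
    gene_ids: Sequence[str],
    a_ppi: np.ndarray | PPIAdjacency | None,
    extra: dict | None = None,
) -> None:
    """Single-archive checkpoint: tensors, gene ordering, prior and config.

    Loadable without the original edge list; ``extra`` may hold additional
    tensors (e.g. scaling-layer and head weights) and config of a fine-tuned
    model.
    """
    payload: dict[str, np.ndarray] = {
        f"tensor_{k}": v for k, v in params.tensors.items()
    }
    payload["gene_ids"] = np.array(list(gene_ids), dtype=object)
    payload["a_ppi"] = _as_array(a_ppi) if a_ppi is not None else np.zeros((0, 0))
    extra = extra or {}
    extra_tensors = extra.pop("tensors", {})
    for k, v in extra_tensors.items():
        payload[f"extra_{k}"] = np.asarray(v)
    payload["config_json"] = np.array(
        json.dumps({"params": params.config(), "extra": extra}, sort_keys=True)
    )
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path: str | Path):
    """Load a checkpoint; returns (params, gene_ids, a_ppi, extra dict)."""
    with np.load(path, allow_pickle=True) as z:
        cfg = json.loads(str(z["config_json"]))
        tensors = {
            k[len("tensor_") :]: z[k] for k in z.files if k.startswith("tensor_")
        }
        params = Csg2aParams(tensors, **cfg["params"])
        gene_ids = [str(g) for g in z["gene_ids"]]
        a_ppi = z["a_ppi"]
        a_ppi = None if a_ppi.size == 0 else a_ppi
        extra = cfg["extra"]
        extra["tensors"] = {
            k[len("extra_") :]: z[k] for k in z.files if k.startswith("extra_")
        }
    return params, gene_ids, a_ppi, extra
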
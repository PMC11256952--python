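"""Training stages as scikit-learn-style estimators.

:class:`PerturbationNetwork` is the pretraining stage: it fits the
condition-specific attention network to paired (basal, condition, perturbed)
transcriptome triples with an MSE loss on the perturbed profile.

:class:`IC50Regressor` is the transfer stage: it wraps a pretrained (and by
default fully frozen) perturbation core with a learnable per-gene scaling
layer ``g0' = (g0 − μ)/σ`` that re-aligns new basal profiles with the
pretraining expression space, plus a bias-free prediction head that maps the
concatenation [predicted perturbed profile, condition representation, scaled
basal profile] to a scalar natural-log IC50.

Both estimators follow the scikit-learn contract (``get_params`` /
``set_params``, fitted attributes with trailing underscores, ``fit`` returns
``self``) and are deterministic given their ``seed``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .chem import (
    ChemicalCondition,
    DEFAULT_DOSE_UM,
    DEFAULT_TIME_H,
    resolve_structure_encoder,
)
from .io import DrugResponseRecord, ExpressionMatrix, PPIAdjacency
from .network import (
    ACTIVATIONS,
    Csg2aParams,
    backward_batch,
    condition_features,
    forward_batch,
    init_csg2a_params,
    load_checkpoint,
    save_checkpoint,
    _as_array,
)

SIGMA_FLOOR = 1e-4


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error over all entries."""
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


class _Adam:
    """Plain Adam over a dict of named tensors."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, tensors: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1**self.t)
            vhat = self.v[name] / (1 - self.b2**self.t)
            tensors[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _unpack_X(X) -> tuple[np.ndarray, list[ChemicalCondition]]:
    g0, conds = X
    g0 = np.asarray(g0, dtype=np.float64)
    if g0.ndim == 1:
        g0 = g0[None, :]
    conds = list(conds)
    if len(conds) != g0.shape[0]:
        raise ValueError(f"{g0.shape[0]} profiles but {len(conds)} conditions")
    return g0, conds


class PerturbationNetwork(BaseEstimator):
    """Condition-specific attention network trained on perturbation triples.

    Parameters
    ----------
    n_hidden:
        Width h of the per-gene condition representation.
    cce_hidden:
        Hidden width of the bias-free condition-encoder MLP.
    fp_bits, fp_radius:
        Circular-fingerprint configuration of the default structure encoder.
    activation, dropout:
        Nonlinearity and dropout rate of the perturbation network.
    attention:
        When False the core degenerates to the plain additive baseline
        (z = g0 + D, no gene–gene attention) used for ablation.
    scale_attention:
        Optional 1/√h scaling of the dot-product scores (off by default:
        the scores are summed with a binary prior and used directly as
        weights).
    use_ppi:
        Whether to add the interaction prior passed to :meth:`fit`.
    learning_rate, batch_size, max_epochs, patience, val_fraction, seed:
        Adam optimisation protocol; the parameters returned are the ones with
        the best validation MSE (best-checkpoint selection), and all
        stochastic choices derive from ``seed``.
    """

    def __init__(
        self,
        *,
        n_hidden: int = 64,
        cce_hidden: int = 512,
        fp_bits: int = 128,
        fp_radius: int = 2,
        activation: str = "tanh",
        dropout: float = 0.1,
        attention: bool = True,
        scale_attention: bool = False,
        use_ppi: bool = True,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 20,
        val_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.n_hidden = n_hidden
        self.cce_hidden = cce_hidden
        self.fp_bits = fp_bits
        self.fp_radius = fp_radius
        self.activation = activation
        self.dropout = dropout
        self.attention = attention
        self.scale_attention = scale_attention
        self.use_ppi = use_ppi
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    # -- helpers -----------------------------------------------------------

    def _encoder(self):
        return resolve_structure_encoder(
            {"type": "fingerprint", "bits": self.fp_bits, "radius": self.fp_radius}
        )

    def _eval_forward(self, g0: np.ndarray, feats: dict, chunk: int = 256) -> np.ndarray:
        out = np.empty_like(g0)
        for lo in range(0, g0.shape[0], chunk):
            hi = lo + chunk
            sub = {k: v[lo:hi] for k, v in feats.items()}
            out[lo:hi], _ = forward_batch(self.params_, g0[lo:hi], sub, self.ppi_)
        return out

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, *, ppi=None, gene_ids: Sequence[str] | None = None):
        """Fit on (basal profiles, conditions) → perturbed profiles.

        ``X`` is a pair ``(g0, conditions)`` with ``g0`` of shape
        (n_samples, n_genes); ``y`` holds the perturbed profiles with the same
        shape.  ``ppi`` is the optional interaction prior (adjacency array or
        :class:`PPIAdjacency`) aligned to the gene ordering.
        """
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        g0, conds = _unpack_X(X)
        y = np.asarray(y, dtype=np.float64)
        if y.shape != g0.shape:
            raise ValueError(f"target shape {y.shape} != input shape {g0.shape}")
        n, n_genes = g0.shape
        if isinstance(ppi, PPIAdjacency) and gene_ids is None:
            gene_ids = ppi.gene_ids
        self.gene_ids_ = list(gene_ids) if gene_ids is not None else None
        a_ppi = _as_array(ppi) if (ppi is not None and self.use_ppi) else None
        self.ppi_ = a_ppi

        rng = np.random.default_rng(self.seed)
        self.params_ = init_csg2a_params(
            n_genes,
            n_hidden=self.n_hidden,
            fp_bits=self.fp_bits,
            fp_radius=self.fp_radius,
            cce_hidden=self.cce_hidden,
            activation=self.activation,
            dropout=self.dropout,
            scale_attention=self.scale_attention,
            attention=self.attention,
            rng=rng,
        )
        encoder = self._encoder()
        feats = condition_features(conds, encoder)

        perm = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if train_idx.size == 0:
            raise ValueError("no training samples left after validation split")

        opt = _Adam(self.learning_rate)
        best_val, best_params, best_epoch = np.inf, None, -1
        history: dict[str, list[float]] = {"train_mse": [], "val_mse": []}
        since_best = 0
        for epoch in range(self.max_epochs):
            order = train_idx[rng.permutation(train_idx.size)]
            batch_losses = []
            for b, lo in enumerate(range(0, order.size, self.batch_size)):
                idx = order[lo : lo + self.batch_size]
                sub = {k: v[idx] for k, v in feats.items()}
                gc, cache = forward_batch(
                    self.params_, g0[idx], sub, a_ppi, training=True, rng=rng
                )
                diff = gc - y[idx]
                loss = float(np.mean(diff**2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, batch {b}"
                    )
                batch_losses.append(loss)
                d_gc = 2.0 * diff / diff.size
                grads, _ = backward_batch(self.params_, cache, d_gc)
                opt.step(self.params_.tensors, grads)
            val_mse = mse_loss(
                self._eval_forward(g0[val_idx], {k: v[val_idx] for k, v in feats.items()}),
                y[val_idx],
            )
            history["train_mse"].append(float(np.mean(batch_losses)))
            history["val_mse"].append(val_mse)
            if val_mse < best_val:
                best_val, best_epoch, since_best = val_mse, epoch, 0
                best_params = self.params_.copy()
            else:
                since_best += 1
                if since_best > self.patience:
                    break
        self.params_ = best_params
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_mse_ = float(best_val)
        self.n_genes_ = n_genes
        self.encoder_ = encoder
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted perturbed profiles (deterministic, dropout off)."""
        g0, conds = _unpack_X(X)
        feats = condition_features(conds, self.encoder_)
        return self._eval_forward(g0, feats)

    def attention_maps(self, X) -> np.ndarray:
        """Per-sample attention matrices (the weights actually applied)."""
        g0, conds = _unpack_X(X)
        if not self.params_.attention:
            raise ValueError("the plain additive core has no attention maps")
        feats = condition_features(conds, self.encoder_)
        maps = np.empty((g0.shape[0], self.n_genes_, self.n_genes_))
        for lo in range(0, g0.shape[0], 64):
            hi = lo + 64
            sub = {k: v[lo:hi] for k, v in feats.items()}
            _, cache = forward_batch(self.params_, g0[lo:hi], sub, self.ppi_)
            maps[lo:hi] = cache["A"]
        return maps

    def score(self, X, y) -> float:
        """Negative MSE (higher is better, per scikit-learn convention)."""
        return -mse_loss(self.predict(X), np.asarray(y, dtype=np.float64))

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        save_checkpoint(
            path,
            self.params_,
            self.gene_ids_ or [f"g{i}" for i in range(self.n_genes_)],
            self.ppi_,
            extra={"estimator": self.get_params()},
        )

    @classmethod
    def load(cls, path) -> "PerturbationNetwork":
        params, gene_ids, a_ppi, extra = load_checkpoint(path)
        est = cls(**{k: v for k, v in extra.get("estimator", {}).items()})
        est.params_ = params
        est.gene_ids_ = gene_ids
        est.ppi_ = a_ppi
        est.n_genes_ = params.n_genes
        est.encoder_ = est._encoder()
        est.history_ = {}
        return est


def _softplus(x):
    return np.logaddexp(0.0, x)


def _softplus_inv(y):
    # inverse of softplus for y > 0
    return np.where(y > 30, y, np.log(np.expm1(np.clip(y, 1e-10, None))))


class IC50Regressor(BaseEstimator):
    """Cell-level log IC50 prediction by frozen transfer from a pretrained core.

    Parameters
    ----------
    pretrained:
        A fitted :class:`PerturbationNetwork`, a checkpoint path, or None.
        With None a randomly initialised core is created at ``fit`` time
        (the no-pretraining ablation).
    freeze_pretrained:
        When True (default) no pretrained tensor changes during fitting —
        only the scaling layer and the head train; verified bitwise by
        :meth:`core_checksum`.
    head_hidden:
        Width of the bias-free prediction head (input → head_hidden → 1).
    fusion:
        "concat" (default) joins [gc, D, g0'] into one vector; "sum" adds
        them, for ablation.
    dose_uM, time_h:
        Treatment condition injected into records that carry none
        (viability screens are conventionally read out at 10 µM / 72 h).
    init_scaling_from_data:
        Initialise (μ, σ) at the per-gene mean/std of the fine-tuning basal
        matrix (standard normalisation-layer practice); they remain free
        parameters trained by the IC50 loss.
    """

    def __init__(
        self,
        *,
        pretrained=None,
        freeze_pretrained: bool = True,
        head_hidden: int = 256,
        fusion: str = "concat",
        dose_uM: float = DEFAULT_DOSE_UM,
        time_h: float = DEFAULT_TIME_H,
        activation: str = "tanh",
        init_scaling_from_data: bool = True,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 100,
        patience: int = 10,
        val_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.pretrained = pretrained
        self.freeze_pretrained = freeze_pretrained
        self.head_hidden = head_hidden
        self.fusion = fusion
        self.dose_uM = dose_uM
        self.time_h = time_h
        self.activation = activation
        self.init_scaling_from_data = init_scaling_from_data
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    # -- assembly ----------------------------------------------------------

    def _resolve_core(self, n_genes: int, rng) -> tuple[Csg2aParams, np.ndarray | None, object]:
        src = self.pretrained
        if src is None:
            params = init_csg2a_params(n_genes, rng=rng)
            enc = resolve_structure_encoder(
                {"type": "fingerprint", "bits": params.fp_bits, "radius": params.fp_radius}
            )
            return params, None, enc
        if isinstance(src, (str, bytes)) or hasattr(src, "__fspath__"):
            params, _, a_ppi, _ = load_checkpoint(src)
            enc = resolve_structure_encoder(
                {"type": "fingerprint", "bits": params.fp_bits, "radius": params.fp_radius}
            )
            return params.copy(), a_ppi, enc
        if isinstance(src, PerturbationNetwork):
            return src.params_.copy(), src.ppi_, src.encoder_
        if isinstance(src, Csg2aParams):
            enc = resolve_structure_encoder(
                {"type": "fingerprint", "bits": src.fp_bits, "radius": src.fp_radius}
            )
            return src.copy(), None, enc
        raise TypeError(f"cannot use {type(src).__name__} as a pretrained core")

    @property
    def sigma_(self) -> np.ndarray:
        """Effective per-gene scale (strictly positive by construction)."""
        return _softplus(self.rho_) + SIGMA_FLOOR

    def core_checksum(self) -> str:
        """Bitwise digest of every pretrained tensor (freeze verification)."""
        return self.core_params_.checksum()

    def scale_basal(self, g0: np.ndarray) -> np.ndarray:
        """The scaling layer g0' = (g0 − μ)/σ."""
        return (np.asarray(g0, dtype=np.float64) - self.mu_) / self.sigma_

    # -- forward/backward --------------------------------------------------

    def _forward(self, g0, feats, training=False, rng=None):
        g0p = (g0 - self.mu_) / self.sigma_
        gc, cache = forward_batch(self.core_params_, g0p, feats, self.core_ppi_, training, rng)
        D = cache["D"]
        if self.fusion == "concat":
            u = np.concatenate([gc, D, g0p], axis=1)
        elif self.fusion == "sum":
            u = gc + D + g0p
        else:
            raise ValueError(f"unknown fusion {self.fusion!r}")
        act, _ = ACTIVATIONS[self.activation]
        hh_pre = u @ self.head_tensors_["Wh1"]
        hh = act(hh_pre)
        yhat = (hh @ self.head_tensors_["Wh2"])[:, 0]
        cache.update({"g0_raw": g0, "g0p": g0p, "u": u, "hh_pre": hh_pre, "hh": hh})
        return yhat, cache

    def _backward(self, cache, d_yhat):
        _, dact = ACTIVATIONS[self.activation]
        n = self.core_params_.n_genes
        Wh1, Wh2 = self.head_tensors_["Wh1"], self.head_tensors_["Wh2"]
        dy = d_yhat[:, None]
        head_grads = {
            "Wh2": cache["hh"].T @ dy,
        }
        dhh = dy @ Wh2.T
        dhh_pre = dhh * dact(cache["hh_pre"], cache["hh"])
        head_grads["Wh1"] = cache["u"].T @ dhh_pre
        du = dhh_pre @ Wh1.T
        if self.fusion == "concat":
            d_gc, d_D, d_g0p_head = du[:, :n], du[:, n : 2 * n], du[:, 2 * n :]
        else:
            d_gc = d_D = d_g0p_head = du
        core_grads, d_g0p_core = backward_batch(self.core_params_, cache, d_gc, d_D_extra=d_D)
        d_g0p = d_g0p_core + d_g0p_head
        inv_s = 1.0 / self.sigma_
        centered = cache["g0_raw"] - self.mu_
        d_mu = -(d_g0p * inv_s).sum(axis=0)
        d_rho = (d_g0p * centered * (-(inv_s**2))).sum(axis=0) * _sigmoid(self.rho_)
        scale_grads = {"mu": d_mu, "rho": d_rho}
        return head_grads, scale_grads, core_grads

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        """Fit on (basal profiles, conditions) → log IC50 values."""
        g0, conds = _unpack_X(X)
        y = np.asarray(y, dtype=np.float64).ravel()
        if y.size != g0.shape[0]:
            raise ValueError("one target per record required")
        n, n_genes = g0.shape
        rng = np.random.default_rng(self.seed)
        self.core_params_, self.core_ppi_, self.encoder_ = self._resolve_core(n_genes, rng)
        if self.core_params_.n_genes != n_genes:
            raise ValueError(
                f"checkpoint gene universe ({self.core_params_.n_genes}) does not "
                f"match input ({n_genes})"
            )

        if self.init_scaling_from_data:
            self.mu_ = g0.mean(axis=0)
            self.rho_ = _softplus_inv(np.maximum(g0.std(axis=0), 10 * SIGMA_FLOOR))
        else:
            self.mu_ = np.zeros(n_genes)
            self.rho_ = _softplus_inv(np.ones(n_genes))

        u_len = 3 * n_genes if self.fusion == "concat" else n_genes
        self.head_tensors_ = {
            "Wh1": rng.normal(0.0, np.sqrt(2.0 / u_len), (u_len, self.head_hidden)),
            "Wh2": rng.normal(0.0, np.sqrt(1.0 / self.head_hidden), (self.head_hidden, 1)),
        }

        feats = condition_features(conds, self.encoder_)
        perm = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if train_idx.size == 0:
            raise ValueError("no training samples left after validation split")

        frozen = self.freeze_pretrained
        checksum_before = self.core_params_.checksum()
        opt = _Adam(self.learning_rate)
        best_val, best_state, best_epoch, since_best = np.inf, None, -1, 0
        history: dict[str, list[float]] = {
            "train_rmse": [], "val_rmse": [], "val_pcc": []
        }
        for epoch in range(self.max_epochs):
            order = train_idx[rng.permutation(train_idx.size)]
            sq_err, n_seen = 0.0, 0
            for b, lo in enumerate(range(0, order.size, self.batch_size)):
                idx = order[lo : lo + self.batch_size]
                sub = {k: v[idx] for k, v in feats.items()}
                yhat, cache = self._forward(g0[idx], sub, training=True, rng=rng)
                diff = yhat - y[idx]
                loss = float(np.mean(diff**2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite fine-tuning loss at epoch {epoch}, batch {b}"
                    )
                sq_err += float((diff**2).sum())
                n_seen += idx.size
                d_yhat = 2.0 * diff / diff.size
                head_grads, scale_grads, core_grads = self._backward(cache, d_yhat)
                scaling = {"mu": self.mu_, "rho": self.rho_}
                tensors = {**self.head_tensors_, **scaling}
                grads = {**head_grads, **scale_grads}
                if not frozen:
                    tensors.update(self.core_params_.tensors)
                    grads.update(core_grads)
                opt.step(tensors, grads)
                self.mu_, self.rho_ = scaling["mu"], scaling["rho"]
            val_pred = self._predict_eval(g0[val_idx], {k: v[val_idx] for k, v in feats.items()})
            val_rmse = float(np.sqrt(np.mean((val_pred - y[val_idx]) ** 2)))
            if val_idx.size >= 2 and np.std(val_pred) > 0 and np.std(y[val_idx]) > 0:
                val_pcc = float(np.corrcoef(val_pred, y[val_idx])[0, 1])
            else:
                val_pcc = float("nan")
            history["train_rmse"].append(float(np.sqrt(sq_err / n_seen)))
            history["val_rmse"].append(val_rmse)
            history["val_pcc"].append(val_pcc)
            if val_rmse < best_val:
                best_val, best_epoch, since_best = val_rmse, epoch, 0
                best_state = (
                    self.mu_.copy(),
                    self.rho_.copy(),
                    {k: v.copy() for k, v in self.head_tensors_.items()},
                    None if frozen else self.core_params_.copy(),
                )
            else:
                since_best += 1
                if since_best > self.patience:
                    break
        self.mu_, self.rho_, self.head_tensors_, core = best_state
        if core is not None:
            self.core_params_ = core
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.best_val_rmse_ = float(best_val)
        self.n_genes_ = n_genes
        if frozen:
            assert self.core_params_.checksum() == checksum_before
        return self

    def _predict_eval(self, g0, feats, chunk: int = 256) -> np.ndarray:
        out = np.empty(g0.shape[0])
        for lo in range(0, g0.shape[0], chunk):
            hi = lo + chunk
            sub = {k: v[lo:hi] for k, v in feats.items()}
            out[lo:hi], _ = self._forward(g0[lo:hi], sub)
        return out

    def predict(self, X) -> np.ndarray:
        g0, conds = _unpack_X(X)
        feats = condition_features(conds, self.encoder_)
        return self._predict_eval(g0, feats)

    def predict_perturbed(self, X) -> np.ndarray:
        """Perturbed-profile predictions of the (scaled) core, for interpretation."""
        g0, conds = _unpack_X(X)
        feats = condition_features(conds, self.encoder_)
        out = np.empty_like(np.asarray(g0, dtype=np.float64))
        for lo in range(0, g0.shape[0], 256):
            hi = lo + 256
            sub = {k: v[lo:hi] for k, v in feats.items()}
            g0p = self.scale_basal(g0[lo:hi])
            out[lo:hi], _ = forward_batch(self.core_params_, g0p, sub, self.core_ppi_)
        return out

    def attention_maps(self, X) -> np.ndarray:
        """Attention matrices of the core on scaled inputs, one per sample."""
        g0, conds = _unpack_X(X)
        if not self.core_params_.attention:
            raise ValueError("the plain additive core has no attention maps")
        feats = condition_features(conds, self.encoder_)
        n = self.core_params_.n_genes
        maps = np.empty((g0.shape[0], n, n))
        for lo in range(0, g0.shape[0], 64):
            hi = lo + 64
            sub = {k: v[lo:hi] for k, v in feats.items()}
            g0p = self.scale_basal(g0[lo:hi])
            _, cache = forward_batch(self.core_params_, g0p, sub, self.core_ppi_)
            maps[lo:hi] = cache["A"]
        return maps

    def score(self, X, y) -> float:
        """Negative MSE on log IC50 (higher is better)."""
        return -mse_loss(self.predict(X), np.asarray(y, dtype=np.float64).ravel())

    # -- persistence -------------------------------------------------------

    def save(self, path, gene_ids: Sequence[str] | None = None) -> None:
        save_checkpoint(
            path,
            self.core_params_,
            gene_ids or [f"g{i}" for i in range(self.n_genes_)],
            self.core_ppi_,
            extra={
                "estimator": {
                    k: v
                    for k, v in self.get_params(deep=False).items()
                    if k != "pretrained"
                },
                "finetuned": True,
                "tensors": {
                    "mu": self.mu_,
                    "rho": self.rho_,
                    "Wh1": self.head_tensors_["Wh1"],
                    "Wh2": self.head_tensors_["Wh2"],
                },
            },
        )

    @classmethod
    def load(cls, path) -> "IC50Regressor":
        params, gene_ids, a_ppi, extra = load_checkpoint(path)
        est = cls(**extra.get("estimator", {}))
        est.core_params_ = params
        est.core_ppi_ = a_ppi
        est.encoder_ = resolve_structure_encoder(
            {"type": "fingerprint", "bits": params.fp_bits, "radius": params.fp_radius}
        )
        tensors = extra["tensors"]
        est.mu_ = tensors["mu"]
        est.rho_ = tensors["rho"]
        est.head_tensors_ = {"Wh1": tensors["Wh1"], "Wh2": tensors["Wh2"]}
        est.n_genes_ = params.n_genes
        est.history_ = {}
        return est


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# --------------------------------------------------------------------------
# functional wrappers over the estimators

def pretrain(
    triples: Sequence[tuple[np.ndarray, np.ndarray, ChemicalCondition]],
    ppi=None,
    gene_ids: Sequence[str] | None = None,
    **config,
) -> PerturbationNetwork:
    """Train the perturbation network on (g0, gc, condition) triples."""
    if len(triples) == 0:
        raise ValueError("need at least one training triple")
    g0 = np.stack([t[0] for t in triples])
    gc = np.stack([t[1] for t in triples])
    conds = [t[2] for t in triples]
    model = PerturbationNetwork(**config)
    return model.fit((g0, conds), gc, ppi=ppi, gene_ids=gene_ids)


def response_arrays(
    records: Sequence[DrugResponseRecord],
    basal: ExpressionMatrix,
    dose_uM: float = DEFAULT_DOSE_UM,
    time_h: float = DEFAULT_TIME_H,
) -> tuple[np.ndarray, list[ChemicalCondition], np.ndarray]:
    """Resolve response records against a basal matrix into model inputs."""
    index = {s: i for i, s in enumerate(basal.sample_ids)}
    missing = sorted({r.cell_id for r in records} - set(index))
    if missing:
        raise KeyError(f"cell ids without a basal profile: {missing[:10]}")
    g0 = np.stack([basal.values[index[r.cell_id]] for r in records])
    conds = [ChemicalCondition(r.smiles, dose_uM, time_h) for r in records]
    y = np.array([r.log_ic50 for r in records])
    return g0, conds, y


def finetune(
    records: Sequence[DrugResponseRecord],
    basal: ExpressionMatrix,
    pretrained=None,
    **config,
) -> IC50Regressor:
    """Fine-tune a (frozen) pretrained core to log IC50 prediction."""
    model = IC50Regressor(pretrained=pretrained, **config)
    g0, conds, y = response_arrays(records, basal, model.dose_uM, model.time_h)
    return model.fit((g0, conds), y)
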
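"""Sparsely-connected autoencoder (SCA) and its variational variant (vSCA).

The model is a single-hidden-layer autoencoder whose encoder and decoder
weights are constrained by a binary genes x features connectivity mask:
a latent node receives input only from (and reconstructs only) the genes
it is biologically linked to, so each hidden unit is interpretable as the
activity of one transcription factor, miRNA, kinase or gene signature.

Masking is enforced by elementwise multiplication of the gradient with
the mask at every optimization step, with masked weights initialized to
zero — masked positions therefore hold *exactly* zero throughout
training, which is the testable contract.  Optimization is plain
mini-batch Adam (lr 0.01, beta1 0.9, beta2 0.999, eps 1e-8, no decay) on
the mean-squared reconstruction error, with ReLU on the hidden layer and
a linear output layer.  The implementation is pure numpy: the network is
one masked matmul each way, so hand-written backpropagation is both
transparent and bit-reproducible given a seed.

The variational variant adds a masked log-variance head, samples the
latent vector by reparameterization and penalizes the posterior with a
weighted KL divergence against a standard normal; its ``encode`` returns
the posterior means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .knowledge import ConnectivityMask
from .preprocess import CountsMatrix

logger = logging.getLogger("scamine")


@dataclass
class TrainingConfig:
    """Adam/loss hyperparameters; the optimizer defaults are fixed by the method."""

    learning_rate: float = 0.01
    beta_1: float = 0.9
    beta_2: float = 0.999
    epsilon: float = 1e-8
    decay: float = 0.0
    epochs: int = 100
    batch_size: int | None = None  # None -> min(64, n_cells)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class LatentMatrix:
    """Cells x features latent activations from one trained model."""

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    run_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError("latent shape does not match id lists")

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.cell_ids, columns=self.feature_ids).to_csv(
            path, sep="\t", index_label="cell"
        )


@dataclass
class TrainedModel:
    """Weights of a fitted SCA/vSCA plus the mask that shaped them."""

    encoder_weights: np.ndarray  # genes x features
    encoder_bias: np.ndarray
    decoder_weights: np.ndarray  # features x genes
    decoder_bias: np.ndarray
    mask: ConnectivityMask
    variant: str
    final_loss: float
    seed: int
    config: TrainingConfig
    # vSCA only: masked log-variance head
    logvar_weights: np.ndarray | None = None
    logvar_bias: np.ndarray | None = None
    kl_weight: float = 0.0
    loss_history: list[float] = field(default_factory=list)
    kl_history: list[float] = field(default_factory=list)
    final_latent: np.ndarray | None = None

    def save(self, path: str | Path) -> None:
        arrays = dict(
            encoder_weights=self.encoder_weights,
            encoder_bias=self.encoder_bias,
            decoder_weights=self.decoder_weights,
            decoder_bias=self.decoder_bias,
            mask=self.mask.mask,
        )
        if self.logvar_weights is not None:
            arrays["logvar_weights"] = self.logvar_weights
            arrays["logvar_bias"] = self.logvar_bias
        meta = dict(
            variant=self.variant,
            final_loss=self.final_loss,
            seed=self.seed,
            kl_weight=self.kl_weight,
            genes=self.mask.genes,
            features=self.mask.features,
            config=asdict(self.config),
        )
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["_meta"]).decode())
            mask = ConnectivityMask(meta["genes"], meta["features"], z["mask"])
            return TrainedModel(
                encoder_weights=z["encoder_weights"],
                encoder_bias=z["encoder_bias"],
                decoder_weights=z["decoder_weights"],
                decoder_bias=z["decoder_bias"],
                mask=mask,
                variant=meta["variant"],
                final_loss=meta["final_loss"],
                seed=meta["seed"],
                config=TrainingConfig(**meta["config"]),
                logvar_weights=z["logvar_weights"] if "logvar_weights" in z else None,
                logvar_bias=z["logvar_bias"] if "logvar_bias" in z else None,
                kl_weight=meta["kl_weight"],
            )


def _check_inputs(counts: CountsMatrix, mask: ConnectivityMask) -> None:
    if counts.gene_ids != mask.genes:
        raise ValueError(
            "counts gene rows do not match the connectivity-mask gene order"
        )
    if counts.n_cells < 2:
        raise ValueError("training needs at least 2 cells")
    if len(mask.features) < 2:
        raise ValueError("training needs at least 2 latent features")


def _glorot_masked(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform Glorot-style init with per-feature fan computed on the mask."""
    fan = mask.sum(axis=0).astype(np.float64)  # per latent node
    limit = np.sqrt(6.0 / (2.0 * np.maximum(fan, 1.0)))
    w = rng.uniform(-1.0, 1.0, size=mask.shape) * limit[None, :]
    return w * mask


def _sign_correct(We: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Flip encoder units whose mean pre-activation starts negative.

    Expression inputs are non-negative, so a hidden unit whose masked
    weight vector points away from the data mean is dead under ReLU at
    initialization and receives zero gradient forever.  Flipping the sign
    of such units (a measure-preserving change to the symmetric init
    distribution) guarantees every latent node starts alive.
    """
    mean_pre = X.mean(axis=0) @ We
    return We * np.where(mean_pre < 0, -1.0, 1.0)[None, :]


class _Adam:
    def __init__(self, params: list[np.ndarray], cfg: TrainingConfig) -> None:
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.cfg = cfg

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        c = self.cfg
        lr = c.learning_rate / (1.0 + c.decay * self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= c.beta_1
            m += (1 - c.beta_1) * g
            v *= c.beta_2
            v += (1 - c.beta_2) * g * g
            mhat = m / (1 - c.beta_1 ** self.t)
            vhat = v / (1 - c.beta_2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + c.epsilon)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def train_sca(
    counts: CountsMatrix, mask: ConnectivityMask, config: TrainingConfig | None = None
) -> TrainedModel:
    """Fit a masked autoencoder on cells-as-samples reconstruction.

    ``counts`` must already be restricted to the mask's gene rows (genes
    without any knowledge edge are excluded from input and output).
    Results are bit-reproducible given identical inputs and seed.
    """
    config = config or TrainingConfig()
    _check_inputs(counts, mask)
    M = mask.mask.astype(np.float64)
    X = np.ascontiguousarray(counts.values.T)  # cells x genes
    n_cells = X.shape[0]
    rng = np.random.default_rng(config.seed)

    We = _sign_correct(_glorot_masked(M, rng), X)
    be = np.zeros(M.shape[1])
    # near-zero decoder + mean output bias: training starts at the mean
    # predictor, so hidden units are never silenced to absorb decoder noise
    # and only grow along directions that reduce residual error
    Wd = _glorot_masked(M.T, rng) * 0.01
    bd = X.mean(axis=0)
    params = [We, be, Wd, bd]
    opt = _Adam(params, config)

    batch = config.batch_size or min(64, n_cells)
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n_cells)
        epoch_loss = 0.0
        for start in range(0, n_cells, batch):
            idx = order[start : start + batch]
            xb = X[idx]
            hpre = xb @ We + be
            h = _relu(hpre)
            y = h @ Wd + bd
            resid = y - xb
            loss = float(np.mean(resid ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            dy = 2.0 * resid / resid.size
            gWd = (h.T @ dy) * M.T
            gbd = dy.sum(axis=0)
            dh = dy @ Wd.T
            dhpre = dh * (hpre > 0)
            gWe = (xb.T @ dhpre) * M
            gbe = dhpre.sum(axis=0)
            opt.step(params, [gWe, gbe, gWd, gbd])
        history.append(epoch_loss / n_cells)

    h_final = _relu(X @ We + be)
    final_loss = float(np.mean((h_final @ Wd + bd - X) ** 2))
    return TrainedModel(
        encoder_weights=We,
        encoder_bias=be,
        decoder_weights=Wd,
        decoder_bias=bd,
        mask=mask,
        variant="sca",
        final_loss=final_loss,
        seed=config.seed,
        config=config,
        loss_history=history,
        final_latent=h_final,
    )


def train_vsca(
    counts: CountsMatrix,
    mask: ConnectivityMask,
    config: TrainingConfig | None = None,
    kl_weight: float = 1e-3,
) -> TrainedModel:
    """Fit the variational variant: masked mean/log-variance encoder heads,
    reparameterized sampling, loss = MSE + kl_weight * KL(q || N(0, I))."""
    config = config or TrainingConfig()
    if kl_weight < 0:
        raise ValueError("kl_weight must be non-negative")
    _check_inputs(counts, mask)
    M = mask.mask.astype(np.float64)
    X = np.ascontiguousarray(counts.values.T)
    n_cells = X.shape[0]
    rng = np.random.default_rng(config.seed)

    Wm = _sign_correct(_glorot_masked(M, rng), X)
    bm = np.zeros(M.shape[1])
    Wv = _glorot_masked(M, rng) * 0.01  # start near unit posterior variance
    bv = np.zeros(M.shape[1])
    Wd = _glorot_masked(M.T, rng) * 0.01
    bd = X.mean(axis=0)
    params = [Wm, bm, Wv, bv, Wd, bd]
    opt = _Adam(params, config)

    batch = config.batch_size or min(64, n_cells)
    history: list[float] = []
    kl_history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n_cells)
        epoch_loss = 0.0
        epoch_kl = 0.0
        for start in range(0, n_cells, batch):
            idx = order[start : start + batch]
            xb = X[idx]
            b = len(idx)
            mu = xb @ Wm + bm
            logvar = np.clip(xb @ Wv + bv, -15.0, 15.0)
            eps = rng.standard_normal(mu.shape)
            std = np.exp(0.5 * logvar)
            z = mu + std * eps
            y = z @ Wd + bd
            resid = y - xb
            mse = float(np.mean(resid ** 2))
            kl = float(np.mean(np.sum(-0.5 * (1 + logvar - mu ** 2 - np.exp(logvar)), axis=1)))
            loss = mse + kl_weight * kl
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss * b
            epoch_kl += kl * b

            dy = 2.0 * resid / resid.size
            gWd = (z.T @ dy) * M.T
            gbd = dy.sum(axis=0)
            dz = dy @ Wd.T
            dmu = dz + kl_weight * mu / b
            dlogvar = dz * eps * 0.5 * std + kl_weight * (-0.5) * (1 - np.exp(logvar)) / b
            gWm = (xb.T @ dmu) * M
            gbm = dmu.sum(axis=0)
            gWv = (xb.T @ dlogvar) * M
            gbv = dlogvar.sum(axis=0)
            opt.step(params, [gWm, gbm, gWv, gbv, gWd, gbd])
        history.append(epoch_loss / n_cells)
        kl_history.append(epoch_kl / n_cells)

    mu_final = X @ Wm + bm
    logvar_final = np.clip(X @ Wv + bv, -15.0, 15.0)
    mse_final = float(np.mean((mu_final @ Wd + bd - X) ** 2))
    kl_final = float(
        np.mean(np.sum(-0.5 * (1 + logvar_final - mu_final ** 2 - np.exp(logvar_final)), axis=1))
    )
    return TrainedModel(
        encoder_weights=Wm,
        encoder_bias=bm,
        decoder_weights=Wd,
        decoder_bias=bd,
        mask=mask,
        variant="vsca",
        final_loss=mse_final + kl_weight * kl_final,
        seed=config.seed,
        config=config,
        logvar_weights=Wv,
        logvar_bias=bv,
        kl_weight=kl_weight,
        loss_history=history,
        kl_history=kl_history,
        final_latent=mu_final,
    )


def encode(model: TrainedModel, counts: CountsMatrix, run_id: int = 0) -> LatentMatrix:
    """Project cells into the latent space of a trained model.

    SCA applies the hidden-layer ReLU; vSCA returns the posterior means
    (no sampling at encode time), so encoding is deterministic.
    """
    if counts.gene_ids != model.mask.genes:
        missing = [g for g in model.mask.genes if g not in set(counts.gene_ids)]
        raise ValueError(
            f"counts genes do not match model mask; missing {missing[:10]!r}"
            + ("..." if len(missing) > 10 else "")
        )
    X = counts.values.T
    h = X @ model.encoder_weights + model.encoder_bias
    if model.variant == "sca":
        h = _relu(h)
    return LatentMatrix(
        values=h,
        feature_ids=list(model.mask.features),
        cell_ids=list(counts.cell_ids),
        run_id=run_id,
    )
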
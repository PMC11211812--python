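"""Stochastic training of the branched model on a perturbation screen.

The loss matches the decoder head: mean squared error for scalar
outcomes, heteroscedastic Gaussian negative log-likelihood for perturbed
expression profiles. Gradients are hand-derived reverse-mode through the
encoder -> active branches -> aggregation -> decoder composition. The
Gaussian head's variance is handled on the log scale throughout: the
floor sigma^2 >= eps is applied as a clamp of the pre-activation at
log(eps), whose gradient is zero where the clamp binds.

A validation split for early stopping is carved from the training fold
(never from the test fold); all randomness — validation split, batch
shuffling, dropout masks — flows from ``TrainConfig.seed``, so two runs
with identical inputs produce identical parameters.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import PerturbScreen
from .model import BranchedModel
from .nn import Adam

__all__ = ["TrainConfig", "TrainReport", "train"]


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 128
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    early_stop_patience: int = 30
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.early_stop_patience) <= 0:
            raise ValueError("epochs, batch_size and patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")


@dataclass
class TrainReport:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0
    reduction: str = "mean"
    checksum: str = ""


def _param_checksum(model: BranchedModel) -> str:
    h = hashlib.sha256()
    for p in model.parameters():
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()[:16]


def _forward_backward(
    model: BranchedModel,
    X: np.ndarray,
    T: np.ndarray,
    D: np.ndarray | None,
    Dmask: np.ndarray | None,
    Y: np.ndarray,
    drop_mask: np.ndarray | None,
) -> float:
    """One mean-reduced loss evaluation with gradient accumulation."""
    cfg = model.config
    d = cfg.latent_dim
    e, enc_cache = model.encoder.forward(X)
    if drop_mask is not None:
        e = e * drop_mask
    z = np.zeros((X.shape[0], d))
    branch_caches: dict[int, tuple] = {}
    for k in range(model.n_branches):
        w = T[:, k]
        if not np.any(w != 0):
            continue
        if cfg.dosed:
            feats = model.transform_dose(D[:, k], Dmask[:, k])
            inp = np.hstack([e, feats])
        else:
            inp = e
        fk, cache = model.branches[k].forward(inp)
        branch_caches[k] = cache
        z += w[:, None] * fk
    raw, dec_cache = model.decoder.forward(z)

    n = X.shape[0]
    if cfg.head == "scalar":
        resid = raw[:, 0] - Y
        loss = float(np.mean(resid**2))
        g_raw = (2.0 / n) * resid[:, None]
    else:
        p = cfg.output_dim
        mu = raw[:, :p]
        logv = np.maximum(raw[:, p:], np.log(cfg.variance_floor))
        resid = mu - Y
        inv = np.exp(-logv)
        loss = float(np.mean(0.5 * (logv + resid**2 * inv)))
        scale = 1.0 / (n * p)
        g_mu = scale * resid * inv
        g_logv = scale * 0.5 * (1.0 - resid**2 * inv)
        g_logv = np.where(raw[:, p:] > np.log(cfg.variance_floor), g_logv, 0.0)
        g_raw = np.hstack([g_mu, g_logv])

    g_z = model.decoder.backward(g_raw, dec_cache)
    g_e = np.zeros_like(e)
    for k, cache in branch_caches.items():
        g_inp = model.branches[k].backward(T[:, k][:, None] * g_z, cache)
        g_e += g_inp[:, :d]
    if drop_mask is not None:
        g_e = g_e * drop_mask
    model.encoder.backward(g_e, enc_cache)
    return loss


def _eval_loss(model: BranchedModel, X, T, D, Dmask, Y) -> float:
    from .losses import gaussian_nll, mse_loss

    if model.config.head == "scalar":
        pred = model.forward(X, T, D, Dmask)
        return mse_loss(pred, Y)
    pred = model.forward(X, T, D, Dmask)
    return gaussian_nll(pred.mu, pred.sigma2, Y, reduction="mean")


def train(
    model: BranchedModel,
    screen: PerturbScreen,
    train_idx: Sequence[int] | None,
    cfg: TrainConfig,
) -> tuple[BranchedModel, TrainReport]:
    """Fit the model on the training-fold triplets of a screen.

    ``train_idx`` restricts training to a cross-validation fold (None
    uses every triplet); test-fold rows are never touched. Returns the
    model with its best-validation-loss parameters restored, plus the
    loss traces. Raises on a non-finite loss (divergence).
    """
    if (screen.outcome_kind == "scalar") != (model.config.head == "scalar"):
        raise ValueError("screen outcome kind does not match model head")
    idx = np.arange(screen.n_samples) if train_idx is None else np.asarray(list(train_idx), int)
    sub = screen.subset(idx)
    X = sub.control_matrix
    T = sub.design.matrix
    D = sub.design.dosages if sub.design.is_dosed else None
    Dmask = sub.design.dose_mask if sub.design.is_dosed else None
    Y = sub.outcome_matrix if sub.outcome_kind == "profile" else np.asarray(sub.outcomes)

    if model.config.dosed and model.dose_lo is None and model.dose_levels is None:
        model.fit_dose_transform(D[Dmask])

    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = int(round(cfg.val_fraction * n))
    val, tr = perm[:n_val], perm[n_val:]
    if tr.size == 0:
        raise ValueError("no training samples left after validation split")

    opt = Adam(
        model.parameters(),
        model.gradients(),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    report = TrainReport()
    best = np.inf
    best_params = [p.copy() for p in model.parameters()]
    patience = 0
    dropout = model.config.dropout

    def take(A, i):
        return None if A is None else A[i]

    for epoch in range(cfg.epochs):
        order = rng.permutation(tr.size)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, tr.size, cfg.batch_size):
            b = tr[order[start : start + cfg.batch_size]]
            model.zero_grad()
            drop = None
            if dropout > 0:
                drop = (rng.random((b.size, model.config.latent_dim)) >= dropout) / (1 - dropout)
            loss = _forward_backward(
                model, X[b], T[b], take(D, b), take(Dmask, b), Y[b], drop
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            opt.step()
            epoch_loss += loss
            n_batches += 1
        report.train_losses.append(epoch_loss / n_batches)

        if val.size:
            vloss = _eval_loss(model, X[val], T[val], take(D, val), take(Dmask, val), Y[val])
        else:
            vloss = report.train_losses[-1]
        if not np.isfinite(vloss):
            raise RuntimeError(f"training diverged: non-finite validation loss at epoch {epoch}")
        report.val_losses.append(vloss)

        if vloss < best - 1e-12:
            best = vloss
            best_epoch = epoch
            for dst, src in zip(best_params, model.parameters()):
                dst[...] = src
            report.best_epoch = epoch
            patience = 0
        else:
            patience += 1
            if patience >= cfg.early_stop_patience:
                break

    for dst, src in zip(model.parameters(), best_params):
        dst[...] = src
    report.checksum = _param_checksum(model)
    return model, report
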
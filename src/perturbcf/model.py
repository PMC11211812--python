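"""Branched counterfactual perturbation model.

The model maps an unperturbed profile x and an intervention vector
t = (t_1, ..., t_K) to the predicted perturbed outcome

    y_hat = d( sum_k t_k * f_k(e(x)) )

with a shared encoder e: R^p -> R^d, one latent-to-latent branch f_k per
known perturbation, and a shared decoder d. Active branches are summed
linearly in latent space; the decoder then captures nonlinear
combinatorial effects. Branches with no active sample in a batch are
never evaluated; because inactive samples enter the sum with an exact
zero weight, skipping is bitwise-equivalent to evaluating every branch.

Two decoder heads are supported: a scalar head (drug-synergy screens)
and a heteroscedastic Gaussian head predicting a per-gene mean and
variance, with the variance floored at a small epsilon for numerical
stability. Dosage, when present, is standardized and fed to the first
layer of the corresponding branch only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .nn import MLP

__all__ = ["ModelConfig", "BranchedModel", "GaussianPrediction"]

#: default variance floor for the Gaussian head
VARIANCE_FLOOR = 1e-6


@dataclass
class ModelConfig:
    """Architecture and initialization choices.

    ``latent_dim`` is the width d of the shared latent space;
    ``encoder_widths``/``branch_widths``/``decoder_widths`` are hidden
    layer sizes (may be empty for a single affine map). ``head`` selects
    the decoder output: ``scalar`` for a single response value,
    ``gaussian`` for per-gene mean and variance. ``variance_floor`` is
    the epsilon applied as sigma^2 = max(sigma^2, eps). ``dose_transform``
    maps raw doses to the branch input feature: ``log10_minmax`` (default,
    numeric, supports interpolation to unseen doses) rescales log10(dose)
    to [0, 1] over the training doses; ``categorical`` one-hot encodes
    the distinct training dose levels.
    """

    input_dim: int
    output_dim: int
    latent_dim: int = 16
    encoder_widths: list[int] = field(default_factory=lambda: [64])
    branch_widths: list[int] = field(default_factory=list)
    decoder_widths: list[int] = field(default_factory=lambda: [64])
    activation: str = "elu"
    head: Literal["scalar", "gaussian"] = "gaussian"
    variance_floor: float = VARIANCE_FLOOR
    dosed: bool = False
    dose_transform: Literal["log10_minmax", "categorical"] = "log10_minmax"
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class GaussianPrediction:
    """Per-gene predictive mean and (floored) variance."""

    mu: np.ndarray
    sigma2: np.ndarray


class BranchedModel:
    """Encoder, K perturbation branches and a shared decoder."""

    def __init__(
        self,
        config: ModelConfig,
        perturbation_ids: Sequence[str],
        dose_levels: Sequence[float] | None = None,
    ) -> None:
        self.config = config
        self.perturbation_ids = [str(p) for p in perturbation_ids]
        if len(set(self.perturbation_ids)) != len(self.perturbation_ids):
            raise ValueError("perturbation ids must be unique")
        self.dose_lo: float | None = None
        self.dose_hi: float | None = None
        self.dose_levels: list[float] | None = None
        if config.dosed and dose_levels is not None:
            self.fit_dose_transform(dose_levels)

        rng = np.random.default_rng(config.seed)
        streams = rng.spawn(2 + len(self.perturbation_ids))
        d = config.latent_dim
        self.encoder = MLP(
            [config.input_dim, *config.encoder_widths, d], config.activation, streams[0]
        )
        branch_in = d + self._n_dose_features()
        self.branches = [
            MLP([branch_in, *config.branch_widths, d], config.activation, s)
            for s in streams[2:]
        ]
        out = 1 if config.head == "scalar" else 2 * config.output_dim
        self.decoder = MLP([d, *config.decoder_widths, out], config.activation, streams[1])

    # -- dose handling ------------------------------------------------------

    def _n_dose_features(self) -> int:
        if not self.config.dosed:
            return 0
        if self.config.dose_transform == "categorical":
            if self.dose_levels is None:
                raise ValueError("categorical dose transform needs dose_levels at build time")
            return len(self.dose_levels)
        return 1

    def fit_dose_transform(self, doses: Sequence[float]) -> None:
        """Calibrate the dose feature on the training doses (all > 0)."""
        doses = np.asarray([float(x) for x in doses], dtype=float)
        doses = doses[doses > 0]
        if doses.size == 0:
            raise ValueError("no positive doses to calibrate on")
        if self.config.dose_transform == "categorical":
            self.dose_levels = sorted(set(doses.tolist()))
        else:
            logd = np.log10(doses)
            self.dose_lo = float(logd.min())
            self.dose_hi = float(logd.max())

    def transform_dose(self, dose: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Raw doses -> branch input features; unmasked entries map to 0.

        Under ``log10_minmax`` the undosed sentinel and the smallest
        training dose both map to feature 0.0 (the declared reference
        value). Returns (n, n_dose_features).
        """
        dose = np.asarray(dose, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if self.config.dose_transform == "categorical":
            feats = np.zeros((dose.shape[0], len(self.dose_levels)))
            for i in np.flatnonzero(mask):
                level = float(dose[i])
                try:
                    j = self.dose_levels.index(level)
                except ValueError:
                    raise ValueError(f"unseen dose level {level} under categorical transform")
                feats[i, j] = 1.0
            return feats
        if self.dose_lo is None:
            raise ValueError("dose transform not calibrated; call fit_dose_transform")
        span = self.dose_hi - self.dose_lo
        feats = np.zeros((dose.shape[0], 1))
        idx = np.flatnonzero(mask)
        if idx.size:
            logd = np.log10(dose[idx])
            feats[idx, 0] = (logd - self.dose_lo) / span if span > 0 else 0.0
        return feats

    # -- forward pieces -----------------------------------------------------

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Shared latent embedding of unperturbed profiles (batch or single)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"profile has {x.shape[1]} features, model expects {self.config.input_dim}"
            )
        return self.encoder(x)

    def branch_apply(
        self, h: np.ndarray, k: int, dose: np.ndarray | float | None = None
    ) -> np.ndarray:
        """Apply branch k to latent vectors, with optional dosage."""
        if not 0 <= k < self.n_branches:
            raise IndexError(f"branch index {k} out of range")
        h = np.atleast_2d(np.asarray(h, dtype=float))
        if self.config.dosed:
            if dose is None:
                feats = np.zeros((h.shape[0], self._n_dose_features()))
            else:
                dose_arr = np.full(h.shape[0], float(dose)) if np.isscalar(dose) else np.asarray(dose, float)
                feats = self.transform_dose(dose_arr, np.ones(h.shape[0], bool))
            h = np.hstack([h, feats])
        elif dose is not None:
            raise ValueError("dose given but the model is not dose-conditioned")
        return self.branches[k](h)

    def aggregate(self, branch_outputs: dict[int, np.ndarray], weights: np.ndarray) -> np.ndarray:
        """Latent effect z = sum_k w_k * f_k(e(x)) over supplied branches.

        ``branch_outputs`` maps branch index -> (n, d) output; branches
        absent from the dict must have zero weight everywhere. An all-zero
        weight row (empty dict allowed) yields the zero vector — the
        empty-sum convention — so decoding z = 0 gives the model's
        control-state prediction.
        """
        weights = np.atleast_2d(np.asarray(weights, dtype=float))
        d = self.config.latent_dim
        z = np.zeros((weights.shape[0], d))
        for k in sorted(branch_outputs):
            z += weights[:, k][:, None] * branch_outputs[k]
        return z

    def decode_scalar(self, z: np.ndarray) -> np.ndarray:
        if self.config.head != "scalar":
            raise ValueError("model head is not scalar")
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return self.decoder(z)[:, 0]

    def decode_gaussian(self, z: np.ndarray) -> GaussianPrediction:
        if self.config.head != "gaussian":
            raise ValueError("model head is not gaussian")
        z = np.atleast_2d(np.asarray(z, dtype=float))
        raw = self.decoder(z)
        p = self.config.output_dim
        mu = raw[:, :p]
        sigma2 = np.maximum(np.exp(raw[:, p:]), self.config.variance_floor)
        return GaussianPrediction(mu, sigma2)

    def _latent(
        self,
        x: np.ndarray,
        t: np.ndarray,
        dose: np.ndarray | None = None,
        dose_mask: np.ndarray | None = None,
        skip_zero_branches: bool = True,
    ) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        t = np.atleast_2d(np.asarray(t, dtype=float))
        if t.shape != (x.shape[0], self.n_branches):
            raise ValueError("treatment matrix shape does not match batch and branch count")
        e = self.encode(x)
        z = np.zeros((x.shape[0], self.config.latent_dim))
        if self.config.dosed:
            if dose is None:
                dose = np.zeros_like(t)
                dose_mask = np.zeros(t.shape, dtype=bool)
            elif dose_mask is None:
                dose_mask = np.asarray(dose) > 0
        elif dose is not None:
            raise ValueError("dose given but the model is not dose-conditioned")
        for k in range(self.n_branches):
            w = t[:, k]
            if skip_zero_branches and not np.any(w != 0):
                continue  # inactive branch: never evaluated
            if self.config.dosed:
                feats = self.transform_dose(dose[:, k], dose_mask[:, k])
                fk = self.branches[k](np.hstack([e, feats]))
            else:
                fk = self.branches[k](e)
            z += w[:, None] * fk
        return z

    def forward(
        self,
        x: np.ndarray,
        t: np.ndarray,
        dose: np.ndarray | None = None,
        dose_mask: np.ndarray | None = None,
        skip_zero_branches: bool = True,
    ):
        """Full prediction for a batch (or single) of triplets.

        Returns a scalar vector or a :class:`GaussianPrediction`
        depending on the configured head. ``skip_zero_branches=False``
        forces the naive evaluation of every branch (identical result;
        used for equivalence checks).
        """
        single = np.asarray(x).ndim == 1
        z = self._latent(x, t, dose, dose_mask, skip_zero_branches)
        if self.config.head == "scalar":
            out = self.decode_scalar(z)
            return out[0] if single else out
        pred = self.decode_gaussian(z)
        if single:
            return GaussianPrediction(pred.mu[0], pred.sigma2[0])
        return pred

    # -- parameters / serialization -----------------------------------------

    def modules(self) -> list[MLP]:
        return [self.encoder, *self.branches, self.decoder]

    def parameters(self) -> list[np.ndarray]:
        return [p for m in self.modules() for p in m.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for m in self.modules() for g in m.gradients()]

    def zero_grad(self) -> None:
        for m in self.modules():
            m.zero_grad()

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: config, branch order and all tensors."""
        arrays: dict[str, np.ndarray] = {}
        for mi, m in enumerate(self.modules()):
            for li, (W, b) in enumerate(zip(m.W, m.b)):
                arrays[f"m{mi}_W{li}"] = W
                arrays[f"m{mi}_b{li}"] = b
        meta = {
            "schema": 1,
            "config": asdict(self.config),
            "perturbation_ids": self.perturbation_ids,
            "dose_lo": self.dose_lo,
            "dose_hi": self.dose_hi,
            "dose_levels": self.dose_levels,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "BranchedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("schema") != 1:
                raise ValueError("unknown checkpoint schema")
            cfg = ModelConfig(**meta["config"])
            model = cls.__new__(cls)
            model.config = cfg
            model.perturbation_ids = list(meta["perturbation_ids"])
            model.dose_lo = meta["dose_lo"]
            model.dose_hi = meta["dose_hi"]
            model.dose_levels = meta["dose_levels"]
            rng = np.random.default_rng(cfg.seed)
            streams = rng.spawn(2 + len(model.perturbation_ids))
            d = cfg.latent_dim
            model.encoder = MLP([cfg.input_dim, *cfg.encoder_widths, d], cfg.activation, streams[0])
            branch_in = d + model._n_dose_features()
            model.branches = [
                MLP([branch_in, *cfg.branch_widths, d], cfg.activation, s) for s in streams[2:]
            ]
            out = 1 if cfg.head == "scalar" else 2 * cfg.output_dim
            model.decoder = MLP([d, *cfg.decoder_widths, out], cfg.activation, streams[1])
            for mi, m in enumerate(model.modules()):
                for li in range(len(m.W)):
                    m.W[li][...] = data[f"m{mi}_W{li}"]
                    m.b[li][...] = data[f"m{mi}_b{li}"]
        return model
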
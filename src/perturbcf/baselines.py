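"""Reference predictors the branched model is compared against.

``linear_baseline`` averages the observed mean responses of the single
perturbations making up a combination — the prediction of a world with
purely additive-in-outcome effects. ``linear_branch_average`` is the
ablation of the trained model that evaluates each branch separately and
averages the decoded predictions in outcome space, removing the
decoder's nonlinear combination of effects (the full model aggregates
in latent space *before* decoding). ``random_baseline`` predicts the
control centroid (or a randomly drawn training profile) and serves as
the denominator reference for normalized MSE.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np

from .data import PerturbScreen
from .model import BranchedModel, GaussianPrediction

__all__ = ["linear_baseline", "linear_branch_average", "random_baseline"]


def linear_baseline(
    screen: PerturbScreen,
    combo: Iterable[str],
    train_idx: Sequence[int] | None = None,
) -> np.ndarray:
    """Mean of the single-perturbation mean outcome profiles of ``combo``."""
    if screen.outcome_kind != "profile":
        raise ValueError("linear baseline is defined for profile outcomes")
    combo = [str(c) for c in combo]
    if not combo:
        raise ValueError("empty combination")
    idx = range(screen.n_samples) if train_idx is None else train_idx
    rows_by_single: dict[str, list[int]] = {c: [] for c in combo}
    for i in idx:
        key = screen.design.combo_key(i)
        if len(key) == 1:
            (p,) = key
            if p in rows_by_single:
                rows_by_single[p].append(i)
    profiles = []
    Y = screen.outcome_matrix
    for c in combo:
        if not rows_by_single[c]:
            raise ValueError(f"no single-perturbation observations for {c!r}")
        profiles.append(Y[rows_by_single[c]].mean(axis=0))
    return np.mean(profiles, axis=0)


def linear_branch_average(
    model: BranchedModel,
    x: np.ndarray,
    combo: Iterable[str],
    doses: dict[str, float] | None = None,
    mode: Literal["additive", "mean"] = "additive",
):
    """Combine single-branch predictions in outcome space.

    Each member of ``combo`` is evaluated with a one-hot treatment
    vector (its dose attached if given); unlike the full forward pass,
    the decoder never sees the summed latent effect, so any nonlinear
    combination of effects is removed. ``mode="additive"`` (default)
    adds the single effects on top of the control-state prediction,
    y0 + sum_k (y_k - y0) with y0 = decode(z=0) — for an affine decoder
    this equals the full forward pass exactly. ``mode="mean"`` is the
    plain average of the single-branch predictions.
    """
    combo = [str(c) for c in combo]
    if not combo:
        raise ValueError("empty combination")
    K = model.n_branches
    preds = []
    for c in combo:
        if c not in model.perturbation_ids:
            raise ValueError(f"unknown perturbation: {c!r}")
        k = model.perturbation_ids.index(c)
        t = np.zeros(K)
        t[k] = 1.0
        dose = None
        mask = None
        if model.config.dosed:
            dose = np.zeros((1, K))
            mask = np.zeros((1, K), dtype=bool)
            if doses and c in doses:
                dose[0, k] = doses[c]
                mask[0, k] = True
        preds.append(model.forward(np.atleast_2d(x), t[None, :], dose, mask))
    if mode == "additive":
        t0 = np.zeros((1, K))
        dose0 = np.zeros((1, K)) if model.config.dosed else None
        mask0 = np.zeros((1, K), dtype=bool) if model.config.dosed else None
        y0 = model.forward(np.atleast_2d(x), t0, dose0, mask0)
        if model.config.head == "scalar":
            return float(y0 + np.sum([pp - y0 for pp in preds]))
        mu = y0.mu + np.sum([pp.mu - y0.mu for pp in preds], axis=0)
        sigma2 = np.mean([pp.sigma2 for pp in preds], axis=0)
        return GaussianPrediction(mu[0], sigma2[0])
    if mode != "mean":
        raise ValueError(f"unknown mode: {mode}")
    if model.config.head == "scalar":
        return float(np.mean(preds))
    mu = np.mean([pp.mu for pp in preds], axis=0)
    sigma2 = np.mean([pp.sigma2 for pp in preds], axis=0)
    return GaussianPrediction(mu[0], sigma2[0])


def random_baseline(
    screen: PerturbScreen,
    seed: int = 0,
    strategy: Literal["control_centroid", "sampled"] = "control_centroid",
) -> np.ndarray:
    """Uninformed reference prediction.

    Default: the control centroid (mean unperturbed profile). The
    ``sampled`` option draws one training outcome profile under ``seed``.
    """
    if screen.controls.n_samples == 0:
        raise ValueError("screen has no control profiles")
    if strategy == "control_centroid":
        return screen.controls.values.mean(axis=0)
    if strategy == "sampled":
        if screen.outcome_kind != "profile":
            raise ValueError("sampled baseline needs profile outcomes")
        rng = np.random.default_rng(seed)
        i = int(rng.integers(0, screen.n_samples))
        return screen.outcome_matrix[i].copy()
    raise ValueError(f"unknown strategy: {strategy}")
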
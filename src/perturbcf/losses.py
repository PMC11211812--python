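"""Training objectives: mean squared error and heteroscedastic Gaussian NLL."""

from __future__ import annotations

from typing import Literal

import numpy as np

__all__ = ["mse_loss", "gaussian_nll"]


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """(1/N) sum_i (pred_i - target_i)^2."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.mean((pred - target) ** 2))


def gaussian_nll(
    mu: np.ndarray,
    sigma2: np.ndarray,
    target: np.ndarray,
    reduction: Literal["sum", "mean"] = "sum",
) -> float:
    """Negative Gaussian log-likelihood (constant dropped).

    sum_{i,j} 1/2 ( log sigma2_ij + (mu_ij - y_ij)^2 / sigma2_ij ),
    optionally divided by the number of terms (``reduction="mean"``).
    The per-gene variance lets the model down-weight noisy genes.
    """
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    target = np.asarray(target, dtype=float)
    if mu.shape != target.shape or sigma2.shape != mu.shape:
        raise ValueError("mu, sigma2 and target must share a shape")
    if mu.size == 0:
        raise ValueError("empty input")
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be strictly positive (variance floor violated)")
    terms = 0.5 * (np.log(sigma2) + (mu - target) ** 2 / sigma2)
    return float(terms.sum() if reduction == "sum" else terms.mean())
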
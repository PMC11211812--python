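"""Evaluation metrics for reconstructed perturbation responses.

All profile metrics are computed on the mean post-perturbation profile
of a condition (not per cell). Correlations of an all-constant vector
are undefined and reported as missing (None) rather than zero. The
"effect" scope subtracts the control mean from both prediction and
truth before correlating, so a method is not rewarded for reproducing
the control background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ScopeMetrics", "EvalReport", "top_k_degs", "eval_condition"]


@dataclass
class ScopeMetrics:
    pcc: float | None
    scc: float | None
    r2: float
    mse: float
    nmse: float | None
    effect_pcc: float | None


@dataclass
class EvalReport:
    all_genes: ScopeMetrics
    top_k: ScopeMetrics
    k: int


def top_k_degs(perturbed_mean: np.ndarray, control_mean: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k genes with largest |mean shift| vs. control.

    Ranked by absolute difference of means; ties keep input order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    diff = np.abs(np.asarray(perturbed_mean, float) - np.asarray(control_mean, float))
    if k > diff.size:
        raise ValueError(f"k={k} exceeds gene count {diff.size}")
    return np.argsort(-diff, kind="stable")[:k]


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float | None:
    if np.std(a) == 0 or np.std(b) == 0:
        return None
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    return float(stats.spearmanr(a, b).statistic)


def _scope(pred: np.ndarray, truth: np.ndarray, control: np.ndarray, base: np.ndarray | None) -> ScopeMetrics:
    mse = float(np.mean((pred - truth) ** 2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    r2 = 1.0 - float(np.sum((pred - truth) ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    nmse = None
    if base is not None:
        base_mse = float(np.mean((base - truth) ** 2))
        nmse = mse / base_mse if base_mse > 0 else float("inf")
    return ScopeMetrics(
        pcc=_corr(pred, truth, "pearson"),
        scc=_corr(pred, truth, "spearman"),
        r2=r2,
        mse=mse,
        nmse=nmse,
        effect_pcc=_corr(pred - control, truth - control, "pearson"),
    )


def eval_condition(
    pred: np.ndarray,
    truth: np.ndarray,
    control_mean: np.ndarray,
    k: int = 50,
    baseline: np.ndarray | None = None,
) -> EvalReport:
    """Score one held-out condition.

    ``pred`` is the predicted mean profile, ``truth`` the observed cells
    of the condition (one row per cell; a single profile is accepted),
    ``baseline`` the reference prediction whose error normalizes the MSE
    (normalized MSE = MSE(pred) / MSE(baseline), both on the same gene
    scope). Top-k genes are ranked on the *true* mean shift vs. control.
    """
    pred = np.asarray(pred, float)
    truth = np.atleast_2d(np.asarray(truth, float))
    if truth.shape[0] < 1:
        raise ValueError("truth must hold at least one cell")
    truth_mean = truth.mean(axis=0)
    control_mean = np.asarray(control_mean, float)
    if not (pred.shape == truth_mean.shape == control_mean.shape):
        raise ValueError("pred, truth and control_mean must share gene dimension")

    deg = top_k_degs(truth_mean, control_mean, min(k, pred.size))
    base = None if baseline is None else np.asarray(baseline, float)
    return EvalReport(
        all_genes=_scope(pred, truth_mean, control_mean, base),
        top_k=_scope(pred[deg], truth_mean[deg], control_mean[deg], None if base is None else base[deg]),
        k=int(min(k, pred.size)),
    )
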
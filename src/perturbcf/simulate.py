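"""Ground-truth simulator of perturbation screens.

The generator emulates the structure of the screens the model is built
for — single-cell expression screens with combinatorial perturbations,
dose-varying chemical screens, and scalar drug-synergy screens — with
every generative parameter known, so that recovery can be tested.

Generative model for expression screens. Each cell carries a latent
state u ~ N(0, cell_latent_sd^2 I) in an L-dimensional factor space.
Perturbation k shifts the latent state by delta_k (scaled by a Hill
dose-response factor when the screen is dosed); a pair (k, l) may add a
nonlinear interaction gamma_kl * (delta_k ⊙ delta_l) on top of the two
single shifts. The latent state maps to log-scale expression through a
fixed loading matrix and an elementwise softplus — smooth and positive,
so even purely additive latent effects combine non-additively in
expression space — plus gene-wise Gaussian noise. With gamma = 0
everywhere the latent effects are exactly additive, which is the null
the linear ablation should match.

Because measurements are destructive, each perturbed cell's "control"
is generated from the same latent state with independent noise: the
counterfactual pairing is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import ExpressionMatrix, PerturbScreen, TreatmentDesign
from .proxy import GeneSetAnnotation

__all__ = [
    "SynthConfig",
    "Condition",
    "SynthTruth",
    "simulate_screen",
    "simulate_synergy_screen",
    "gmt_from_truth",
]


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _hill(d: float, ec50: float, slope: float) -> float:
    if d <= 0:
        return 0.0
    return d**slope / (d**slope + ec50**slope)


@dataclass
class SynthConfig:
    """Study conditions of a simulated screen.

    Defaults describe a small combinatorial knockout screen: 200 genes
    driven by 10 latent factors, 8 perturbations observed singly plus
    ``n_pairs`` pair conditions, 200 cells per condition. Effect and
    noise magnitudes are set so single-perturbation effects are clearly
    detectable at that depth (per-gene latent shift of order 1 on the
    log-expression scale against gene noise of order 0.3).

    ``interaction_pairs`` lists (k, l, gamma) triples; if None, every
    simulated pair interacts with strength ``gamma``. ``dose_levels``
    switches to a dose-response screen (single perturbations only, one
    condition per perturbation x dose, Hill-shaped latent shifts).
    ``pathway_blocks`` partitions perturbation indices into pathway
    blocks; within a block the latent shift directions are correlated
    (shared block direction plus ``block_within_sd`` individual
    deviation), which is what the gene-set proxy scheme exploits.
    """

    n_genes: int = 200
    n_latent_true: int = 10
    n_perturbations: int = 8
    n_cells_per_condition: int = 200
    n_pairs: int = 12
    effect_scale: float = 1.0
    gamma: float = 1.0
    interaction_pairs: list[tuple[int, int, float]] | None = None
    dose_levels: list[float] | None = None
    hill_ec50: float | None = None
    hill_slope: float = 1.5
    noise_sd: float | np.ndarray = 0.3
    cell_latent_sd: float = 0.2
    pathway_blocks: list[list[int]] | None = None
    block_within_sd: float = 0.4
    # synergy-screen specifics
    n_cell_lines: int = 20
    synergy_noise_sd: float = 0.5
    include_control_condition: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_latent_true, self.n_perturbations, self.n_cells_per_condition) <= 0:
            raise ValueError("counts must be positive")
        if np.any(np.asarray(self.noise_sd) <= 0):
            raise ValueError("noise_sd must be positive")


@dataclass
class Condition:
    perts: tuple[str, ...]
    doses: tuple[float, ...] | None
    rows: np.ndarray
    true_mean: np.ndarray


@dataclass
class SynthTruth:
    loading: np.ndarray  # L x genes
    baseline: np.ndarray  # gene offsets
    delta: np.ndarray  # K x L latent shifts
    gamma: dict[tuple[int, int], float]
    noise_sd: np.ndarray
    control_mean: np.ndarray
    conditions: list[Condition] = field(default_factory=list)
    pathway_blocks: list[list[int]] | None = None
    perturbation_ids: list[str] = field(default_factory=list)
    synergy: dict = field(default_factory=dict)


def _structure(cfg: SynthConfig, rng: np.random.Generator):
    """Fixed generative parameters shared by all cells of a screen."""
    L, K, G = cfg.n_latent_true, cfg.n_perturbations, cfg.n_genes
    W = rng.standard_normal((L, G)) / np.sqrt(L)
    b = rng.normal(1.0, 1.0, size=G)
    if cfg.pathway_blocks is not None:
        delta = np.zeros((K, L))
        for block in cfg.pathway_blocks:
            direction = rng.standard_normal(L)
            direction /= np.linalg.norm(direction)
            for k in block:
                v = direction + cfg.block_within_sd * rng.standard_normal(L) / np.sqrt(L)
                delta[k] = v / np.linalg.norm(v)
    else:
        delta = rng.standard_normal((K, L))
        delta /= np.linalg.norm(delta, axis=1, keepdims=True)
    delta *= cfg.effect_scale * np.sqrt(L)
    noise = np.asarray(cfg.noise_sd, dtype=float)
    if noise.ndim == 0:
        # gene-wise heteroscedastic noise around the configured level
        noise = noise * rng.uniform(0.5, 1.5, size=G)
    return W, b, delta, noise


def _pairs_and_gamma(cfg: SynthConfig, rng: np.random.Generator):
    K = cfg.n_perturbations
    if cfg.interaction_pairs is not None:
        pairs = [(k, l) for k, l, _ in cfg.interaction_pairs]
        gamma = {(min(k, l), max(k, l)): g for k, l, g in cfg.interaction_pairs}
        return pairs, gamma
    all_pairs = [(k, l) for k in range(K) for l in range(k + 1, K)]
    if cfg.n_pairs > len(all_pairs):
        raise ValueError("n_pairs exceeds the number of distinct pairs")
    chosen = rng.choice(len(all_pairs), size=cfg.n_pairs, replace=False)
    pairs = [all_pairs[i] for i in sorted(chosen)]
    gamma = {p: cfg.gamma for p in pairs}
    return pairs, gamma


def simulate_screen(cfg: SynthConfig) -> tuple[PerturbScreen, SynthTruth]:
    """Simulate an expression-outcome screen with known ground truth."""
    rng = np.random.default_rng(cfg.seed)
    struct_rng, cell_rng = rng.spawn(2)
    W, b, delta, noise = _structure(cfg, struct_rng)
    K, L, G = cfg.n_perturbations, cfg.n_latent_true, cfg.n_genes
    pert_ids = [f"g{k}" for k in range(K)]

    # condition table: (active indices, dose per active index or None)
    conds: list[tuple[tuple[int, ...], tuple[float, ...] | None]] = []
    gamma: dict[tuple[int, int], float] = {}
    if cfg.include_control_condition:
        # untreated condition (t = 0): anchors the decoder's control-state
        # prediction at z = 0
        conds.append(((), None))
    if cfg.dose_levels is not None:
        for k in range(K):
            for d in cfg.dose_levels:
                conds.append(((k,), (float(d),)))
    else:
        for k in range(K):
            conds.append(((k,), None))
        pairs, gamma = _pairs_and_gamma(cfg, struct_rng)
        for k, l in pairs:
            conds.append(((k, l), None))

    ec50 = cfg.hill_ec50
    if cfg.dose_levels is not None and ec50 is None:
        ec50 = float(np.exp(np.mean(np.log(cfg.dose_levels))))  # geometric mid-range

    n = cfg.n_cells_per_condition
    n_total = n * len(conds)
    design = np.zeros((n_total, K))
    dosage = np.zeros((n_total, K))
    dose_mask = np.zeros((n_total, K), dtype=bool)
    X = np.empty((n_total, G))
    Y = np.empty((n_total, G))
    truth_conditions: list[Condition] = []

    row = 0
    for ci, (active, doses) in enumerate(conds):
        shift = np.zeros(L)
        for ai, k in enumerate(active):
            w = _hill(doses[ai], ec50, cfg.hill_slope) if doses is not None else 1.0
            shift += w * delta[k]
        if doses is None and len(active) == 2:
            k, l = active
            g = gamma.get((min(k, l), max(k, l)), 0.0)
            shift = shift + g * (delta[k] * delta[l]) / np.sqrt(L)
        true_mean = _softplus(shift @ W + b)

        rows = np.arange(row, row + n)
        u = cell_rng.normal(0.0, cfg.cell_latent_sd, size=(n, L))
        X[rows] = _softplus(u @ W + b) + cell_rng.normal(0.0, noise, size=(n, G))
        Y[rows] = _softplus((u + shift) @ W + b) + cell_rng.normal(0.0, noise, size=(n, G))
        for ai, k in enumerate(active):
            design[rows, k] = 1.0
            if doses is not None:
                dosage[rows, k] = doses[ai]
                dose_mask[rows, k] = True
        truth_conditions.append(
            Condition(tuple(pert_ids[k] for k in active), doses, rows, true_mean)
        )
        row += n

    sample_ids = [f"cell{i}" for i in range(n_total)]
    controls = ExpressionMatrix(X, [f"gene{j}" for j in range(G)], sample_ids)
    outcomes = ExpressionMatrix(Y, controls.gene_ids, [f"pert_{s}" for s in sample_ids])
    td = TreatmentDesign(
        design,
        pert_ids,
        dosage if cfg.dose_levels is not None else None,
        dose_mask if cfg.dose_levels is not None else None,
    )
    screen = PerturbScreen(controls, td, outcomes)
    truth = SynthTruth(
        loading=W,
        baseline=b,
        delta=delta,
        gamma=gamma,
        noise_sd=noise,
        control_mean=_softplus(b),
        conditions=truth_conditions,
        pathway_blocks=cfg.pathway_blocks,
        perturbation_ids=pert_ids,
    )
    return screen, truth


def simulate_synergy_screen(cfg: SynthConfig) -> tuple[PerturbScreen, SynthTruth]:
    """Scalar-outcome analogue: cell lines x drug pairs with known synergy.

    The outcome of pair (k, l) on cell line c is
    y = f(x_c) + s_k + s_l + gamma_kl + noise, with f linear in the cell
    line's true latent factors, s_k additive drug main effects, and
    gamma_kl the ground-truth synergy of the pair.
    """
    rng = np.random.default_rng(cfg.seed)
    struct_rng, cell_rng = rng.spawn(2)
    W, b, _, noise = _structure(cfg, struct_rng)
    K, L, G = cfg.n_perturbations, cfg.n_latent_true, cfg.n_genes
    pert_ids = [f"drug{k}" for k in range(K)]
    pairs, gamma = _pairs_and_gamma(cfg, struct_rng)

    beta = struct_rng.standard_normal(L)
    s = struct_rng.normal(0.0, 2.0, size=K)

    u = cell_rng.standard_normal((cfg.n_cell_lines, L))
    lines = _softplus(u @ W + b) + cell_rng.normal(0.0, noise, size=(cfg.n_cell_lines, G))
    controls = ExpressionMatrix(
        lines, [f"gene{j}" for j in range(G)], [f"line{c}" for c in range(cfg.n_cell_lines)]
    )

    rows_design = []
    pairing = []
    y = []
    cond_rows: dict[tuple[int, int], list[int]] = {p: [] for p in pairs}
    analytic_mean: dict[tuple[int, int], dict[int, float]] = {p: {} for p in pairs}
    i = 0
    for k, l in pairs:
        g = gamma[(k, l)]
        for c in range(cfg.n_cell_lines):
            t = np.zeros(K)
            t[k] = t[l] = 1.0
            rows_design.append(t)
            pairing.append(c)
            mean = float(beta @ u[c]) + s[k] + s[l] + g
            analytic_mean[(k, l)][c] = mean
            y.append(mean + cell_rng.normal(0.0, cfg.synergy_noise_sd))
            cond_rows[(k, l)].append(i)
            i += 1

    design = TreatmentDesign(np.array(rows_design), pert_ids)
    screen = PerturbScreen(controls, design, np.array(y), np.array(pairing))
    truth = SynthTruth(
        loading=W,
        baseline=b,
        delta=np.zeros((K, L)),
        gamma=gamma,
        noise_sd=noise,
        control_mean=_softplus(b),
        perturbation_ids=pert_ids,
        synergy={
            "main_effects": s,
            "beta": beta,
            "cell_latents": u,
            "condition_rows": {p: np.array(r) for p, r in cond_rows.items()},
            "analytic_means": analytic_mean,
        },
    )
    return screen, truth


def gmt_from_truth(truth: SynthTruth, n_shared: int = 6, n_private: int = 2) -> tuple[GeneSetAnnotation, dict[str, list[str]]]:
    """Pathway annotation matching the simulated block structure.

    Perturbation targets in the same block share ``n_shared`` pathways
    and each carries ``n_private`` private ones, so same-block pairs get
    Jaccard n_shared / (n_shared + 2 * n_private) and cross-block pairs
    get 0. Returns the annotation and the pathway -> genes dict (GMT
    orientation, writable with :func:`perturbcf.proxy.write_gmt`).
    """
    if truth.pathway_blocks is None:
        raise ValueError("truth has no pathway blocks")
    gene_sets: dict[str, list[str]] = {}
    for bi, block in enumerate(truth.pathway_blocks):
        members = [truth.perturbation_ids[k] for k in block]
        for m in range(n_shared):
            gene_sets[f"BLOCK{bi}_PW{m}"] = list(members)
        for gene in members:
            for m in range(n_private):
                gene_sets[f"PRIV_{gene}_{m}"] = [gene]
    return GeneSetAnnotation.from_gene_sets(gene_sets), gene_sets
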
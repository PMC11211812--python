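"""Data model and I/O for perturbation screens.

A screen is a collection of training triplets: an unperturbed (control)
expression profile, the intervention applied — a multi-hot vector over the
K known perturbations, optionally with per-perturbation dosages — and the
recorded outcome, which is either a scalar response (e.g. a precomputed
drug-synergy score) or a perturbed expression profile.

Expression values are assumed to be normalized and log-transformed before
they enter this module; no count normalization is performed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TreatmentDesign",
    "PerturbScreen",
    "AlignmentError",
    "load_screen",
    "write_screen",
    "filter_genes",
    "select_hvg",
    "pair_controls",
]

#: sentinel stored in the dosage matrix where no dose was recorded; a
#: presence mask distinguishes it from a true zero dose.
DOSE_SENTINEL = 0.0


class AlignmentError(ValueError):
    """Raised when identifiers cannot be aligned across input files."""


@dataclass
class ExpressionMatrix:
    """samples x genes matrix of log-scale expression with row/column ids."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.gene_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, index: Sequence[int]) -> "ExpressionMatrix":
        index = list(index)
        return ExpressionMatrix(
            self.values[:, index],
            [self.gene_ids[i] for i in index],
            list(self.sample_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class TreatmentDesign:
    """samples x K intervention weights, optionally with dosages.

    Observed (non-proxy) entries are 0/1 multi-hot indicators of which of
    the K perturbations were applied; proxy-augmented rows may carry
    fractional weights in [0, 1]. ``dosages`` holds raw dose values where
    ``dose_mask`` is True and the sentinel 0.0 elsewhere.
    """

    matrix: np.ndarray
    perturbation_ids: list[str]
    dosages: np.ndarray | None = None
    dose_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.perturbation_ids = [str(p) for p in self.perturbation_ids]
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.perturbation_ids):
            raise ValueError("design matrix shape does not match perturbation_ids")
        if np.isnan(self.matrix).any():
            raise ValueError("design matrix contains missing values")
        if (self.matrix < 0).any() or (self.matrix > 1).any():
            raise ValueError("treatment weights must lie in [0, 1]")
        if self.dosages is not None:
            self.dosages = np.asarray(self.dosages, dtype=float)
            if self.dosages.shape != self.matrix.shape:
                raise ValueError("dosage matrix shape must match design matrix")
            if self.dose_mask is None:
                self.dose_mask = self.dosages != DOSE_SENTINEL
            else:
                self.dose_mask = np.asarray(self.dose_mask, dtype=bool)
                if self.dose_mask.shape != self.matrix.shape:
                    raise ValueError("dose mask shape must match design matrix")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_perturbations(self) -> int:
        return self.matrix.shape[1]

    @property
    def is_dosed(self) -> bool:
        return self.dosages is not None

    def combo_key(self, i: int) -> frozenset[str]:
        """Set of perturbation ids active (weight > 0) in row ``i``."""
        active = np.flatnonzero(self.matrix[i] > 0)
        return frozenset(self.perturbation_ids[k] for k in active)


@dataclass
class PerturbScreen:
    """Aligned controls, treatment design and outcomes of one screen.

    ``pairing[i]`` is the row of ``controls`` providing the unperturbed
    profile for outcome ``i``; outcomes are either a 1-D scalar vector
    (synergy-score screens) or an :class:`ExpressionMatrix` of perturbed
    profiles with genes matching ``controls``.
    """

    controls: ExpressionMatrix
    design: TreatmentDesign
    outcomes: np.ndarray | ExpressionMatrix
    pairing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.design.n_samples
        if self.pairing is None:
            if self.controls.n_samples != n:
                raise ValueError("pairing required when controls do not align 1:1")
            self.pairing = np.arange(n)
        self.pairing = np.asarray(self.pairing, dtype=int)
        if self.pairing.shape != (n,):
            raise ValueError("pairing must map every design row to one control row")
        if (self.pairing < 0).any() or (self.pairing >= self.controls.n_samples).any():
            raise ValueError("pairing index out of range")
        if isinstance(self.outcomes, ExpressionMatrix):
            if self.outcomes.n_samples != n:
                raise ValueError("outcome profile count does not match design rows")
            if self.outcomes.gene_ids != self.controls.gene_ids:
                raise AlignmentError("outcome genes differ from control genes")
        else:
            self.outcomes = np.asarray(self.outcomes, dtype=float)
            if self.outcomes.shape != (n,):
                raise ValueError("scalar outcomes must be one value per design row")
            if np.isnan(self.outcomes).any():
                raise ValueError("outcomes contain missing values")

    @property
    def n_samples(self) -> int:
        return self.design.n_samples

    @property
    def outcome_kind(self) -> Literal["scalar", "profile"]:
        return "profile" if isinstance(self.outcomes, ExpressionMatrix) else "scalar"

    @property
    def control_matrix(self) -> np.ndarray:
        """Per-triplet control profiles, pairing applied (n_samples x genes)."""
        return self.controls.values[self.pairing]

    @property
    def outcome_matrix(self) -> np.ndarray:
        if self.outcome_kind != "profile":
            raise ValueError("screen has scalar outcomes")
        return self.outcomes.values  # type: ignore[union-attr]

    def subset(self, index: Sequence[int]) -> "PerturbScreen":
        """Screen restricted to the given triplet rows (controls untouched)."""
        index = np.asarray(list(index), dtype=int)
        design = TreatmentDesign(
            self.design.matrix[index],
            self.design.perturbation_ids,
            None if self.design.dosages is None else self.design.dosages[index],
            None if self.design.dose_mask is None else self.design.dose_mask[index],
        )
        if self.outcome_kind == "profile":
            out = self.outcomes
            outcomes: np.ndarray | ExpressionMatrix = ExpressionMatrix(
                out.values[index],  # type: ignore[union-attr]
                out.gene_ids,  # type: ignore[union-attr]
                [out.sample_ids[i] for i in index],  # type: ignore[union-attr]
            )
        else:
            outcomes = self.outcomes[index]
        return PerturbScreen(self.controls, design, outcomes, self.pairing[index])


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def _read_expression(path: Path, fmt: str) -> ExpressionMatrix:
    path = Path(path)
    if fmt == "mtx":
        from scipy.io import mmread

        m = mmread(path)
        values = np.asarray(m.toarray() if hasattr(m, "toarray") else m)
        genes = Path(str(path) + ".genes.txt").read_text().split()
        samples = Path(str(path) + ".samples.txt").read_text().split()
        return ExpressionMatrix(values, genes, samples)
    if fmt == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        return ExpressionMatrix(np.asarray(X), list(adata.var_names), list(adata.obs_names))
    df = _read_table(path)
    return ExpressionMatrix(df.to_numpy(), list(df.columns), list(df.index))


def load_screen(
    expr_path: str | Path,
    design_path: str | Path,
    outcome_path: str | Path,
    format: Literal["csv", "tsv", "mtx", "h5ad"] = "csv",
) -> PerturbScreen:
    """Load a screen from an expression file, a design table and outcomes.

    Identifiers are aligned by exact, case-sensitive name, never by
    position. The design table has one row per experiment, a ``control``
    column naming the paired control sample, one 0/1 column per
    perturbation, and optional ``dose:<perturbation>`` columns with raw
    dose values (blank/absent means undosed). Scalar outcome files have an
    ``outcome`` column; profile outcomes are an expression matrix whose
    sample ids match the design rows.
    """
    expr = _read_expression(Path(expr_path), format if format in {"mtx", "h5ad"} else "table")
    design_df = _read_table(Path(design_path))
    if "control" not in design_df.columns:
        raise AlignmentError("design table lacks the required 'control' column")

    control_pos = {s: i for i, s in enumerate(expr.sample_ids)}
    missing = [c for c in design_df["control"] if str(c) not in control_pos]
    if missing:
        raise AlignmentError(f"design references unknown control samples: {sorted(set(map(str, missing)))}")
    pairing = np.array([control_pos[str(c)] for c in design_df["control"]])

    pert_cols = [c for c in design_df.columns if c != "control" and not c.startswith("dose:")]
    matrix = design_df[pert_cols].to_numpy(dtype=float)
    dose_cols = [c for c in design_df.columns if c.startswith("dose:")]
    dosages = None
    mask = None
    if dose_cols:
        dosages = np.zeros_like(matrix)
        mask = np.zeros(matrix.shape, dtype=bool)
        for c in dose_cols:
            name = c[len("dose:"):]
            if name not in pert_cols:
                raise AlignmentError(f"dose column for unknown perturbation: {name}")
            k = pert_cols.index(name)
            col = pd.to_numeric(design_df[c], errors="coerce")
            present = col.notna().to_numpy()
            dosages[present, k] = col.to_numpy()[present]
            mask[:, k] = present

    outcome_path = Path(outcome_path)
    out_df = _read_table(outcome_path)
    if out_df.shape[1] == 1 and out_df.columns[0] == "outcome":
        out_pos = {str(s): i for i, s in enumerate(out_df.index)}
        missing = [s for s in design_df.index if str(s) not in out_pos]
        if missing:
            raise AlignmentError(f"outcomes missing for experiments: {sorted(map(str, missing))}")
        outcomes: np.ndarray | ExpressionMatrix = out_df["outcome"].to_numpy(dtype=float)[
            [out_pos[str(s)] for s in design_df.index]
        ]
    else:
        om = ExpressionMatrix(out_df.to_numpy(), list(out_df.columns), list(out_df.index))
        if set(om.gene_ids) != set(expr.gene_ids):
            raise AlignmentError("outcome genes do not match control genes")
        gene_order = [om.gene_ids.index(g) for g in expr.gene_ids]
        row_pos = {s: i for i, s in enumerate(om.sample_ids)}
        missing = [s for s in design_df.index if str(s) not in row_pos]
        if missing:
            raise AlignmentError(f"outcome profiles missing for experiments: {sorted(map(str, missing))}")
        rows = [row_pos[str(s)] for s in design_df.index]
        outcomes = ExpressionMatrix(
            om.values[np.ix_(rows, gene_order)], expr.gene_ids, [str(s) for s in design_df.index]
        )

    design = TreatmentDesign(matrix, pert_cols, dosages, mask)
    return PerturbScreen(expr, design, outcomes, pairing)


def write_screen(screen: PerturbScreen, out_dir: str | Path) -> dict[str, Path]:
    """Write a screen as CSV files readable by :func:`load_screen`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": out_dir / "controls.csv",
        "design": out_dir / "design.csv",
        "outcome": out_dir / "outcomes.csv",
    }
    screen.controls.to_frame().to_csv(paths["expr"])
    design_df = pd.DataFrame(
        screen.design.matrix,
        columns=screen.design.perturbation_ids,
        index=[f"exp{i}" for i in range(screen.n_samples)],
    )
    design_df.insert(0, "control", [screen.controls.sample_ids[j] for j in screen.pairing])
    if screen.design.is_dosed:
        for k, name in enumerate(screen.design.perturbation_ids):
            col = np.where(screen.design.dose_mask[:, k], screen.design.dosages[:, k], np.nan)
            design_df[f"dose:{name}"] = col
    design_df.to_csv(paths["design"])
    if screen.outcome_kind == "scalar":
        pd.DataFrame({"outcome": screen.outcomes}, index=design_df.index).to_csv(paths["outcome"])
    else:
        om = screen.outcomes
        pd.DataFrame(om.values, index=design_df.index, columns=om.gene_ids).to_csv(paths["outcome"])
    (out_dir / "meta.json").write_text(json.dumps({"outcome_kind": screen.outcome_kind}))
    return paths


# ---------------------------------------------------------------------------
# preprocessing


def filter_genes(expr: ExpressionMatrix, min_expr: float = 1.0, min_var: float = 0.8) -> ExpressionMatrix:
    """Remove genes that are both lowly expressed and low-variance.

    A gene is dropped when its expression never reaches ``min_expr``
    (max over samples below the threshold) AND its variance is below
    ``min_var``; either rule alone keeps the gene. Gene order is preserved.
    """
    values = expr.values
    low_expr = values.max(axis=0) < min_expr
    low_var = values.var(axis=0) < min_var
    keep = ~(low_expr & low_var)
    if not keep.any():
        raise ValueError("gene filter removed every gene")
    return expr.subset_genes(np.flatnonzero(keep))


def select_hvg(expr: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the ``n`` most variable genes; ties broken by input order."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > expr.n_genes:
        raise ValueError(f"n={n} exceeds gene count {expr.n_genes}")
    var = expr.values.var(axis=0)
    # stable sort on -var keeps the earlier-indexed gene on ties
    order = np.argsort(-var, kind="stable")[:n]
    return expr.subset_genes(np.sort(order))


def pair_controls(
    perturbed: ExpressionMatrix,
    controls: ExpressionMatrix,
    strategy: Literal["random_control", "mean_control"] = "random_control",
    seed: int = 0,
) -> tuple[np.ndarray, ExpressionMatrix]:
    """Pair each perturbed cell with an unperturbed control profile.

    Single-cell measurements are destructive, so a cell's own pre-treatment
    profile is never observed; pairing substitutes a plausible control.
    ``random_control`` draws a control cell uniformly per perturbed cell
    (reproducible under ``seed``); ``mean_control`` pairs everything to the
    control centroid. Returns ``(pairing, control_matrix)`` where
    ``pairing[i]`` indexes rows of ``control_matrix``.
    """
    if controls.n_samples == 0:
        raise ValueError("control set is empty")
    if strategy == "random_control":
        rng = np.random.default_rng(seed)
        pairing = rng.integers(0, controls.n_samples, size=perturbed.n_samples)
        return pairing, controls
    if strategy == "mean_control":
        centroid = ExpressionMatrix(
            controls.values.mean(axis=0, keepdims=True), controls.gene_ids, ["control_centroid"]
        )
        return np.zeros(perturbed.n_samples, dtype=int), centroid
    raise ValueError(f"unknown pairing strategy: {strategy}")
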
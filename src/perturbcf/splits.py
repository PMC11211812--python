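"""Cross-validation splits for perturbation screens.

Three schemes, in increasing difficulty of the extrapolation they test:

``random_triplet``
    plain k-fold over triplets; a test combination may also occur in
    training (on other control profiles).
``leave_combination_out``
    distinct multi-perturbation combinations (as sets of perturbation
    ids) are partitioned across folds; every triplet carrying a test
    combination is excluded from that fold's training set, so test
    combinations are never seen in training. Single-perturbation
    conditions stay in training (they anchor the branches).
``leave_perturbation_out``
    whole perturbations are held out. ``seen_mode`` selects what is
    tested: ``0of1`` single applications of a held-out perturbation,
    ``1of2`` pairs with exactly one held-out member, ``0of2`` pairs with
    both members held out. Held-out perturbations appear in no training
    row at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .data import PerturbScreen

__all__ = ["SplitSpec", "make_splits", "validate_split"]

Scheme = Literal["random_triplet", "leave_combination_out", "leave_perturbation_out"]
SeenMode = Literal["0of1", "1of2", "0of2"]


@dataclass
class SplitSpec:
    folds: list[tuple[np.ndarray, np.ndarray]]
    scheme: Scheme
    seen_mode: SeenMode | None = None
    held_out: list[frozenset[str]] = field(default_factory=list)


def _combo_keys(screen: PerturbScreen) -> list[frozenset[str]]:
    return [screen.design.combo_key(i) for i in range(screen.n_samples)]


def make_splits(
    screen: PerturbScreen,
    scheme: Scheme,
    n_folds: int = 5,
    seed: int = 0,
    seen_mode: SeenMode | None = None,
) -> SplitSpec:
    """Generate a reproducible cross-validation split for a screen."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    n = screen.n_samples
    keys = _combo_keys(screen)

    if scheme == "random_triplet":
        perm = rng.permutation(n)
        folds = []
        for chunk in np.array_split(perm, n_folds):
            test = np.sort(chunk)
            train = np.sort(np.setdiff1d(perm, chunk))
            folds.append((train, test))
        return SplitSpec(folds, scheme)

    if scheme == "leave_combination_out":
        combos = sorted({k for k in keys if len(k) >= 2}, key=sorted)
        if not combos:
            combos = sorted({k for k in keys if k}, key=sorted)
        if len(combos) < n_folds:
            raise ValueError(
                f"only {len(combos)} distinct combinations for {n_folds} folds"
            )
        order = rng.permutation(len(combos))
        folds = []
        for chunk in np.array_split(order, n_folds):
            test_keys = {combos[i] for i in chunk}
            test = np.array([i for i in range(n) if keys[i] in test_keys], dtype=int)
            train = np.array([i for i in range(n) if keys[i] not in test_keys], dtype=int)
            folds.append((train, test))
        return SplitSpec(folds, scheme)

    if scheme == "leave_perturbation_out":
        if seen_mode not in ("0of1", "1of2", "0of2"):
            raise ValueError("leave_perturbation_out requires seen_mode 0of1, 1of2 or 0of2")
        perts = screen.design.perturbation_ids
        if len(perts) < n_folds:
            raise ValueError("fewer perturbations than folds")
        order = rng.permutation(len(perts))
        folds = []
        held = []
        for chunk in np.array_split(order, n_folds):
            H = frozenset(perts[i] for i in chunk)
            train = np.array([i for i in range(n) if not (keys[i] & H)], dtype=int)
            if seen_mode == "0of1":
                test_rows = [i for i in range(n) if len(keys[i]) == 1 and keys[i] <= H]
            elif seen_mode == "1of2":
                test_rows = [i for i in range(n) if len(keys[i]) == 2 and len(keys[i] & H) == 1]
            else:  # 0of2
                test_rows = [i for i in range(n) if len(keys[i]) == 2 and keys[i] <= H]
            if test_rows:
                folds.append((train, np.array(test_rows, dtype=int)))
                held.append(H)
        if not folds:
            raise ValueError(f"no fold yields test rows under seen_mode={seen_mode}")
        return SplitSpec(folds, scheme, seen_mode, held)

    raise ValueError(f"unknown scheme: {scheme}")


def validate_split(screen: PerturbScreen, spec: SplitSpec) -> None:
    """Post-hoc re-check of the scheme's disjointness guarantees.

    Raises ``ValueError`` describing the first leak found.
    """
    keys = _combo_keys(screen)
    for f, (train, test) in enumerate(spec.folds):
        if np.intersect1d(train, test).size:
            raise ValueError(f"fold {f}: train and test indices overlap")
        if spec.scheme == "leave_combination_out":
            train_keys = {keys[i] for i in train}
            leaked = {keys[i] for i in test} & train_keys
            if leaked:
                raise ValueError(f"fold {f}: combinations leaked into training: {leaked}")
        elif spec.scheme == "leave_perturbation_out":
            H = spec.held_out[f]
            for i in train:
                if keys[i] & H:
                    raise ValueError(
                        f"fold {f}: held-out perturbation {sorted(keys[i] & H)} in training row {i}"
                    )
            for i in test:
                inter = len(keys[i] & H)
                want = {"0of1": (1, 1), "1of2": (2, 1), "0of2": (2, 2)}[spec.seen_mode]
                if (len(keys[i]), inter) != want:
                    raise ValueError(f"fold {f}: test row {i} does not match seen_mode {spec.seen_mode}")
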
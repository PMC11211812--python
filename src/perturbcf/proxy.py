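"""Gene-set similarity proxies for unobserved perturbations.

A model trains one branch per observed perturbation, so an intervention
never seen in training has no branch of its own. Prior knowledge fills
the gap: genes that share annotated pathways tend to have related
knockout effects, so an unseen gene knockout is represented by a
similarity-weighted mixture of the observed branches. Similarity is the
Jaccard index between the pathway-membership sets of two genes; the
resulting proxy weight vector is L1-normalized (weights sum to 1) and is
added to any observed part of the treatment vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneSetAnnotation",
    "ProxyVector",
    "read_gmt",
    "write_gmt",
    "jaccard",
    "similarity_matrix",
    "build_proxy",
    "effective_treatment",
]


@dataclass
class GeneSetAnnotation:
    """gene id -> set of pathway ids containing that gene."""

    membership: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.membership = {str(g): frozenset(map(str, s)) for g, s in self.membership.items()}

    def sets(self, gene: str) -> frozenset[str]:
        if gene not in self.membership:
            raise KeyError(f"gene not in annotation: {gene!r}")
        return self.membership[gene]

    @classmethod
    def from_gene_sets(cls, gene_sets: Mapping[str, Sequence[str]]) -> "GeneSetAnnotation":
        """Invert pathway -> genes (GMT orientation) to gene -> pathways."""
        membership: dict[str, set[str]] = {}
        for pathway, genes in gene_sets.items():
            for g in genes:
                membership.setdefault(str(g), set()).add(str(pathway))
        return cls({g: frozenset(s) for g, s in membership.items()})


@dataclass
class ProxyVector:
    """Fractional weights over the K observed perturbations standing in
    for one unseen perturbation; ``degenerate`` flags an all-zero vector
    (no pathway overlap with any observed perturbation)."""

    weights: np.ndarray
    target: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("proxy weights must be nonnegative")


def read_gmt(path: str | Path) -> GeneSetAnnotation:
    """Read a GMT file (one line per gene set: name, description, genes)."""
    gene_sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]!r}")
        gene_sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetAnnotation.from_gene_sets(gene_sets)


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name, *map(str, genes)]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def jaccard(j: str, jp: str, ann: GeneSetAnnotation) -> float:
    """|N_j ∩ N_j'| / |N_j ∪ N_j'| — the fraction of shared pathways.

    Defined as 0 when both membership sets are empty.
    """
    a, b = ann.sets(j), ann.sets(jp)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def similarity_matrix(
    genes: Sequence[str],
    ann: GeneSetAnnotation,
    similarity: Callable[[str, str, GeneSetAnnotation], float] = jaccard,
) -> np.ndarray:
    """Symmetric gene x gene similarity matrix (any pairwise similarity)."""
    n = len(genes)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            S[i, j] = S[j, i] = similarity(genes[i], genes[j], ann)
    return S


def build_proxy(
    target: str,
    observed: Sequence[str],
    ann: GeneSetAnnotation,
    similarity: Callable[[str, str, GeneSetAnnotation], float] = jaccard,
) -> ProxyVector:
    """Proxy weights for an unseen perturbation over the observed ones.

    weight_j is proportional to the similarity between the target gene
    and observed perturbation j, normalized to sum to 1. Only observed
    single perturbations serve as anchors (each entry of ``observed`` is
    one perturbation id). If the target shares no pathway with any
    observed perturbation the proxy is all-zero and flagged degenerate;
    the model then falls back to its control-state prediction.
    """
    observed = [str(o) for o in observed]
    if target in observed:
        raise ValueError(f"{target!r} is an observed perturbation; no proxy needed")
    sims = np.array([similarity(target, o, ann) for o in observed], dtype=float)
    total = sims.sum()
    if total == 0:
        return ProxyVector(np.zeros(len(observed)), target, degenerate=True)
    return ProxyVector(sims / total, target)


def effective_treatment(
    observed_row: np.ndarray, proxies: Sequence[ProxyVector]
) -> np.ndarray:
    """Observed multi-hot row plus every proxy's weight vector.

    E.g. observed (1,0,0,0,0) with proxy (0,0.4,0.35,0.25,0) gives the
    effective treatment (1,0.4,0.35,0.25,0); with no proxies the row is
    returned unchanged. Each proxy contributes total mass 1, so a pair
    with both members unseen carries total mass 2.
    """
    row = np.asarray(observed_row, dtype=float).copy()
    for p in proxies:
        if p.weights.shape != row.shape:
            raise ValueError("proxy length does not match treatment vector length")
        row = row + p.weights
    return row
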
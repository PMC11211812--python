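"""Minimal dense neural-network layers with reverse-mode gradients.

The model core is a composition of small multilayer perceptrons. Forward
passes return an explicit cache so that several passes through the same
module (e.g. one branch applied to different sample subsets) can coexist
before their gradients are accumulated. All arithmetic is float64 and
fully deterministic for a fixed seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["MLP", "Adam", "elu", "elu_grad"]


def elu(x: np.ndarray) -> np.ndarray:
    # exp only on the negative part to avoid overflow warnings
    neg = np.minimum(x, 0.0)
    return np.where(x > 0, x, np.expm1(neg))


def elu_grad(x: np.ndarray) -> np.ndarray:
    neg = np.minimum(x, 0.0)
    return np.where(x > 0, 1.0, np.exp(neg))


_ACTIVATIONS = {
    "elu": (elu, elu_grad),
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
}


class MLP:
    """Fully connected network: affine layers with a hidden activation.

    ``widths`` lists the layer sizes from input to output, e.g.
    ``[50, 32, 16]`` is two affine maps with the activation between them;
    the final layer is linear (no activation) unless ``final_activation``.
    """

    def __init__(
        self,
        widths: Sequence[int],
        activation: str = "elu",
        rng: np.random.Generator | None = None,
        final_activation: bool = False,
    ) -> None:
        if len(widths) < 2:
            raise ValueError("MLP needs at least an input and an output width")
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation: {activation}")
        self.widths = list(widths)
        self.activation = activation
        self.final_activation = final_activation
        rng = rng or np.random.default_rng()
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            # fan-in scaled normal init
            self.W.append(rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in))
            self.b.append(np.zeros(fan_out))
        self.gW = [np.zeros_like(w) for w in self.W]
        self.gb = [np.zeros_like(b) for b in self.b]

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        """Return ``(output, cache)``; ``x`` is (batch, widths[0])."""
        act, _ = _ACTIVATIONS[self.activation]
        cache = []
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            pre = h @ W + b
            use_act = i < last or self.final_activation
            cache.append((h, pre, use_act))
            h = act(pre) if use_act else pre
        return h, cache

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, grad_out: np.ndarray, cache: list) -> np.ndarray:
        """Accumulate parameter gradients; return gradient w.r.t. the input."""
        _, dact = _ACTIVATIONS[self.activation]
        g = grad_out
        for i in range(len(self.W) - 1, -1, -1):
            h, pre, use_act = cache[i]
            if use_act:
                g = g * dact(pre)
            self.gW[i] += h.T @ g
            self.gb[i] += g.sum(axis=0)
            g = g @ self.W[i].T
        return g

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    def gradients(self) -> list[np.ndarray]:
        return [*self.gW, *self.gb]

    def zero_grad(self) -> None:
        for g in self.gW:
            g[...] = 0.0
        for g in self.gb:
            g[...] = 0.0

    def set_parameters(self, params: Sequence[np.ndarray]) -> None:
        n = len(self.W)
        for i in range(n):
            self.W[i][...] = params[i]
            self.b[i][...] = params[n + i]


class Adam:
    """Adaptive-moment SGD with decoupled weight decay."""

    def __init__(
        self,
        params: Sequence[np.ndarray],
        grads: Sequence[np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = list(params)
        self.grads = list(grads)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p
            p -= self.lr * update
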
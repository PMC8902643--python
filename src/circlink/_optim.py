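"""Small dense-network primitives: activations, seeded init, Adam.

All models in this package are small fully connected networks trained
full-batch or in mini-batches on matrices with at most a few thousand rows,
so plain NumPy with an explicit Adam loop is both fast enough and exactly
reproducible bit-for-bit under a seed.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid  # noqa: F401  (re-exported)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def uniform_fan_in(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Symmetric uniform init scaled by 1/sqrt(fan_in)."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Adam:
    """Adaptive-moment gradient descent over a list of parameter arrays (in place)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""
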
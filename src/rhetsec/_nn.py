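"""Minimal neural-network primitives used by the trainable models.

All models in this package are small (a linear adapter, two-layer
autoencoders, an MLP cluster head, dynamic-convolution layers) and are
trained with hand-derived gradients on numpy arrays.  Keeping the
primitives here avoids a deep-learning framework dependency and makes
every training run exactly reproducible from a single integer seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "softmax", "relu", "one_hot", "glorot", "he"]


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_out, fan_in))


def he(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_out, fan_in))


class Adam:
    """Adam optimiser over a dict of named parameter arrays (updated in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
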
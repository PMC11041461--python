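"""Minimal numpy neural-net utilities: layers, softmax/cross-entropy, Adam.

The networks in this package are small (a few dense layers); forward and
backward passes are written out explicitly in the model classes, and this
module only supplies the shared primitives.  All initialization is driven by
an explicit ``numpy.random.Generator`` so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np


def glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def init_linear(rng: np.random.Generator, n_in: int, n_out: int) -> dict[str, np.ndarray]:
    return {"W": glorot(rng, n_in, n_out), "b": np.zeros(n_out)}


def linear(params: dict[str, np.ndarray], x: np.ndarray) -> np.ndarray:
    return x @ params["W"] + params["b"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(shifted)
    return ez / ez.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    """Mean negative log-likelihood of integer labels under ``probs``."""
    picked = probs[np.arange(len(labels)), labels]
    return float(-np.log(np.clip(picked, eps, None)).mean())


class Adam:
    """Adam over a flat ``{name: array}`` parameter dictionary."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, grad in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * grad
            self.v[key] = b2 * self.v[key] + (1 - b2) * grad * grad
            m_hat = self.m[key] / (1 - b1**self.t)
            v_hat = self.v[key] / (1 - b2**self.t)
            self.params[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
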
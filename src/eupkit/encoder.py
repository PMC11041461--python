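"""Text embedding contract and the deterministic reference encoder.

Post, news and tweet vectors (``p``, ``e``, ``v``) come from a text encoder;
the classifier additionally consumes a *baseline feature* ``o`` — the
penultimate-layer representation of whatever misinformation baseline the
fusion model is wrapping.  Pretrained transformer encoders plug in through
the same interface, but the reference implementation used throughout the
tests is a feature-hashed bag of lemmas with signed hashing and L2
normalization: download-free, deterministic, and linear before
normalization.
"""

from __future__ import annotations

import hashlib
from typing import Callable, Protocol, Sequence

import numpy as np

from . import _nn
from .uncertainty_model import identity_lemmatizer, tokenize


class TextEncoder(Protocol):
    dim: int

    def embed(self, text: str) -> np.ndarray: ...

    def embed_many(self, texts: Sequence[str]) -> np.ndarray: ...


class HashingEncoder:
    """Signed feature-hashing bag-of-lemmas embedding.

    Each lemma is hashed (salted blake2b, stable across processes) to a
    coordinate and a sign; the sentence vector is the signed count vector,
    L2-normalized.  Empty text maps to the zero vector.
    """

    def __init__(self, dim: int = 256, seed: int = 0,
                 lemmatizer: Callable[[str], str] = identity_lemmatizer) -> None:
        if dim <= 0:
            raise ValueError("dim must be positive")
        self.dim = dim
        self.seed = seed
        self.lemmatizer = lemmatizer
        self._salt = int(seed).to_bytes(8, "little", signed=True)
        self._cache: dict[str, tuple[int, int]] = {}

    def _slot(self, lemma: str) -> tuple[int, int]:
        hit = self._cache.get(lemma)
        if hit is None:
            digest = hashlib.blake2b(lemma.encode("utf-8"), digest_size=8, salt=self._salt).digest()
            value = int.from_bytes(digest, "little")
            hit = (value % self.dim, 1 if value & (1 << 63) else -1)
            self._cache[lemma] = hit
        return hit

    def embed(self, text: str, normalize: bool = True) -> np.ndarray:
        vec = np.zeros(self.dim)
        for token in tokenize(text):
            index, sign = self._slot(self.lemmatizer(token))
            vec[index] += sign
        if normalize:
            norm = np.linalg.norm(vec)
            if norm > 0:
                vec /= norm
        return vec

    def embed_many(self, texts: Sequence[str], normalize: bool = True) -> np.ndarray:
        return np.array([self.embed(t, normalize=normalize) for t in texts]) if texts \
            else np.zeros((0, self.dim))


class BaselineAdapter(Protocol):
    """Contract for a plugged-in misinformation baseline.

    ``features`` must return the model's penultimate ("last layer before the
    head") representation with a fixed dimension ``dim``.
    """

    dim: int

    def fit(self, texts: Sequence[str], labels: np.ndarray, seed: int = 0) -> "BaselineAdapter": ...

    def features(self, texts: Sequence[str]) -> np.ndarray: ...


class HashingBaselineAdapter:
    """Reference baseline: a bag-of-embeddings classifier.

    A single hidden layer (tanh) over the hashing embedding, trained with
    cross-entropy; the hidden activations are the baseline feature ``o``.
    """

    def __init__(self, encoder: HashingEncoder | None = None, dim: int = 64,
                 epochs: int = 30, lr: float = 1e-2, batch_size: int = 64) -> None:
        self.encoder = encoder or HashingEncoder()
        self.dim = dim
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.params: dict[str, np.ndarray] | None = None

    def fit(self, texts: Sequence[str], labels: np.ndarray, seed: int = 0) -> "HashingBaselineAdapter":
        x = self.encoder.embed_many(texts)
        y = np.asarray(labels, dtype=int)
        rng = np.random.default_rng(seed)
        params = {}
        params.update({f"h_{k}": v for k, v in _nn.init_linear(rng, self.encoder.dim, self.dim).items()})
        params.update({f"out_{k}": v for k, v in _nn.init_linear(rng, self.dim, 2).items()})
        opt = _nn.Adam(params, lr=self.lr)
        n = len(y)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = x[idx], y[idx]
                h_pre = xb @ params["h_W"] + params["h_b"]
                h = np.tanh(h_pre)
                probs = _nn.softmax(h @ params["out_W"] + params["out_b"])
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                grads = {
                    "out_W": h.T @ dlogits,
                    "out_b": dlogits.sum(axis=0),
                }
                dh = (dlogits @ params["out_W"].T) * (1 - h * h)
                grads["h_W"] = xb.T @ dh
                grads["h_b"] = dh.sum(axis=0)
                opt.step(grads)
        self.params = params
        return self

    def features(self, texts: Sequence[str]) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("baseline adapter not fitted")
        x = self.encoder.embed_many(texts)
        return np.tanh(x @ self.params["h_W"] + self.params["h_b"])


ENCODERS: dict[str, Callable[..., TextEncoder]] = {"hashing": HashingEncoder}
BASELINES: dict[str, Callable[..., BaselineAdapter]] = {"hashing": HashingBaselineAdapter}


def get_encoder(name: str, dim: int, seed: int = 0) -> TextEncoder:
    """Look an encoder up in the registry (``hashing`` or ``external:<name>``)."""
    key = name.split(":", 1)[-1] if name.startswith("external:") else name
    if key not in ENCODERS:
        raise KeyError(f"unknown encoder {name!r}; registered: {sorted(ENCODERS)}")
    return ENCODERS[key](dim=dim, seed=seed)
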
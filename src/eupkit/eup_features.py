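"""The four environmental-uncertainty representations of a post.

For a post with embedding ``p`` and an environment of items ``e_i`` with
cosine similarities ``s_i`` and uncertainty scores ``u_i``:

* similarity representation  ``S = (1/n) * sum_i s_i * (p ⊙ e_i)``
* uncertainty representation ``U = (1/n) * sum_i u_i * e_i``

(⊙ is the Hadamard product; both are zero vectors for an empty
environment, and averaging makes them invariant to environment size).
Each channel is then projected to the common hidden dimension ``h``:

* macro / micro:  ``I_M = MLP(S_M ⊕ U_M)``, ``I_C = MLP(S_C ⊕ U_C)``
* message framing: ``I_F = MLP(u_p * p)`` where ``u_p`` is the post's own
  uncertainty score
* physical: a daily factor
  ``f = Norm(ln(1+|ΔN_cases|) * ln(1+|ΔN_news|))`` scales the three
  projected channels, ``I_P = MLP((f*I_M) ⊕ (f*I_C) ⊕ (f*I_F))``.

The channel projectors live inside the classifier (they are trained
end-to-end); this module provides the arithmetic, the raw per-post feature
matrices, and standalone projector objects for composing the
representations outside a classifier.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _nn
from .data_io import CaseDayRecord
from .environment import EnvironmentWindow


# ---------------------------------------------------------------------------
# elementary arithmetic
# ---------------------------------------------------------------------------

def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of two vectors; 0 when either has zero norm."""
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _env_arrays(env: EnvironmentWindow):
    sims = np.array([item.similarity for item in env.items])
    uncs = np.array([item.uncertainty for item in env.items])
    embs = np.array([item.embedding for item in env.items])
    return sims, embs, uncs


def similarity_representation(p: np.ndarray, env: EnvironmentWindow | tuple) -> np.ndarray:
    """Similarity-weighted mean of Hadamard products, ``mean_i s_i (p ⊙ e_i)``."""
    sims, embs, _ = _env_arrays(env) if isinstance(env, EnvironmentWindow) else env
    if len(sims) == 0:
        return np.zeros_like(p, dtype=float)
    if embs.shape[1] != p.shape[0]:
        raise ValueError("embedding dimension mismatch")
    return (sims[:, None] * (p[None, :] * embs)).mean(axis=0)


def uncertainty_representation(env: EnvironmentWindow | tuple, dim: int | None = None) -> np.ndarray:
    """Uncertainty-weighted mean of environment embeddings, ``mean_i u_i e_i``."""
    sims, embs, uncs = _env_arrays(env) if isinstance(env, EnvironmentWindow) else env
    if len(uncs) == 0:
        if dim is None and isinstance(env, tuple):
            dim = env[1].shape[1] if env[1].ndim == 2 else None
        return np.zeros(dim if dim is not None else 0, dtype=float)
    return (uncs[:, None] * embs).mean(axis=0)


@dataclass
class EnvRepresentation:
    """Similarity and uncertainty representations of one environment."""

    S: np.ndarray
    U: np.ndarray


def environment_representation(p: np.ndarray, env: EnvironmentWindow) -> EnvRepresentation:
    return EnvRepresentation(
        S=similarity_representation(p, env),
        U=uncertainty_representation(env, dim=p.shape[0]),
    )


# ---------------------------------------------------------------------------
# projectors (standalone; the classifier trains its own copies end-to-end)
# ---------------------------------------------------------------------------

class Projector:
    """A single affine projection ``x @ W + b``."""

    def __init__(self, W: np.ndarray, b: np.ndarray | None = None) -> None:
        self.W = np.asarray(W, dtype=float)
        self.b = np.zeros(self.W.shape[1]) if b is None else np.asarray(b, dtype=float)

    @classmethod
    def random(cls, n_in: int, n_out: int, seed: int = 0) -> "Projector":
        rng = np.random.default_rng(seed)
        return cls(_nn.glorot(rng, n_in, n_out))

    @classmethod
    def identity(cls, n: int) -> "Projector":
        return cls(np.eye(n))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self.W.shape[0]:
            raise ValueError(
                f"projector expects input dimension {self.W.shape[0]}, got {x.shape[-1]}"
            )
        return x @ self.W + self.b


def env_feature(rep: EnvRepresentation, projector: Projector) -> np.ndarray:
    """Project the concatenation S ⊕ U to the hidden dimension (I_M or I_C)."""
    return projector(np.concatenate([rep.S, rep.U]))


def framing_feature(p: np.ndarray, u_p: float, projector: Projector) -> np.ndarray:
    """Project the uncertainty-scaled post embedding ``u_p * p`` (I_F)."""
    if not 0.0 <= u_p <= 1.0:
        raise ValueError("u_p must lie in [0,1]")
    return projector(u_p * p)


def physical_feature(
    f: float, I_M: np.ndarray, I_C: np.ndarray, I_F: np.ndarray, projector: Projector
) -> np.ndarray:
    """Project the f-scaled concatenation of the three channels (I_P)."""
    return projector(np.concatenate([f * I_M, f * I_C, f * I_F]))


# ---------------------------------------------------------------------------
# physical environment factor
# ---------------------------------------------------------------------------

class PhysicalUncertainty:
    """Daily physical-environment uncertainty factor.

    The raw factor of day *i* is ``ln(1+|ΔN_cases|) * ln(1+|ΔN_news|)``
    (day-over-day changes); the first day of the series has no predecessor
    and carries no factor.  Raw factors are min-max normalized to [0, 1]
    with bounds fitted on a designated set of (training) dates and clipped
    at apply time.
    """

    def __init__(self, series: Sequence[CaseDayRecord]) -> None:
        self.raw: dict[dt.date, float] = {}
        by_date = {rec.date: rec for rec in series}
        dates = sorted(by_date)
        for prev, cur in zip(dates, dates[1:]):
            if (cur - prev).days != 1:
                raise ValueError(f"case series has a gap between {prev} and {cur}")
            a, b = by_date[prev], by_date[cur]
            self.raw[cur] = math.log1p(abs(b.n_cases - a.n_cases)) * math.log1p(
                abs(b.n_news - a.n_news)
            )
        self.bounds: tuple[float, float] | None = None

    def fit(self, dates: Sequence[dt.date] | None = None) -> "PhysicalUncertainty":
        """Fit normalization bounds on ``dates`` (default: all factor days)."""
        pool = [d for d in (dates if dates is not None else self.raw) if d in self.raw]
        if not pool:
            raise ValueError("no dates with a defined factor to fit on")
        values = [self.raw[d] for d in pool]
        self.bounds = (min(values), max(values))
        return self

    def raw_factor(self, date: dt.date) -> float:
        if date not in self.raw:
            raise KeyError(f"no factor for {date} (absent date or missing predecessor)")
        return self.raw[date]

    def factor(self, date: dt.date) -> float:
        """Normalized factor f ∈ [0, 1] for one date."""
        if self.bounds is None:
            raise RuntimeError("normalization bounds not fitted")
        lo, hi = self.bounds
        value = self.raw_factor(date)
        if hi <= lo:
            return 0.0
        return min(max((value - lo) / (hi - lo), 0.0), 1.0)

    def factors(self, dates: Sequence[dt.date]) -> np.ndarray:
        return np.array([self.factor(d) for d in dates])


def physical_factor(
    series: Sequence[CaseDayRecord],
    date: dt.date,
    fit_dates: Sequence[dt.date] | None = None,
) -> float:
    """One-shot convenience wrapper around :class:`PhysicalUncertainty`."""
    return PhysicalUncertainty(series).fit(fit_dates).factor(date)


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class FeatureBundle:
    """The four projected representations of one post (common dimension h)."""

    I_M: np.ndarray
    I_C: np.ndarray
    I_F: np.ndarray
    I_P: np.ndarray
    f_ph: float

    def __post_init__(self) -> None:
        dims = {v.shape[-1] for v in (self.I_M, self.I_C, self.I_F, self.I_P)}
        if len(dims) != 1:
            raise ValueError(f"channel dimensions differ: {sorted(dims)}")
        for name in ("I_M", "I_C", "I_F", "I_P"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")


@dataclass
class PostFeatures:
    """Raw per-post model inputs for a set of posts.

    ``X_M``/``X_C`` hold the concatenations S ⊕ U (dimension 2d), ``X_F``
    the uncertainty-scaled post embeddings (dimension d), and ``f`` the
    daily physical factors.  The classifier projects these to the hidden
    dimension with its own trainable channel projectors.
    """

    ids: list[str]
    X_M: np.ndarray
    X_C: np.ndarray
    X_F: np.ndarray
    f: np.ndarray
    u_post: np.ndarray
    env_sizes: np.ndarray | None = None   # (n, 2): |M|, |C|

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices) -> "PostFeatures":
        indices = np.asarray(indices)
        return PostFeatures(
            ids=[self.ids[i] for i in indices],
            X_M=self.X_M[indices],
            X_C=self.X_C[indices],
            X_F=self.X_F[indices],
            f=self.f[indices],
            u_post=self.u_post[indices],
            env_sizes=None if self.env_sizes is None else self.env_sizes[indices],
        )
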
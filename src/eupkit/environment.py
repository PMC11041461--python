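"""Per-post information environments.

The macro-media environment of a post is the set of news items released
within the closed interval of ``T`` days before it,
``M = {e : 0 <= t_p - t_e <= T}`` (seconds arithmetic, ``T`` in days).  The
micro-communicative environment first applies the same time filter to the
tweet stream (``C'``) and then keeps the ``k`` tweets most similar to the
post, with ``k = max(ceil(r * |C'|), min(c_min, |C'|))``.  Ties on equal
similarity are broken deterministically: more recent tweet first, then
lexicographic document id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import SECONDS_PER_DAY, DocumentRecord, PostRecord
from .encoder import TextEncoder
from .uncertainty_model import UncertaintyScorer


@dataclass
class EnvironmentItem:
    """One document inside a post's environment, annotated against the post."""

    doc_id: str
    embedding: np.ndarray
    similarity: float
    uncertainty: float
    created_time: float


@dataclass
class EnvironmentWindow:
    """The macro set M or micro set C attached to one post."""

    post_id: str
    kind: str                       # "macro" | "micro"
    items: list[EnvironmentItem] = field(default_factory=list)
    T: int = 3
    r: float | None = None          # micro only
    k: int | None = None            # micro only
    c_min: int | None = None        # micro only

    def __len__(self) -> int:
        return len(self.items)


def in_window(t_post: float, t_doc: float, T: int) -> bool:
    """Closed interval: the document counts iff ``0 <= t_post - t_doc <= T`` days."""
    delta = t_post - t_doc
    return 0.0 <= delta <= T * SECONDS_PER_DAY


def window_filter(post: PostRecord, docs: Sequence[DocumentRecord], T: int) -> list[DocumentRecord]:
    return [d for d in docs if in_window(post.created_time, d.created_time, T)]


def micro_k(n_candidates: int, r: float, c_min: int) -> int:
    """Selected micro-environment size: ``max(ceil(r*n), min(c_min, n))``.

    The ceiling guarantees k >= 1 whenever candidates exist; the floor
    ``c_min`` is capped by the number of available tweets.
    """
    if not 0 < r < 1:
        raise ValueError("r must lie in (0,1)")
    if c_min <= 0:
        raise ValueError("c_min must be positive")
    if n_candidates == 0:
        return 0
    return max(math.ceil(r * n_candidates), min(c_min, n_candidates))


def _sort_key(item: EnvironmentItem):
    # similarity descending, then recency (later first), then id ascending
    return (-item.similarity, -item.created_time, item.doc_id)


def _annotate(
    post: PostRecord,
    docs: Sequence[DocumentRecord],
    encoder: TextEncoder,
    scorer: UncertaintyScorer,
    post_embedding: np.ndarray | None,
) -> list[EnvironmentItem]:
    from .eup_features import cosine_similarity

    p = post_embedding if post_embedding is not None else encoder.embed(post.text)
    items = []
    for doc in docs:
        e = encoder.embed(doc.text)
        items.append(
            EnvironmentItem(
                doc_id=doc.id,
                embedding=e,
                similarity=cosine_similarity(p, e),
                uncertainty=scorer.score(doc.text),
                created_time=doc.created_time,
            )
        )
    return items


def build_macro(
    post: PostRecord,
    news: Sequence[DocumentRecord],
    T: int,
    encoder: TextEncoder,
    scorer: UncertaintyScorer,
    post_embedding: np.ndarray | None = None,
) -> EnvironmentWindow:
    """All news within the closed T-day window, annotated with similarity and
    uncertainty.  An empty window is allowed."""
    selected = window_filter(post, news, T)
    items = sorted(_annotate(post, selected, encoder, scorer, post_embedding), key=_sort_key)
    return EnvironmentWindow(post_id=post.id, kind="macro", items=items, T=T)


def build_micro(
    post: PostRecord,
    tweets: Sequence[DocumentRecord],
    T: int,
    r: float,
    c_min: int,
    encoder: TextEncoder,
    scorer: UncertaintyScorer,
    post_embedding: np.ndarray | None = None,
) -> EnvironmentWindow:
    """Time filter to C', then keep the k most similar tweets."""
    candidates = window_filter(post, tweets, T)
    k = micro_k(len(candidates), r, c_min)
    items = sorted(_annotate(post, candidates, encoder, scorer, post_embedding), key=_sort_key)[:k]
    return EnvironmentWindow(
        post_id=post.id, kind="micro", items=items, T=T, r=r, k=k, c_min=c_min
    )


class EnvironmentBuilder:
    """Vectorized environment construction over cached document arrays.

    Documents are embedded and uncertainty-scored once; per post, the time
    window is a slice (documents sorted by timestamp + binary search) and
    similarities are one matrix-vector product.  Produces the same windows
    as :func:`build_macro` / :func:`build_micro`.
    """

    def __init__(
        self,
        news: Sequence[DocumentRecord],
        tweets: Sequence[DocumentRecord],
        encoder: TextEncoder,
        scorer: UncertaintyScorer,
        T: int,
        r: float,
        c_min: int,
    ) -> None:
        self.encoder = encoder
        self.scorer = scorer
        self.T = T
        self.r = r
        self.c_min = c_min
        self._news = self._pack(news)
        self._tweets = self._pack(tweets)

    def _pack(self, docs: Sequence[DocumentRecord]):
        order = sorted(range(len(docs)), key=lambda i: (docs[i].created_time, docs[i].id))
        times = np.array([docs[i].created_time for i in order])
        ids = np.array([docs[i].id for i in order], dtype=object)
        emb = self.encoder.embed_many([docs[i].text for i in order])
        unit = emb.copy()
        if len(unit):
            norms = np.linalg.norm(unit, axis=1)
            nonzero = norms > 0
            unit[nonzero] /= norms[nonzero, None]
        unc = np.array([self.scorer.score(docs[i].text) for i in order])
        return {"times": times, "ids": ids, "emb": emb, "unit": unit, "unc": unc}

    def _window(self, pack: dict, t_post: float) -> slice:
        lo = np.searchsorted(pack["times"], t_post - self.T * SECONDS_PER_DAY, side="left")
        hi = np.searchsorted(pack["times"], t_post, side="right")
        return slice(lo, hi)

    @staticmethod
    def _unit(vec: np.ndarray) -> np.ndarray:
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def macro_arrays(self, post_embedding: np.ndarray, t_post: float):
        """(similarities, embeddings, uncertainties) of the macro window."""
        pack = self._news
        sl = self._window(pack, t_post)
        sims = pack["unit"][sl] @ self._unit(post_embedding)
        return sims, pack["emb"][sl], pack["unc"][sl]

    def micro_arrays(self, post_embedding: np.ndarray, t_post: float):
        """(similarities, embeddings, uncertainties) of the selected top-k tweets."""
        pack = self._tweets
        sl = self._window(pack, t_post)
        sims = pack["unit"][sl] @ self._unit(post_embedding)
        k = micro_k(len(sims), self.r, self.c_min)
        if k == 0:
            return sims[:0], pack["emb"][sl][:0], pack["unc"][sl][:0]
        times = pack["times"][sl]
        ids = pack["ids"][sl]
        order = np.lexsort((ids, -times, -sims))[:k]
        return sims[order], pack["emb"][sl][order], pack["unc"][sl][order]
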
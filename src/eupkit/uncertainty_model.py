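"""Corpus-trained linguistic uncertainty scorer.

The scorer is a probabilistic n-gram model estimated on a hedge-annotated
corpus.  For every n-gram key ``w`` it keeps three counts:

``F_s``
    occurrences anywhere in the corpus,
``F_u``
    occurrences inside sentences flagged uncertain,
``F_m``
    occurrences as an uncertainty marker (every token of the window carries
    a cue flag).

The marker probability of an n-gram is ``p(c|w) = F_m / F_s`` and a
confidence weight ``conf(w) = 1 - (1 - lambda)**F_s`` discounts rarely seen
keys.  A *feature* is a quadruplet (type, size, context, aggregation): it
scores a sentence by aggregating ``p * conf`` over its n-grams of the given
type/size, where the context chooses between the marker probability
(``F_m/F_s``) and the uncertain-sentence probability (``F_u/F_s``).  The
sentence-level score is the mean of the min-max normalized feature scores,
with normalization bounds fitted on the training corpus only, so it always
lies in [0, 1].
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .data_io import HedgeSentence

_WORD_RE = re.compile(r"\w+", re.UNICODE)

NGRAM_TYPES = ("lemma", "token")
CONTEXTS = ("uncertainty_marker", "uncertain_sentence")
AGGREGATIONS = ("sum", "mean", "max")


def tokenize(text: str) -> list[str]:
    """Lowercased Unicode word tokens."""
    return _WORD_RE.findall(text.lower())


def identity_lemmatizer(token: str) -> str:
    """Reference lemmatizer: lowercasing only (dictionary-free)."""
    return token.lower()


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

@dataclass
class NGramStats:
    """Count tables (F_s, F_u, F_m) for one (type, size) combination."""

    kind: str
    size: int
    counts: dict[tuple[str, ...], list[int]] = field(default_factory=dict)
    total_sentences: int = 0

    def get(self, key: tuple[str, ...]) -> tuple[int, int, int]:
        fs, fu, fm = self.counts.get(key, (0, 0, 0))
        return fs, fu, fm


def _sequence(sentence: HedgeSentence, kind: str) -> list[str]:
    source = sentence.lemmas if kind == "lemma" else sentence.tokens
    return [t.lower() for t in source]


def count_ngrams(corpus: Sequence[HedgeSentence], kind: str = "lemma", size: int = 1) -> NGramStats:
    """Slide a window of width ``size`` over every sentence and tally counts.

    An n-gram counts toward F_m only when *all* of its tokens carry a cue
    flag, and toward F_u only when its sentence is flagged uncertain.
    """
    if kind not in NGRAM_TYPES:
        raise ValueError(f"unknown n-gram type {kind!r}")
    if size < 1:
        raise ValueError("size must be >= 1")
    if not corpus:
        raise ValueError("empty corpus")
    stats = NGramStats(kind=kind, size=size, total_sentences=len(corpus))
    for sentence in corpus:
        seq = _sequence(sentence, kind)
        flags = sentence.cue_flags
        uncertain = sentence.uncertain
        for start in range(len(seq) - size + 1):
            key = tuple(seq[start : start + size])
            row = stats.counts.setdefault(key, [0, 0, 0])
            row[0] += 1
            if uncertain:
                row[1] += 1
            if all(flags[start : start + size]):
                row[2] += 1
    return stats


def marker_probability(stats: NGramStats, key: tuple[str, ...] | str) -> float:
    """Conditional probability that ``key`` acts as an uncertainty marker,
    ``F_m / F_s``; 0 for unseen keys."""
    if isinstance(key, str):
        key = (key,)
    fs, _, fm = stats.get(key)
    return fm / fs if fs else 0.0


def context_probability(stats: NGramStats, key: tuple[str, ...] | str, context: str) -> float:
    """``F_m/F_s`` for the marker context, ``F_u/F_s`` for the
    uncertain-sentence context; 0 for unseen keys."""
    if isinstance(key, str):
        key = (key,)
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    fs, fu, fm = stats.get(key)
    if fs == 0:
        return 0.0
    return (fm if context == "uncertainty_marker" else fu) / fs


def confidence(stats: NGramStats, key: tuple[str, ...] | str, lam: float) -> float:
    """Evidence weight ``1 - (1 - lam)**F_s``: 0 at F_s = 0, increasing in
    F_s, bounded below 1."""
    if not 0 < lam < 1:
        raise ValueError("lambda must lie in (0,1)")
    if isinstance(key, str):
        key = (key,)
    fs, _, _ = stats.get(key)
    return 1.0 - (1.0 - lam) ** fs


# ---------------------------------------------------------------------------
# feature quadruplets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """One scoring feature: (type, size, context, aggregation)."""

    kind: str
    size: int
    context: str
    aggregation: str

    def __post_init__(self) -> None:
        if self.kind not in NGRAM_TYPES:
            raise ValueError(f"unknown n-gram type {self.kind!r}")
        if self.size not in (1, 2, 3):
            raise ValueError("size must be 1, 2 or 3")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


#: The first feature: lemma unigrams in the marker context, sum-aggregated.
F1 = FeatureSpec("lemma", 1, "uncertainty_marker", "sum")


def default_feature_set() -> list[FeatureSpec]:
    """Eight quadruplets: {lemma, token} x {1, 2} x both contexts, with sum
    aggregation for unigrams and max for bigrams."""
    specs = []
    for kind in NGRAM_TYPES:
        for size, agg in ((1, "sum"), (2, "max")):
            for context in CONTEXTS:
                specs.append(FeatureSpec(kind, size, context, agg))
    return specs


def feature_score(
    stats: NGramStats,
    tokens: Sequence[str],
    lemmas: Sequence[str],
    spec: FeatureSpec,
    lam: float,
) -> float:
    """Raw (unnormalized) feature score of a tokenized sentence.

    Each n-gram contributes ``p(context|w) * conf(w)``; contributions are
    combined with the spec's aggregation.  Empty sentences score 0.
    """
    seq = [t.lower() for t in (lemmas if spec.kind == "lemma" else tokens)]
    contributions: list[float] = []
    for start in range(len(seq) - spec.size + 1):
        key = tuple(seq[start : start + spec.size])
        p = context_probability(stats, key, spec.context)
        contributions.append(p * confidence(stats, key, lam))
    if not contributions:
        return 0.0
    if spec.aggregation == "sum":
        return float(sum(contributions))
    if spec.aggregation == "mean":
        return float(sum(contributions) / len(contributions))
    return float(max(contributions))


# ---------------------------------------------------------------------------
# the scorer
# ---------------------------------------------------------------------------

class UncertaintyScorer:
    """Maps any sentence to an uncertainty score in [0, 1].

    Built by :func:`fit_scorer`; scoring never mutates the count tables, and
    unseen n-grams contribute 0 so open-vocabulary post text is handled.
    """

    def __init__(
        self,
        stats: dict[tuple[str, int], NGramStats],
        features: list[FeatureSpec],
        confidence_lambda: float,
        norm_bounds: list[tuple[float, float]] | None = None,
        lemmatizer: Callable[[str], str] = identity_lemmatizer,
    ) -> None:
        self.stats = stats
        self.features = features
        self.confidence_lambda = confidence_lambda
        self.norm_bounds = norm_bounds
        self.lemmatizer = lemmatizer

    # -- scoring -----------------------------------------------------------

    @property
    def fitted(self) -> bool:
        return self.norm_bounds is not None

    def raw_scores(self, tokens: Sequence[str], lemmas: Sequence[str]) -> np.ndarray:
        return np.array(
            [
                feature_score(self.stats[(spec.kind, spec.size)], tokens, lemmas, spec, self.confidence_lambda)
                for spec in self.features
            ]
        )

    def score_tokens(self, tokens: Sequence[str], lemmas: Sequence[str] | None = None) -> float:
        if not self.fitted:
            raise RuntimeError("scorer not fitted: normalization bounds missing")
        if lemmas is None:
            lemmas = [self.lemmatizer(t) for t in tokens]
        raw = self.raw_scores(tokens, lemmas)
        normed = np.empty_like(raw)
        for i, ((lo, hi), value) in enumerate(zip(self.norm_bounds, raw)):
            if hi > lo:
                normed[i] = min(max((value - lo) / (hi - lo), 0.0), 1.0)
            else:
                normed[i] = 0.0
        return float(normed.mean())

    def score(self, text: str) -> float:
        """Sentence uncertainty of raw text (tokenize, lemmatize, score)."""
        tokens = tokenize(text)
        return self.score_tokens(tokens)

    def marker_probability(self, lemma: str) -> float:
        """Unigram lemma marker probability, using the F1 count table."""
        stats = self.stats.get(("lemma", 1))
        if stats is None:
            raise KeyError("no lemma unigram table in this scorer")
        return marker_probability(stats, lemma)

    # -- serialization -----------------------------------------------------

    SERIAL_VERSION = 1
    _KEY_SEP = "␟"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "version": self.SERIAL_VERSION,
            "confidence_lambda": self.confidence_lambda,
            "features": [
                [spec.kind, spec.size, spec.context, spec.aggregation] for spec in self.features
            ],
            "norm_bounds": self.norm_bounds,
            "stats": {
                f"{kind}:{size}": {
                    "total_sentences": table.total_sentences,
                    "counts": {self._KEY_SEP.join(key): row for key, row in table.counts.items()},
                }
                for (kind, size), table in self.stats.items()
            },
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def fingerprint(self) -> str:
        """SHA-256 of the serialized scorer (for checkpoint compatibility checks)."""
        import hashlib

        return hashlib.sha256(self.to_json().encode("utf-8")).hexdigest()

    @classmethod
    def from_json(cls, source: str | Path) -> "UncertaintyScorer":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(str(source))
        stats: dict[tuple[str, int], NGramStats] = {}
        for label, table in payload["stats"].items():
            kind, size_text = label.split(":")
            size = int(size_text)
            stats[(kind, size)] = NGramStats(
                kind=kind,
                size=size,
                counts={
                    tuple(key.split(cls._KEY_SEP)): [int(v) for v in row]
                    for key, row in table["counts"].items()
                },
                total_sentences=int(table["total_sentences"]),
            )
        features = [FeatureSpec(*row) for row in payload["features"]]
        bounds = payload["norm_bounds"]
        return cls(
            stats=stats,
            features=features,
            confidence_lambda=payload["confidence_lambda"],
            norm_bounds=None if bounds is None else [tuple(b) for b in bounds],
        )


def fit_scorer(
    corpus: Sequence[HedgeSentence],
    features: Sequence[FeatureSpec] | None = None,
    confidence_lambda: float = 0.1,
    lemmatizer: Callable[[str], str] = identity_lemmatizer,
) -> UncertaintyScorer:
    """Count n-grams and fit per-feature normalization bounds on ``corpus``.

    The corpus must contain at least one uncertain and one certain sentence;
    a single-class corpus yields a degenerate model and is rejected.
    """
    if not corpus:
        raise ValueError("empty corpus")
    n_uncertain = sum(s.uncertain for s in corpus)
    if n_uncertain == 0:
        raise ValueError("degenerate corpus: no uncertain sentences")
    if n_uncertain == len(corpus):
        raise ValueError("degenerate corpus: no certain sentences")
    if not 0 < confidence_lambda < 1:
        raise ValueError("confidence_lambda must lie in (0,1)")
    specs = list(features) if features is not None else default_feature_set()
    stats: dict[tuple[str, int], NGramStats] = {}
    for spec in specs:
        key = (spec.kind, spec.size)
        if key not in stats:
            stats[key] = count_ngrams(corpus, kind=spec.kind, size=spec.size)
    scorer = UncertaintyScorer(stats, specs, confidence_lambda, lemmatizer=lemmatizer)
    raw = np.array([scorer.raw_scores(s.tokens, s.lemmas) for s in corpus])
    scorer.norm_bounds = [(float(lo), float(hi)) for lo, hi in zip(raw.min(axis=0), raw.max(axis=0))]
    return scorer
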
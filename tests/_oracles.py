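"""Independent brute-force oracles and random-instance generators.

Everything here is deliberately written in the most literal way possible
(nested loops, exhaustive enumeration) and shares no code with the package
internals it is used to check.
"""

from __future__ import annotations

import math

import numpy as np

from eupkit.data_io import HedgeSentence


# ---------------------------------------------------------------------------
# n-gram counting
# ---------------------------------------------------------------------------

def brute_force_ngram_counts(corpus, kind: str, size: int) -> dict:
    """Literal recount of (F_s, F_u, F_m) for every n-gram key."""
    table: dict[tuple, list[int]] = {}
    for sentence in corpus:
        seq = sentence.lemmas if kind == "lemma" else sentence.tokens
        seq = [t.lower() for t in seq]
        for start in range(0, len(seq) - size + 1):
            key = tuple(seq[start : start + size])
            if key not in table:
                table[key] = [0, 0, 0]
            table[key][0] += 1
            if sentence.uncertain == 1:
                table[key][1] += 1
            all_cues = True
            for offset in range(size):
                if sentence.cue_flags[start + offset] != 1:
                    all_cues = False
            if all_cues:
                table[key][2] += 1
    return {k: tuple(v) for k, v in table.items()}


def random_hedge_corpus(rng: np.random.Generator, n_sentences: int,
                        vocab: int = 8, max_len: int = 9) -> list[HedgeSentence]:
    """Tiny random corpora with aggressive key collisions."""
    corpus = []
    for _ in range(n_sentences):
        length = int(rng.integers(1, max_len + 1))
        tokens = [f"w{rng.integers(vocab)}" for _ in range(length)]
        lemmas = [t if rng.random() < 0.7 else f"l{rng.integers(vocab)}" for t in tokens]
        flags = [int(rng.random() < 0.3) for _ in range(length)]
        uncertain = 1 if any(flags) else int(rng.random() < 0.2)
        corpus.append(HedgeSentence(tokens, lemmas, flags, uncertain))
    return corpus


# ---------------------------------------------------------------------------
# environments
# ---------------------------------------------------------------------------

def brute_force_window(t_post: float, doc_times, T_days: int) -> list[int]:
    """Indices of documents inside the closed T-day window, by full scan."""
    keep = []
    for i, t in enumerate(doc_times):
        delta = t_post - t
        if 0.0 <= delta <= T_days * 86400.0:
            keep.append(i)
    return keep


def brute_force_topk(sims, times, ids, r: float, c_min: int) -> list:
    """Full sort then prefix, with the (similarity, recency, id) tie-break."""
    n = len(sims)
    if n == 0:
        return []
    k = max(math.ceil(r * n), min(c_min, n))
    order = sorted(range(n), key=lambda i: (-sims[i], -times[i], ids[i]))
    return [ids[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# partial AUC
# ---------------------------------------------------------------------------

def brute_force_sp_auc(scores, labels, fpr_max: float = 0.1) -> float:
    """Exhaustive-threshold empirical ROC, trapezoidal partial area,
    McClish standardization."""
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    points = [(0.0, 0.0)]
    for threshold in sorted(set(scores), reverse=True):
        tp = sum(1 for s, y in zip(scores, labels) if s >= threshold and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= threshold and y == 0)
        points.append((fp / n_neg, tp / n_pos))
    points.sort()
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        if x1 <= fpr_max:
            area += (x1 - x0) * (y0 + y1) / 2.0
        elif x0 < fpr_max:
            # interpolate the crossing point
            y_cut = y0 + (y1 - y0) * (fpr_max - x0) / (x1 - x0)
            area += (fpr_max - x0) * (y0 + y_cut) / 2.0
    a_min = fpr_max**2 / 2.0
    a_max = fpr_max
    return 0.5 * (1.0 + (area - a_min) / (a_max - a_min))
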
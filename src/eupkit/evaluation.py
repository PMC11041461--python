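"""Metrics and experiment harnesses.

Classification quality is reported as accuracy, per-class F1 and macro-F1
(the unweighted mean of the two per-class F1 values).  Ranking quality on
imbalanced data uses the standardized partial AUC restricted to low false
positive rates: with ``A = pAUC`` over FPR in [0, fpr_max],

    spAUC = 1/2 * (1 + (A - A_min) / (A_max - A_min)),
    A_min = fpr_max**2 / 2  (chance diagonal),  A_max = fpr_max,

so chance maps to 0.5 and perfect separation to 1.0 regardless of
``fpr_max``.  Tied scores are collapsed into a single threshold step (the
standard empirical-ROC convention), which matters for partial areas.

The ablation and class-imbalance harnesses retrain / re-evaluate the full
pipeline; they are thin drivers over :mod:`eupkit.pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(predictions, labels, positive: int = 1) -> ConfusionCounts:
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if pred.shape != y.shape:
        raise ValueError("predictions and labels disagree in length")
    pos_pred = pred == positive
    pos_true = y == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_pred & pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
    )


def accuracy(counts: ConfusionCounts) -> float:
    if counts.total == 0:
        raise ValueError("empty evaluation set")
    return (counts.tp + counts.tn) / counts.total


def accuracy_score(predictions, labels) -> float:
    return accuracy(confusion_counts(predictions, labels))


def f1_per_class(counts: ConfusionCounts) -> float:
    """``2tp / (2tp + fp + fn)``; 0 by convention when the denominator is 0."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    return 2 * counts.tp / denom if denom else 0.0


def f1_score(predictions, labels, positive: int = 1) -> float:
    return f1_per_class(confusion_counts(predictions, labels, positive=positive))


def macro_f1(predictions, labels) -> float:
    """Unweighted mean of the per-class F1 values of the two classes."""
    return 0.5 * (f1_score(predictions, labels, positive=1) + f1_score(predictions, labels, positive=0))


# ---------------------------------------------------------------------------
# standardized partial AUC
# ---------------------------------------------------------------------------

def sp_auc(scores, labels, fpr_max: float = 0.1) -> float:
    """Standardized partial AUC over FPR in [0, ``fpr_max``].

    The empirical ROC (ties collapsed into single threshold steps) is
    integrated with the trapezoidal rule up to ``fpr_max`` (linear
    interpolation at the cut) and rescaled so the chance diagonal gives 0.5
    and perfect separation 1.0.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if scores.shape != y.shape:
        raise ValueError("scores and labels disagree in length")
    if not 0.0 < fpr_max <= 1.0:
        raise ValueError("fpr_max must lie in (0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for ranking metrics")
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    if fpr_max < fpr[-1]:
        tpr_cut = float(np.interp(fpr_max, fpr, tpr))
        keep = fpr <= fpr_max
        fpr = np.append(fpr[keep], fpr_max)
        tpr = np.append(tpr[keep], tpr_cut)
    p_auc = float(np.trapezoid(tpr, fpr))
    a_min = fpr_max**2 / 2.0
    a_max = fpr_max
    return 0.5 * (1.0 + (p_auc - a_min) / (a_max - a_min))


def permutation_band(
    scores,
    labels,
    fpr_max: float = 0.1,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """(lo, hi) quantiles of spAUC under random label permutation."""
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=int)
    values = np.empty(n_permutations)
    for i in range(n_permutations):
        values[i] = sp_auc(scores, rng.permutation(y), fpr_max=fpr_max)
    return (
        float(np.quantile(values, alpha / 2)),
        float(np.quantile(values, 1 - alpha / 2)),
    )


# ---------------------------------------------------------------------------
# imbalance construction
# ---------------------------------------------------------------------------

def subsample_to_ratio(labels, ratio: float, seed: int = 0, positive: int = 1) -> np.ndarray:
    """Indices of a subset whose majority:minority ratio is ``ratio``:1.

    Keeps every majority-class (label != ``positive``) item and downsamples
    the ``positive`` class to ``round(n_majority / ratio)`` items (at least
    one; an unreachable ratio is an error).
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    y = np.asarray(labels, dtype=int)
    majority = np.flatnonzero(y != positive)
    minority = np.flatnonzero(y == positive)
    n_keep = int(round(len(majority) / ratio))
    if n_keep < 1:
        raise ValueError(f"ratio {ratio}:1 unreachable with {len(majority)} majority items")
    if n_keep > len(minority):
        # a shortfall within rounding (e.g. ratio 1 on near-balanced data)
        # keeps the whole minority class; a real shortfall is an error
        if len(minority) and round(len(majority) / len(minority)) <= ratio:
            n_keep = len(minority)
        else:
            raise ValueError(
                f"ratio {ratio}:1 unreachable: needs {n_keep} minority items, have {len(minority)}"
            )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(minority, size=n_keep, replace=False)
    return np.sort(np.concatenate([majority, chosen]))


# ---------------------------------------------------------------------------
# harnesses (thin drivers over the pipeline)
# ---------------------------------------------------------------------------

def ablation_run(
    world,
    config,
    channels_to_drop: Sequence[str] = (),
    task: str = "detect",
    seed: int = 0,
    prepared=None,
) -> dict[str, float]:
    """Retrain with the named channels zeroed out; report the usual metrics.

    Dropping is done by zeroing the projected channel vectors everywhere
    (including inside the physical channel's input), so parameter counts
    match the full model.  Dropping all four channels is rejected.
    """
    from . import pipeline

    if prepared is None:
        prepared = pipeline.prepare(world, config)
    out = pipeline.train_eval(
        prepared, task=task, seed=seed, drop_channels=tuple(channels_to_drop)
    )
    return out.metrics


def imbalance_harness(
    world,
    config,
    ratios: Sequence[float] = (10, 20, 50, 100),
    task: str = "detect",
    seed: int = 0,
    prepared=None,
) -> pd.DataFrame:
    """Evaluate one fixed trained model on majority:minority test sets.

    For each requested real:fake ratio the test fold is rebuilt by
    downsampling the minority (fake / high-spread) class; macro-F1 and
    spAUC (FPR <= 0.1) are reported per ratio.
    """
    from . import pipeline

    if prepared is None:
        prepared = pipeline.prepare(world, config)
    out = pipeline.train_eval(prepared, task=task, seed=seed)
    y_test = out.y_test
    probs = out.test_probs
    rows = []
    for i, ratio in enumerate(ratios):
        idx = subsample_to_ratio(y_test, ratio, seed=seed + i, positive=1)
        y_sub = y_test[idx]
        p_sub = probs[idx]
        pred = p_sub.argmax(axis=1)
        rows.append(
            {
                "ratio": ratio,
                "n_majority": int(np.sum(y_sub == 0)),
                "n_minority": int(np.sum(y_sub == 1)),
                "accuracy": accuracy_score(pred, y_sub),
                "macro_f1": macro_f1(pred, y_sub),
                "sp_auc": sp_auc(p_sub[:, 1], y_sub),
            }
        )
    return pd.DataFrame(rows)
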
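"""End-to-end glue: scorer training, feature extraction, training runs.

The canonical flow is

    world  ->  fit scorer on the hedge corpus
           ->  extract per-post channel inputs (macro, micro, framing, raw
               physical factor)
           ->  temporally blocked 60/20/20 split (7-day blocks,
               stratified by block label rate)
           ->  normalize the physical factor with training-fold bounds
           ->  train a classifier, early-stopping on validation macro-F1
           ->  metrics on the held-out fold.

:func:`prepare` does everything up to the split once per world (feature
extraction is the expensive part and is label-independent), and
:func:`train_eval` runs one split/train/evaluate cycle from it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import CaseDayRecord, DocumentRecord, PostRecord, RunConfig, timestamp_to_date
from .encoder import HashingBaselineAdapter, TextEncoder, get_encoder
from .environment import EnvironmentBuilder
from .eup_features import PhysicalUncertainty, PostFeatures
from .fusion_classifier import ClassifierResults, EUPClassifier, GatedFusionClassifier
from .synthetic_data import GeneratedWorld
from .uncertainty_model import UncertaintyScorer, fit_scorer

TASKS = ("detect", "spread")


def derive_seed(seed: int, offset: int) -> int:
    """Deterministic sub-seed below 2**31."""
    return (seed * 1000003 + offset) % (2**31 - 1)


def split_indices(
    labels: np.ndarray, seed: int, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation/test indices (disjoint by construction)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        train.append(idx[:n_train])
        val.append(idx[n_train : n_train + n_val])
        test.append(idx[n_train + n_val :])
    return tuple(np.sort(np.concatenate(part)) for part in (train, val, test))


def split_by_day(
    days: np.ndarray,
    seed: int,
    labels: np.ndarray | None = None,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    block_days: int = 7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Temporally blocked train/validation/test indices.

    Consecutive calendar days are grouped into blocks of ``block_days`` and
    every post of a block lands in the same fold.  Blocking prevents two
    leaks that post-level (or even day-level) splits allow when labels are
    coupled to the day's environment: memorizing per-day label rates through
    day-identifying features, and interpolating a held-out day's rate from
    temporally adjacent training days whose environment windows overlap.
    With ``labels`` the block-to-fold assignment is stratified: blocks are
    ordered by label rate (randomly jittered) and each run of five is dealt
    to folds 3:1:1 in random within-run order, keeping fold label rates
    close to the global rate without rank bias.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if block_days < 1:
        raise ValueError("block_days must be >= 1")
    days = np.asarray(days)
    rng = np.random.default_rng(seed)
    blocks = (days - days.min()) // block_days
    unique = np.unique(blocks)
    assignment: dict = {}
    if labels is not None:
        y = np.asarray(labels, dtype=float)
        rates = np.array([y[blocks == b].mean() for b in unique])
        order = np.argsort(rates + rng.uniform(-0.02, 0.02, size=len(unique)), kind="stable")
        pattern = np.array([0, 0, 0, 1, 2])
        for start in range(0, len(order), 5):
            run = order[start : start + 5]
            slots = rng.permutation(pattern)[: len(run)]
            for i, fold in zip(run, slots):
                assignment[unique[i]] = int(fold)
    else:
        order = rng.permutation(len(unique))
        counts = {b: int(np.sum(blocks == b)) for b in unique}
        total = len(days)
        filled = [0, 0, 0]
        for i in order:
            block = unique[i]
            deficits = [fractions[j] - filled[j] / total for j in range(3)]
            fold = int(np.argmax(deficits))
            assignment[block] = fold
            filled[fold] += counts[block]
    folds = np.array([assignment[b] for b in blocks])
    out = tuple(np.flatnonzero(folds == j) for j in range(3))
    if any(len(part) == 0 for part in out):
        raise ValueError("a fold received no posts; too few distinct day blocks")
    return out


def extract_features(
    posts: Sequence[PostRecord],
    news: Sequence[DocumentRecord],
    tweets: Sequence[DocumentRecord],
    case_series: Sequence[CaseDayRecord],
    scorer: UncertaintyScorer,
    encoder: TextEncoder,
    config: RunConfig,
) -> PostFeatures:
    """Per-post channel inputs.

    ``X_M``/``X_C`` are the S ⊕ U environment representations, ``X_F`` the
    uncertainty-scaled post embedding, and ``f`` holds the *raw* (not yet
    normalized) physical factor so that normalization bounds can later be
    fitted on a training fold only.
    """
    builder = EnvironmentBuilder(
        news, tweets, encoder, scorer, T=config.T, r=config.r, c_min=config.c_min
    )
    physical = PhysicalUncertainty(case_series)
    d = encoder.dim
    n = len(posts)
    X_M = np.zeros((n, 2 * d))
    X_C = np.zeros((n, 2 * d))
    X_F = np.zeros((n, d))
    f_raw = np.zeros(n)
    u_post = np.zeros(n)
    env_sizes = np.zeros((n, 2), dtype=int)
    for i, post in enumerate(posts):
        p = encoder.embed(post.text)
        u = scorer.score(post.text)
        u_post[i] = u
        X_F[i] = u * p
        for j, arrays in enumerate(
            (builder.macro_arrays(p, post.created_time), builder.micro_arrays(p, post.created_time))
        ):
            sims, embs, uncs = arrays
            env_sizes[i, j] = len(sims)
            if len(sims):
                S = p * (sims @ embs) / len(sims)
                U = (uncs @ embs) / len(sims)
            else:
                S = np.zeros(d)
                U = np.zeros(d)
            target = X_M if j == 0 else X_C
            target[i] = np.concatenate([S, U])
        f_raw[i] = physical.raw_factor(timestamp_to_date(post.created_time))
    return PostFeatures(
        ids=[p.id for p in posts],
        X_M=X_M,
        X_C=X_C,
        X_F=X_F,
        f=f_raw,
        u_post=u_post,
        env_sizes=env_sizes,
    )


def physical_bounds(features: PostFeatures, train_idx: np.ndarray) -> tuple[float, float]:
    """(min, max) of the raw physical factor over a training fold."""
    raw = features.f[train_idx]
    return float(raw.min()), float(raw.max())


def apply_physical_bounds(features: PostFeatures, bounds: tuple[float, float]) -> PostFeatures:
    """Min-max normalize the raw physical factor with given bounds, clipped."""
    lo, hi = bounds
    if hi > lo:
        f = np.clip((features.f - lo) / (hi - lo), 0.0, 1.0)
    else:
        f = np.zeros_like(features.f)
    return dataclasses.replace(features, f=f)


def normalize_physical(features: PostFeatures, train_idx: np.ndarray) -> PostFeatures:
    """Min-max normalize the raw physical factor with training-fold bounds."""
    return apply_physical_bounds(features, physical_bounds(features, train_idx))


@dataclass
class PreparedData:
    """A world with its fitted scorer and extracted (raw) features."""

    config: RunConfig
    scorer: UncertaintyScorer
    encoder: TextEncoder
    features: PostFeatures
    posts: list[PostRecord]
    y_detect: np.ndarray
    y_spread: np.ndarray
    days: np.ndarray

    def labels(self, task: str) -> np.ndarray:
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
        return self.y_detect if task == "detect" else self.y_spread


def prepare(
    world: GeneratedWorld,
    config: RunConfig | None = None,
    scorer: UncertaintyScorer | None = None,
) -> PreparedData:
    """Fit the scorer and extract features for every post of a world."""
    config = config or RunConfig()
    if scorer is None:
        scorer = fit_scorer(world.hedge_corpus, confidence_lambda=config.confidence_lambda)
    encoder = get_encoder(config.encoder, dim=config.embed_dim, seed=config.seed)
    features = extract_features(
        world.posts, world.news, world.tweets, world.case_series, scorer, encoder, config
    )
    return PreparedData(
        config=config,
        scorer=scorer,
        encoder=encoder,
        features=features,
        posts=list(world.posts),
        y_detect=np.array([p.veracity_label for p in world.posts], dtype=int),
        y_spread=np.array([p.spread_label for p in world.posts], dtype=int),
        days=np.array([timestamp_to_date(p.created_time).toordinal() for p in world.posts]),
    )


@dataclass
class TaskOutput:
    """One split/train/evaluate cycle."""

    task: str
    mode: str
    results: ClassifierResults
    metrics: dict[str, float]
    split: tuple[np.ndarray, np.ndarray, np.ndarray]
    y_test: np.ndarray
    test_probs: np.ndarray
    test_ids: list[str]
    f_bounds: tuple[float, float] = (0.0, 1.0)
    baseline_adapter: object | None = None


def train_eval(
    prepared: PreparedData,
    task: str = "detect",
    mode: str = "eup",
    seed: int = 0,
    drop_channels: Sequence[str] = (),
) -> TaskOutput:
    """Split, train and evaluate one classifier on a prepared world."""
    if mode not in ("eup", "fused"):
        raise ValueError("mode must be 'eup' or 'fused'")
    config = prepared.config
    y = prepared.labels(task)
    train_idx, val_idx, test_idx = split_by_day(prepared.days, derive_seed(seed, 1), labels=y)
    f_bounds = physical_bounds(prepared.features, train_idx)
    features = apply_physical_bounds(prepared.features, f_bounds)
    f_train = features.subset(train_idx)
    f_val = features.subset(val_idx)
    f_test = features.subset(test_idx)

    adapter = None
    if mode == "eup":
        model = EUPClassifier(f_train, y[train_idx], hidden_dim=config.hidden_dim, config=config)
        results = model.fit(
            seed=derive_seed(seed, 2),
            val_data=(f_val, y[val_idx]),
            drop_channels=drop_channels,
        )
        o_test = None
    else:
        adapter = HashingBaselineAdapter(
            encoder=get_encoder(config.encoder, dim=config.embed_dim, seed=config.seed + 1),
            dim=config.baseline_dim,
        )
        texts = [p.text for p in prepared.posts]
        adapter.fit([texts[i] for i in train_idx], y[train_idx], seed=derive_seed(seed, 3))
        o_all = adapter.features(texts)
        model = GatedFusionClassifier(
            f_train, y[train_idx], o_all[train_idx], hidden_dim=config.hidden_dim, config=config
        )
        results = model.fit(
            seed=derive_seed(seed, 2),
            val_data=(f_val, y[val_idx], o_all[val_idx]),
            drop_channels=drop_channels,
        )
        o_test = o_all[test_idx]

    metrics = results.evaluate(f_test, y[test_idx], baseline=o_test)
    probs = results.predict_proba(f_test, baseline=o_test)
    return TaskOutput(
        task=task,
        mode=mode,
        results=results,
        metrics=metrics,
        split=(train_idx, val_idx, test_idx),
        y_test=y[test_idx],
        test_probs=probs,
        test_ids=f_test.ids,
        f_bounds=f_bounds,
        baseline_adapter=adapter,
    )


def run_pipeline(
    world: GeneratedWorld,
    config: RunConfig | None = None,
    tasks: Sequence[str] = TASKS,
    mode: str = "eup",
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Full pipeline for one world; returns a metrics table per task."""
    prepared = prepare(world, config)
    return {
        task: train_eval(prepared, task=task, mode=mode, seed=seed).metrics for task in tasks
    }


def ablation_table(
    prepared: PreparedData,
    task: str = "detect",
    seeds: Sequence[int] = (0, 1, 2),
    channels: Sequence[str] = ("macro", "micro", "framing", "physical"),
    mode: str = "eup",
) -> pd.DataFrame:
    """Baseline vs single-channel-dropped accuracy, averaged over seeds."""
    rows = []
    for seed in seeds:
        base = train_eval(prepared, task=task, mode=mode, seed=seed)
        rows.append({"seed": seed, "dropped": "none", **base.metrics})
        for channel in channels:
            out = train_eval(prepared, task=task, mode=mode, seed=seed, drop_channels=(channel,))
            rows.append({"seed": seed, "dropped": channel, **out.metrics})
    return pd.DataFrame(rows)


def sweep(
    world: GeneratedWorld,
    config: RunConfig | None = None,
    param: str = "T",
    values: Sequence[float] = (1, 3, 5, 7, 9),
    task: str = "detect",
    seed: int = 0,
) -> pd.DataFrame:
    """Re-extract and retrain for each value of the window length T or the
    extraction fraction r; environments change, so features are rebuilt."""
    if param not in ("T", "r"):
        raise ValueError("param must be 'T' or 'r'")
    config = config or RunConfig()
    scorer = fit_scorer(world.hedge_corpus, confidence_lambda=config.confidence_lambda)
    rows = []
    for value in values:
        cfg = dataclasses.replace(config, **{param: type(getattr(config, param))(value)})
        prepared = prepare(world, cfg, scorer=scorer)
        out = train_eval(prepared, task=task, seed=seed)
        mean_sizes = prepared.features.env_sizes.mean(axis=0)
        rows.append(
            {
                param: value,
                "mean_macro_size": float(mean_sizes[0]),
                "mean_micro_size": float(mean_sizes[1]),
                **out.metrics,
            }
        )
    return pd.DataFrame(rows)
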
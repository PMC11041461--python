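"""Seeded synthetic infodemic worlds.

A *world* is everything the rest of the package consumes: a hedge-annotated
training corpus, a daily case/news timeline, day-stamped news and tweet
streams, and labeled posts.  The generative story:

* **Lexicon.**  A content vocabulary plus a small hedge lexicon.  Each
  hedge lemma ``w`` has a marker propensity ``π_w``: the probability that
  an occurrence of ``w`` is annotated as an uncertainty cue.  The corpus
  sentence flag is 1 iff the sentence contains any cue, so the count model
  can recover ``π_w`` from the corpus.

* **Timeline.**  Daily new cases follow an epidemic curve (exponential
  rise, plateau, decay) with Poisson noise; daily news volume rises with
  the curve.  The day-level physical uncertainty is the normalized
  ``ln(1+|Δcases|)·ln(1+|Δnews|)`` factor of the generated series — the
  same quantity the feature extractor computes — so the generative coupling
  targets exactly what the pipeline measures.

* **Streams.**  News items and tweets mix day-specific topic words with
  hedge lemmas; the hedge-insertion rate grows with the day's latent
  uncertainty.  Under ``coupling="shared"`` (default) both streams are
  driven by the physical factor; ``coupling="independent"`` gives each
  stream its own smooth AR(1) latent, decorrelating the channels so that
  single-channel worlds are identifiable in ablation experiments.

* **Posts.**  Each post has an idiosyncratic framing-uncertainty level
  ``u ~ Beta`` controlling its own hedge rate.  Veracity and spread labels
  are Bernoulli draws from a logistic model over the generator's latent
  channel intensities:
  ``P(fake) = σ(β0 + β_F·u + β_M·ū_macro + β_C·ū_micro + β_P·f_day)``,
  with ``ū_macro``/``ū_micro`` the volume-weighted mean stream latents over
  the post's trailing window.  A ``None`` intercept is auto-centred so the
  marginal label rate is ~0.5; all-zero slopes make labels independent of
  every feature.  Ground truth (latents, linear predictors, probabilities)
  is returned so label probabilities can be recomputed exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .data_io import (
    CaseDayRecord,
    DocumentRecord,
    HedgeSentence,
    PostRecord,
    UTC,
    write_case_series,
    write_documents,
    write_hedge_corpus,
    write_posts,
)

HEDGE_LEXICON = [
    "might", "may", "maybe", "possibly", "perhaps", "reportedly", "allegedly",
    "unclear", "apparently", "likely", "unlikely", "suggests", "rumored",
    "unconfirmed", "supposedly", "speculated", "uncertain", "probably",
    "presumably", "seemingly", "potentially", "arguably", "purportedly",
    "claimed", "doubtful", "conceivably", "ostensibly", "hinted", "suspected",
    "alleged",
]

CHANNEL_NAMES = ("framing", "macro", "micro", "physical")


@dataclass
class LabelModel:
    """Logistic coefficients of one binary label."""

    framing: float = 3.0
    macro: float = 3.0
    micro: float = 3.0
    physical: float = 3.0
    intercept: float | None = None  # None: auto-centre to a ~50% base rate

    def slopes(self) -> np.ndarray:
        return np.array([self.framing, self.macro, self.micro, self.physical])


@dataclass
class WorldConfig:
    seed: int = 0
    # lexicon
    vocab_size: int = 400
    n_marker_lemmas: int = 30
    marker_propensities: tuple[float, ...] | None = None   # default: drawn in (0.55, 0.95)
    # hedge corpus; per-sentence hedge rates are Beta-distributed so the
    # corpus spans plainly factual through heavily hedged sentences
    n_hedge_sentences: int = 5000
    hedge_marker_rate: float = 0.15          # mean per-sentence hedge rate
    hedge_rate_concentration: float = 3.0    # Beta a+b; lower = heavier tails
    hedge_len_mean: float = 20.0
    # timeline
    n_days: int = 90
    start_date: dt.date = dt.date(2020, 1, 1)
    rise_days: int = 20
    plateau_days: int = 20
    base_cases: float = 20.0
    peak_cases: float = 800.0
    weekend_dip: tuple[float, float] = (0.45, 0.4)  # Sat/Sun reporting multipliers
    flat_timeline: bool = False     # constant noise-free counts (null physical signal)
    news_per_day: float = 40.0
    tweets_per_day: float = 80.0
    # document text
    doc_len_mean: float = 24.0
    marker_base: float = 0.01
    marker_gain: float = 0.14
    n_topics: int = 10
    topic_size: int = 40
    topic_mix: float = 0.85
    coupling: str = "shared"        # "shared" | "independent"
    ar_rho: float = 0.8
    latent_sharpness: float = 1.0   # >1: bimodal quiet/eruptive stream days
    # posts
    n_posts: int = 4000
    post_len_mean: float = 30.0
    post_marker_base: float = 0.03
    post_marker_gain: float = 0.55
    post_margin_days: int = 10
    framing_alpha: float = 0.3
    framing_beta: float = 0.3
    label_window_days: int = 0      # labels couple to the same-day environment
    retweet_mean: float = 2.0
    detect: LabelModel = field(default_factory=LabelModel)
    spread: LabelModel = field(default_factory=LabelModel)

    def __post_init__(self) -> None:
        if self.coupling not in ("shared", "independent"):
            raise ValueError("coupling must be 'shared' or 'independent'")
        if self.marker_propensities is not None and len(self.marker_propensities) != self.n_marker_lemmas:
            raise ValueError("marker_propensities length must equal n_marker_lemmas")
        if self.label_window_days < 0:
            raise ValueError("label_window_days must be >= 0")
        if self.post_margin_days < max(self.label_window_days, 1):
            raise ValueError("post_margin_days must cover the label window")
        if self.post_margin_days >= self.n_days:
            raise ValueError("no days left for posts")
        for rate in (self.news_per_day, self.tweets_per_day, self.base_cases, self.peak_cases):
            if rate <= 0:
                raise ValueError("rates must be positive")


@dataclass
class GeneratedWorld:
    config: WorldConfig
    hedge_corpus: list[HedgeSentence]
    case_series: list[CaseDayRecord]
    news: list[DocumentRecord]
    tweets: list[DocumentRecord]
    posts: list[PostRecord]
    ground_truth: pd.DataFrame
    marker_lemmas: list[str]
    marker_propensities: np.ndarray
    day_table: pd.DataFrame

    def write(self, directory: str | Path) -> None:
        """Write the whole world in the formats the readers understand."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_posts(directory / "posts.jsonl", self.posts)
        write_documents(directory / "news.jsonl", self.news)
        write_documents(directory / "tweets.jsonl", self.tweets)
        write_case_series(directory / "cases.csv", self.case_series)
        write_hedge_corpus(directory / "hedge_corpus.jsonl", self.hedge_corpus)
        self.ground_truth.to_csv(directory / "ground_truth.csv", index=False)


def _epidemic_curve(cfg: WorldConfig) -> np.ndarray:
    decay_days = max(cfg.n_days - cfg.rise_days - cfg.plateau_days, 1)
    curve = np.empty(cfg.n_days)
    for d in range(cfg.n_days):
        if d < cfg.rise_days:
            curve[d] = cfg.base_cases * (cfg.peak_cases / cfg.base_cases) ** (d / cfg.rise_days)
        elif d < cfg.rise_days + cfg.plateau_days:
            curve[d] = cfg.peak_cases
        else:
            t = (d - cfg.rise_days - cfg.plateau_days) / decay_days
            curve[d] = cfg.peak_cases * (cfg.base_cases / cfg.peak_cases) ** t
    return curve


def _normalized_factor(cases: np.ndarray, news: np.ndarray) -> np.ndarray:
    raw = np.zeros(len(cases))
    raw[1:] = np.log1p(np.abs(np.diff(cases))) * np.log1p(np.abs(np.diff(news)))
    if len(cases) > 1:
        lo, hi = raw[1:].min(), raw[1:].max()
        if hi > lo:
            raw[1:] = (raw[1:] - lo) / (hi - lo)
        else:
            raw[1:] = 0.0
    raw[0] = 0.0
    return raw


def _ar1_z(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    z = np.empty(n)
    z[0] = rng.standard_normal()
    noise = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    for d in range(1, n):
        z[d] = rho * z[d - 1] + math.sqrt(1.0 - rho * rho) * noise[d - 1]
    return z


def _window_smooth(v: np.ndarray, width: int) -> np.ndarray:
    """Trailing moving average over ``width`` days (the label-window view)."""
    if width <= 1:
        return v
    cum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.maximum(np.arange(len(v)) - width + 1, 0)
    hi = np.arange(len(v)) + 1
    return (cum[hi] - cum[lo]) / (hi - lo)


def _orthogonalized(z: np.ndarray, others: list[np.ndarray], smooth_width: int = 1) -> np.ndarray:
    """Residualize ``z`` against ``others`` and restandardize.

    Independent latent *processes* still show sizeable empirical correlation
    over a few dozen days — and their trailing window means correlate even
    when the day series are orthogonal.  The regression coefficients are
    therefore computed between the *smoothed* (label-window) versions, so
    the realized window-mean drivers are orthogonal across channels: an
    orthogonal design rather than an in-expectation-independent one.
    """
    if others:
        X = np.column_stack([np.ones(len(z)), *others])
        Xs = np.column_stack([_window_smooth(X[:, j], smooth_width) for j in range(X.shape[1])])
        coef, *_ = np.linalg.lstsq(Xs, _window_smooth(z, smooth_width), rcond=None)
        z = z - X @ coef
    sd = z.std()
    if sd > 0:
        z = z / sd
    return z




class _TextSampler:
    """Shared token machinery for corpus, documents and posts."""

    def __init__(self, cfg: WorldConfig, rng_lexicon: np.random.Generator) -> None:
        self.cfg = cfg
        self.content = [f"term{i:03d}" for i in range(cfg.vocab_size)]
        markers = list(HEDGE_LEXICON)
        while len(markers) < cfg.n_marker_lemmas:
            markers.append(f"hedge{len(markers):02d}")
        self.markers = markers[: cfg.n_marker_lemmas]
        if cfg.marker_propensities is not None:
            self.propensities = np.asarray(cfg.marker_propensities, dtype=float)
        else:
            self.propensities = rng_lexicon.uniform(0.55, 0.95, size=cfg.n_marker_lemmas)
        weights = 1.0 / (np.arange(cfg.vocab_size) + 10.0)
        self.content_p = weights / weights.sum()
        # a global topic pool, independent of the calendar day
        self.topics = [
            rng_lexicon.choice(cfg.vocab_size, size=cfg.topic_size, replace=False)
            for _ in range(cfg.n_topics)
        ]

    def doc_text(self, rng: np.random.Generator, topic_id: int, marker_prob: float, length_mean: float) -> str:
        length = max(5, int(rng.poisson(length_mean)))
        topic = self.topics[topic_id]
        words = []
        for _ in range(length):
            if rng.random() < marker_prob:
                words.append(self.markers[rng.integers(len(self.markers))])
            elif rng.random() < self.cfg.topic_mix:
                words.append(self.content[topic[rng.integers(len(topic))]])
            else:
                words.append(self.content[rng.choice(self.cfg.vocab_size, p=self.content_p)])
        return " ".join(words)


def generate_world(config: WorldConfig | None = None, **overrides) -> GeneratedWorld:
    """Sample a complete world from ``config`` (all randomness from its seed)."""
    cfg = dataclasses.replace(config or WorldConfig(), **overrides) if overrides else (config or WorldConfig())
    children = np.random.SeedSequence(cfg.seed).spawn(7)
    rng_lex, rng_corpus, rng_time, rng_news, rng_tweets, rng_posts, rng_labels = (
        np.random.default_rng(s) for s in children
    )
    sampler = _TextSampler(cfg, rng_lex)

    # -- hedge corpus ------------------------------------------------------
    corpus: list[HedgeSentence] = []
    rate_a = cfg.hedge_marker_rate * cfg.hedge_rate_concentration
    rate_b = (1.0 - cfg.hedge_marker_rate) * cfg.hedge_rate_concentration
    for _ in range(cfg.n_hedge_sentences):
        length = 3 + int(rng_corpus.poisson(max(cfg.hedge_len_mean - 3, 1)))
        sentence_rate = float(rng_corpus.beta(rate_a, rate_b))
        tokens: list[str] = []
        flags: list[int] = []
        for _ in range(length):
            if rng_corpus.random() < sentence_rate:
                m = int(rng_corpus.integers(len(sampler.markers)))
                tokens.append(sampler.markers[m])
                flags.append(int(rng_corpus.random() < sampler.propensities[m]))
            else:
                tokens.append(sampler.content[rng_corpus.choice(cfg.vocab_size, p=sampler.content_p)])
                flags.append(0)
        corpus.append(HedgeSentence(tokens, list(tokens), flags, int(any(flags))))

    # -- timeline ----------------------------------------------------------
    D = cfg.n_days
    if cfg.flat_timeline:
        cases = np.full(D, int(cfg.base_cases))
        n_news_day = np.full(D, int(cfg.news_per_day))
    else:
        curve = _epidemic_curve(cfg)
        week = np.ones(7)
        week[5], week[6] = cfg.weekend_dip
        cycle = week[np.arange(D) % 7]
        cases = rng_time.poisson(curve * cycle)
        news_rate = cfg.news_per_day * (0.6 + 0.8 * curve / cfg.peak_cases) * cycle
        n_news_day = rng_time.poisson(news_rate)
    n_tweets_day = (
        np.full(D, int(cfg.tweets_per_day))
        if cfg.flat_timeline
        else rng_time.poisson(np.full(D, float(cfg.tweets_per_day)))
    )
    f_day = _normalized_factor(cases.astype(float), n_news_day.astype(float))
    if cfg.coupling == "shared":
        lat_news = f_day.copy()
        lat_tweet = f_day.copy()
    else:
        zf = f_day - f_day.mean()
        width = cfg.label_window_days + 1
        z_news = _orthogonalized(_ar1_z(rng_time, D, cfg.ar_rho), [zf], smooth_width=width)
        z_tweet = _orthogonalized(
            _ar1_z(rng_time, D, cfg.ar_rho), [zf, z_news], smooth_width=width
        )
        lat_news = ndtr(cfg.latent_sharpness * z_news)
        lat_tweet = ndtr(cfg.latent_sharpness * z_tweet)

    case_series = [
        CaseDayRecord(cfg.start_date + dt.timedelta(days=d), int(cases[d]), int(n_news_day[d]))
        for d in range(D)
    ]

    def day_epoch(d: int) -> float:
        return dt.datetime.combine(cfg.start_date + dt.timedelta(days=d), dt.time(), UTC).timestamp()

    # -- streams -----------------------------------------------------------
    def make_stream(rng, prefix, day_counts, latent, kind):
        docs: list[DocumentRecord] = []
        doc_days: list[int] = []
        for d in range(D):
            m_prob = cfg.marker_base + cfg.marker_gain * latent[d]
            for i in range(int(day_counts[d])):
                docs.append(
                    DocumentRecord(
                        id=f"{prefix}-{d:03d}-{i:04d}",
                        text=sampler.doc_text(
                            rng, int(rng.integers(cfg.n_topics)), m_prob, cfg.doc_len_mean
                        ),
                        created_time=float(int(day_epoch(d) + rng.uniform(0, 86400))),
                        source_kind=kind,
                    )
                )
                doc_days.append(d)
        return docs, np.array(doc_days, dtype=int)

    news, news_days = make_stream(rng_news, "news", n_news_day, lat_news, "news")
    tweets, tweet_days = make_stream(rng_tweets, "tweet", n_tweets_day, lat_tweet, "tweet")

    # -- posts -------------------------------------------------------------
    n = cfg.n_posts
    days = rng_posts.integers(cfg.post_margin_days, D, size=n)
    times = np.floor(
        np.array([day_epoch(int(d)) for d in days]) + rng_posts.uniform(0, 86400, size=n)
    )
    u_post = rng_posts.beta(cfg.framing_alpha, cfg.framing_beta, size=n)
    W = cfg.label_window_days

    def env_latent_means(docs, doc_days, latent) -> np.ndarray:
        # mean stream latent over exactly the documents inside each post's
        # closed trailing window -- the quantity the extractor averages
        doc_times = np.array([doc.created_time for doc in docs])
        order = np.argsort(doc_times, kind="stable")
        doc_times = doc_times[order]
        values = latent[doc_days[order]]
        cum = np.concatenate([[0.0], np.cumsum(values)])
        lo = np.searchsorted(doc_times, times - W * 86400.0, side="left")
        hi = np.searchsorted(doc_times, times, side="right")
        out = np.where(hi > lo, (cum[hi] - cum[lo]) / np.maximum(hi - lo, 1), latent[days])
        return out

    if W == 0:
        u_macro = lat_news[days]
        u_micro = lat_tweet[days]
    else:
        u_macro = env_latent_means(news, news_days, lat_news)
        u_micro = env_latent_means(tweets, tweet_days, lat_tweet)
    f_post = f_day[days]

    posts: list[PostRecord] = []
    latents = np.column_stack([u_post, u_macro, u_micro, f_post])

    def draw_labels(model: LabelModel, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float]:
        lp = latents @ model.slopes()
        intercept = -float(lp.mean()) if model.intercept is None else model.intercept
        probs = expit(intercept + lp)
        return (rng.random(n) < probs).astype(int), probs, intercept

    fake, p_fake, b0_detect = draw_labels(cfg.detect, rng_labels)
    high, p_high, b0_spread = draw_labels(cfg.spread, rng_labels)
    retweets = np.where(high == 1, 1 + rng_labels.poisson(cfg.retweet_mean, size=n), 0)

    for i in range(n):
        d = int(days[i])
        m_prob = cfg.post_marker_base + cfg.post_marker_gain * u_post[i]
        posts.append(
            PostRecord(
                id=f"post-{i:05d}",
                text=sampler.doc_text(
                    rng_posts, int(rng_posts.integers(cfg.n_topics)), m_prob, cfg.post_len_mean
                ),
                created_time=float(times[i]),
                retweet_count=int(retweets[i]),
                veracity_label=int(fake[i]),
                spread_label=int(high[i]),
            )
        )

    ground_truth = pd.DataFrame(
        {
            "id": [p.id for p in posts],
            "day": days,
            "u_post": u_post,
            "u_macro": u_macro,
            "u_micro": u_micro,
            "f_day": f_post,
            "p_fake": p_fake,
            "veracity_label": fake,
            "p_high": p_high,
            "spread_label": high,
            "intercept_detect": b0_detect,
            "intercept_spread": b0_spread,
        }
    )
    day_table = pd.DataFrame(
        {
            "day": np.arange(D),
            "date": [cfg.start_date + dt.timedelta(days=d) for d in range(D)],
            "n_cases": cases,
            "n_news": n_news_day,
            "n_tweets": n_tweets_day,
            "f_day": f_day,
            "lat_news": lat_news,
            "lat_tweet": lat_tweet,
        }
    )
    return GeneratedWorld(
        config=cfg,
        hedge_corpus=corpus,
        case_series=case_series,
        news=news,
        tweets=tweets,
        posts=posts,
        ground_truth=ground_truth,
        marker_lemmas=list(sampler.markers),
        marker_propensities=sampler.propensities,
        day_table=day_table,
    )


def single_signal_world(
    channel: str,
    strength: float,
    config: WorldConfig | None = None,
) -> GeneratedWorld:
    """A world in which exactly one channel carries label signal.

    All logistic slopes are zero except the named channel's, for both the
    veracity and the spread label, and the stream latents are decorrelated
    (``coupling="independent"``) so the signal is attributable to that
    channel alone.
    """
    if channel not in CHANNEL_NAMES:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNEL_NAMES}")
    cfg = config or WorldConfig()
    coeffs = {name: (strength if name == channel else 0.0) for name in CHANNEL_NAMES}
    cfg = dataclasses.replace(
        cfg,
        coupling="independent",
        ar_rho=0.0,            # iid day latents: label-rate memory dies with the window
        latent_sharpness=3.0,  # bimodal quiet/eruptive days: clear per-channel signal
        label_window_days=3,   # couple to the window-mean the channels measure
        detect=LabelModel(**coeffs, intercept=None),
        spread=LabelModel(**coeffs, intercept=None),
    )
    return generate_world(cfg)
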
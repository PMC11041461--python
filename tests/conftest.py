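import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from eupkit.data_io import HedgeSentence, RunConfig
from eupkit.pipeline import prepare
from eupkit.synthetic_data import WorldConfig, generate_world
from eupkit.uncertainty_model import fit_scorer


@pytest.fixture
def toy_corpus():
    """Three sentences with hand-countable n-gram statistics."""
    return [
        HedgeSentence(["maybe", "rain"], ["maybe", "rain"], [1, 0], 1),
        HedgeSentence(["maybe", "later"], ["maybe", "later"], [1, 0], 1),
        HedgeSentence(["no", "rain"], ["no", "rain"], [0, 0], 0),
    ]


def small_world_config(seed: int = 42, **overrides) -> WorldConfig:
    defaults = dict(
        seed=seed,
        n_days=45,
        n_posts=250,
        n_hedge_sentences=500,
        news_per_day=8.0,
        tweets_per_day=16.0,
    )
    defaults.update(overrides)
    return WorldConfig(**defaults)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(small_world_config())


@pytest.fixture(scope="session")
def small_prepared(small_world):
    return prepare(small_world, RunConfig())


@pytest.fixture(scope="session")
def small_scorer(small_world):
    return fit_scorer(small_world.hedge_corpus)


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
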
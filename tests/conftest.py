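from datetime import date

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import worksent as ws

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def tweet(text: str, tweet_id: str = "t0", day: date = date(2020, 6, 1)) -> ws.RawTweet:
    return ws.RawTweet(tweet_id, day, text)


@pytest.fixture
def make_tweet():
    counter = iter(range(10_000))

    def _make(text: str) -> ws.RawTweet:
        return tweet(text, tweet_id=f"t{next(counter)}")

    return _make


@pytest.fixture
def toy_vectors() -> ws.WordVectorTable:
    """Five words with hand-set geometry: job/work/office cluster along e1,
    cat/dog cluster along e2; within-cluster cosines are known by construction."""
    return ws.WordVectorTable(
        {
            "work": np.array([1.0, 0.0, 0.0]),
            "job": np.array([0.9, 0.1, 0.0]),
            "office": np.array([0.8, 0.0, 0.2]),
            "cat": np.array([0.0, 1.0, 0.0]),
            "dog": np.array([0.1, 0.9, 0.0]),
        }
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A modest generated corpus shared by read-only tests."""
    spec = ws.default_spec(seed=5, n_tweets=400)
    corpus, truth = ws.generate_corpus(spec)
    return spec, corpus, truth
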
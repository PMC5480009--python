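import pytest

from screensent.synthetic import (
    CorpusConfig,
    LexiconSpec,
    RetweetParams,
    generate_corpus,
)

SMALL_LEX = LexiconSpec(
    positive=("awareness", "detection", "saves", "recommend", "health"),
    negative=("painful", "worried", "dread", "hurts", "awful"),
    neutral=("doctor", "today", "appointment", "week", "results",
             "clinic", "going", "year", "time", "people"),
    mixing_weights={"positive": 0.4, "negative": 0.4, "neutral": 0.0},
)


def make_config(**overrides) -> CorpusConfig:
    defaults = dict(
        n_tweets=300,
        modality="colonoscopy",
        true_proportions=(0.3, 0.3, 0.4),
        lexicons=SMALL_LEX,
        tweet_length=8.0,
        retweet_params={
            "positive": RetweetParams(1.0, 0.8),
            "negative": RetweetParams(2.0, 0.8),
            "neutral": RetweetParams(1.0, 0.8),
        },
        arrival_rates={"positive": 40.0, "negative": 40.0, "neutral": 40.0},
        seed=7,
    )
    defaults.update(overrides)
    return CorpusConfig(**defaults)


@pytest.fixture
def small_corpus():
    return generate_corpus(make_config())
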
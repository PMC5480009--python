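"""Synthetic microblog corpus generator with known latent sentiment structure.

Generates tweet-like records for one screening modality: latent sentiment
drawn from configurable proportions, text sampled from sentiment-loaded
lexicons mixed with neutral vocabulary, retweet counts drawn from
sentiment-specific negative binomials, and per-sentiment Poisson counts of
new (original) tweets.  Every downstream stage of the pipeline is testable
against the latent truth this module records.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .lexicons import NEGATIVE_LEXICON, NEUTRAL_VOCABULARY, POSITIVE_LEXICON

SENTIMENTS: tuple[str, str, str] = ("positive", "negative", "neutral")
MODALITIES: tuple[str, str, str] = ("colonoscopy", "mammography", "pap_smear")

__all__ = [
    "SENTIMENTS",
    "MODALITIES",
    "RetweetParams",
    "LexiconSpec",
    "CorpusConfig",
    "TweetRecord",
    "generate_corpus",
    "sample_retweet_counts",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "write_truth_csv",
    "modality_presets",
]


@dataclass(frozen=True)
class RetweetParams:
    """Negative-binomial retweet distribution: mean ``mu`` >= 0, dispersion
    ``k`` > 0, variance ``mu + mu**2 / k`` (small ``k`` = heavy heterogeneity)."""

    mu: float
    k: float

    def validate(self, name: str = "retweet_params") -> None:
        if self.mu < 0:
            raise ValueError(f"{name}.mu must be >= 0, got {self.mu}")
        if self.k <= 0:
            raise ValueError(f"{name}.k must be > 0, got {self.k}")


@dataclass(frozen=True)
class LexiconSpec:
    """Token pools for text generation.

    Each sentiment's tweet text mixes its loaded lexicon (weight ``w``) with
    the shared neutral vocabulary (weight ``1 - w``); neutral tweets draw
    from the neutral vocabulary alone.  The three pools must be pairwise
    disjoint so latent classes are identifiable.
    """

    positive: tuple[str, ...] = POSITIVE_LEXICON
    negative: tuple[str, ...] = NEGATIVE_LEXICON
    neutral: tuple[str, ...] = NEUTRAL_VOCABULARY
    mixing_weights: dict[str, float] = field(
        default_factory=lambda: {"positive": 0.4, "negative": 0.4, "neutral": 0.0}
    )

    def validate(self) -> None:
        pools = {"positive": set(self.positive), "negative": set(self.negative),
                 "neutral": set(self.neutral)}
        names = list(pools)
        for i, a in enumerate(names):
            if not pools[a]:
                raise ValueError(f"lexicons.{a} must be non-empty")
            for b in names[i + 1:]:
                overlap = pools[a] & pools[b]
                if overlap:
                    raise ValueError(
                        f"lexicons.{a} and lexicons.{b} overlap: {sorted(overlap)[:5]}"
                    )
        for s in SENTIMENTS:
            w = self.mixing_weights.get(s, 0.0)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"lexicons.mixing_weights[{s!r}] must be in [0, 1], got {w}")

    def pool(self, sentiment: str) -> tuple[str, ...]:
        return {"positive": self.positive, "negative": self.negative,
                "neutral": self.neutral}[sentiment]


@dataclass(frozen=True)
class CorpusConfig:
    """Full recipe for one modality sub-corpus."""

    n_tweets: int
    modality: str
    true_proportions: tuple[float, float, float]  # (p_pos, p_neg, p_neu)
    lexicons: LexiconSpec = field(default_factory=LexiconSpec)
    tweet_length: float = 11.0  # mean tokens per tweet (Poisson, min 3)
    retweet_params: dict[str, RetweetParams] = field(
        default_factory=lambda: {s: RetweetParams(1.0, 0.8) for s in SENTIMENTS}
    )
    arrival_rates: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in SENTIMENTS}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_tweets < 0:
            raise ValueError(f"n_tweets must be >= 0, got {self.n_tweets}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        p = self.true_proportions
        if len(p) != 3 or any(pi < 0 or pi > 1 for pi in p):
            raise ValueError(f"true_proportions entries must lie in [0, 1], got {p}")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError(
                f"true_proportions must sum to 1 (tolerance 1e-9), got sum={sum(p)!r}"
            )
        self.lexicons.validate()
        if self.tweet_length <= 0:
            raise ValueError(f"tweet_length must be > 0, got {self.tweet_length}")
        for s in SENTIMENTS:
            self.retweet_params[s].validate(f"retweet_params[{s!r}]")
            if self.arrival_rates.get(s, 0.0) < 0:
                raise ValueError(f"arrival_rates[{s!r}] must be >= 0")


@dataclass
class TweetRecord:
    """One message: text, retweet count, modality, originality flag, and —
    for synthetic or manually labeled data only — the true sentiment."""

    id: str
    text: str
    modality: str
    retweet_count: int
    is_original: bool
    true_sentiment: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "TweetRecord":
        return cls(**json.loads(line))


def sample_retweet_counts(
    mu: float, k: float, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """Draw ``n`` retweet counts from a negative binomial with mean ``mu``
    and dispersion ``k`` (variance ``mu + mu**2/k``).

    ``mu = 0`` degenerates to all zeros; ``k -> inf`` approaches Poisson.
    """
    if k <= 0:
        raise ValueError(f"dispersion k must be > 0, got {k}")
    if mu < 0:
        raise ValueError(f"mean mu must be >= 0, got {mu}")
    if n < 0:
        raise ValueError(f"sample size n must be >= 0, got {n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if mu == 0:
        return np.zeros(n, dtype=np.int64)
    # NB(mu, k) == Poisson mixed over Gamma(shape=k, scale=mu/k) rates
    return rng.negative_binomial(n=k, p=k / (k + mu), size=n).astype(np.int64)


def _draw_texts(
    rng: np.random.Generator,
    sentiment: str,
    lengths: np.ndarray,
    lex: LexiconSpec,
) -> list[str]:
    """Vectorized text generation for all tweets of one sentiment.

    Each token is drawn i.i.d. from the mixture: weight ``w`` on the
    sentiment's loaded lexicon, ``1 - w`` on the neutral vocabulary.
    """
    w = lex.mixing_weights.get(sentiment, 0.0)
    loaded = np.asarray(lex.pool(sentiment), dtype=object)
    neutral = np.asarray(lex.neutral, dtype=object)
    total = int(lengths.sum())
    from_loaded = rng.random(total) < w
    loaded_pick = rng.integers(len(loaded), size=total)
    neutral_pick = rng.integers(len(neutral), size=total)
    tokens = np.where(from_loaded, loaded[loaded_pick], neutral[neutral_pick])
    texts = []
    start = 0
    for L in lengths:
        texts.append(" ".join(tokens[start:start + L]))
        start += L
    return texts


def generate_corpus(config: CorpusConfig) -> list[TweetRecord]:
    """Generate ``config.n_tweets`` records with latent sentiment recorded.

    Deterministic: the same config (including seed) reproduces byte-identical
    output.  Stage-level sub-streams (sentiment draw, text, retweets,
    originality) are derived from one top-level seed so each stage is
    reproducible in isolation.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_sent, rng_text, rng_rt, rng_orig = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    n = config.n_tweets
    p = np.asarray(config.true_proportions, dtype=float)
    p = p / p.sum()  # exact renormalization inside the 1e-9 tolerance
    sent_idx = rng_sent.choice(3, size=n, p=p)
    lengths = np.maximum(3, rng_text.poisson(config.tweet_length, size=n))

    # Per-sentiment Poisson arrival of new original tweets, capped at the
    # number of records carrying that sentiment.
    orig_flags = np.zeros(n, dtype=bool)
    for si, s in enumerate(SENTIMENTS):
        idx = np.flatnonzero(sent_idx == si)
        rate = config.arrival_rates.get(s, 0.0)
        n_orig = int(min(len(idx), rng_orig.poisson(rate))) if rate > 0 else 0
        if n_orig:
            chosen = rng_orig.choice(idx, size=n_orig, replace=False)
            orig_flags[chosen] = True

    retweets = np.zeros(n, dtype=np.int64)
    texts: list[str] = [""] * n
    for si, s in enumerate(SENTIMENTS):
        idx = np.flatnonzero(sent_idx == si)
        rp = config.retweet_params[s]
        retweets[idx] = sample_retweet_counts(rp.mu, rp.k, len(idx), rng_rt)
        for j, text in zip(idx, _draw_texts(rng_text, s, lengths[idx], config.lexicons)):
            texts[j] = text

    return [
        TweetRecord(
            id=f"{config.modality}-{config.seed}-{i:06d}",
            text=texts[i],
            modality=config.modality,
            retweet_count=int(retweets[i]),
            is_original=bool(orig_flags[i]),
            true_sentiment=SENTIMENTS[sent_idx[i]],
        )
        for i in range(n)
    ]


def write_corpus_jsonl(records: Iterable[TweetRecord], path) -> None:
    """Write records as UTF-8 JSON Lines, one record per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_corpus_jsonl(path) -> list[TweetRecord]:
    with open(path, encoding="utf-8") as fh:
        return [TweetRecord.from_json(line) for line in fh if line.strip()]


def write_truth_csv(records: Sequence[TweetRecord], path) -> None:
    """Accompanying truth table: id, true_sentiment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id,true_sentiment\n")
        for rec in records:
            fh.write(f"{rec.id},{rec.true_sentiment or ''}\n")


def modality_presets(
    n_tweets: int = 2500, seed: int = 0
) -> dict[str, CorpusConfig]:
    """Default study conditions for the three modality sub-corpora.

    The presets encode the qualitative regime the study design targets:
    colonoscopy chatter skews negative with negative messages both arriving
    more often and spreading more; mammography chatter skews positive but its
    rarer negative messages spread more; Pap-smear chatter is symmetric in
    proportions, arrival and spread.
    """
    base_k = 0.8
    presets = {
        "colonoscopy": CorpusConfig(
            n_tweets=n_tweets,
            modality="colonoscopy",
            true_proportions=(0.17, 0.28, 0.55),
            retweet_params={
                "positive": RetweetParams(1.0, base_k),
                "negative": RetweetParams(2.2, base_k),
                "neutral": RetweetParams(1.2, base_k),
            },
            arrival_rates={
                "positive": 0.045 * n_tweets,
                "negative": 0.085 * n_tweets,
                "neutral": 0.15 * n_tweets,
            },
            seed=seed,
        ),
        "mammography": CorpusConfig(
            n_tweets=n_tweets,
            modality="mammography",
            true_proportions=(0.30, 0.13, 0.57),
            retweet_params={
                "positive": RetweetParams(1.0, base_k),
                "negative": RetweetParams(2.5, base_k),
                "neutral": RetweetParams(1.2, base_k),
            },
            arrival_rates={
                "positive": 0.09 * n_tweets,
                "negative": 0.03 * n_tweets,
                "neutral": 0.15 * n_tweets,
            },
            seed=seed + 1,
        ),
        "pap_smear": CorpusConfig(
            n_tweets=n_tweets,
            modality="pap_smear",
            true_proportions=(0.20, 0.20, 0.60),
            retweet_params={
                "positive": RetweetParams(1.2, base_k),
                "negative": RetweetParams(1.2, base_k),
                "neutral": RetweetParams(1.2, base_k),
            },
            arrival_rates={
                "positive": 0.06 * n_tweets,
                "negative": 0.06 * n_tweets,
                "neutral": 0.15 * n_tweets,
            },
            seed=seed + 2,
        ),
    }
    return presets
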
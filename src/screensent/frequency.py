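"""Word-frequency analysis of original tweets by sentiment class."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .lexicons import MODALITY_QUERY_TERMS, STOPWORDS
from .synthetic import TweetRecord
from .tokenizer import tokenize

__all__ = ["FrequencyTable", "word_frequencies"]


@dataclass
class FrequencyTable:
    """Ranked token counts for one sentiment class.

    Entries are (token, count, rank) with counts non-increasing, ranks
    consecutive from 1, and count ties broken lexicographically.
    """

    sentiment: str
    entries: list[tuple[str, int, int]]
    n_docs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.sentiment, rank, token, count) for token, count, rank in self.entries],
            columns=["sentiment", "rank", "token", "count"],
        )

    def to_dict(self) -> dict:
        return {
            "sentiment": self.sentiment,
            "n_docs": self.n_docs,
            "entries": [
                {"token": t, "count": c, "rank": r} for t, c, r in self.entries
            ],
        }


def word_frequencies(
    tweets: Sequence[TweetRecord],
    labels: Sequence[str],
    sentiment: str,
    stopwords: Iterable[str] | None = None,
    top_k: int = 25,
    extra_exclude: Iterable[str] = (),
) -> FrequencyTable:
    """Top-k token counts over original tweets carrying one sentiment.

    Only records with ``is_original`` contribute; stopwords and the
    modality's own search keywords are excluded so the query terms do not
    dominate their own corpus.  ``stopwords=None`` uses the built-in list.
    An empty match set yields an empty table, not an error.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if len(tweets) != len(labels):
        raise ValueError("tweets and labels have different lengths")
    stop = STOPWORDS if stopwords is None else frozenset(stopwords)
    exclude = set(stop) | set(extra_exclude)
    modalities = {t.modality for t in tweets}
    for m in modalities:
        exclude |= MODALITY_QUERY_TERMS.get(m, frozenset())

    counter: Counter[str] = Counter()
    n_docs = 0
    for tweet, label in zip(tweets, labels):
        if label != sentiment or not tweet.is_original:
            continue
        n_docs += 1
        counter.update(tok for tok in tokenize(tweet.text) if tok not in exclude)

    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    entries = [(token, count, rank) for rank, (token, count) in enumerate(ranked, 1)]
    return FrequencyTable(sentiment=sentiment, entries=entries, n_docs=n_docs)
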
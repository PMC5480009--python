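"""Dual-classifier sentiment labeling: train/test protocol and validation.

Two binary naive Bayes models trained on the same labeled pool — positive vs
nonpositive and negative vs nonnegative — are combined into a three-way
positive/negative/neutral label.  A held-out, label-stratified test split
yields the 3x3 confusion table (manual label x pipeline label) that drives
the downstream misclassification correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .naive_bayes import MultinomialNaiveBayes
from .synthetic import TweetRecord
from .tokenizer import tokenize

LABELS: tuple[str, str, str] = ("positive", "negative", "neutral")

__all__ = [
    "LABELS",
    "ConfusionTable",
    "ClassifiedCorpus",
    "DualNaiveBayesSentiment",
    "split_train_test",
    "combine_binary",
    "classify_corpus",
    "evaluate",
]


@dataclass
class ConfusionTable:
    """3x3 counts: rows = manual (true) label, columns = pipeline label,
    both ordered (positive, negative, neutral)."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValueError(f"confusion table must be 3x3, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion table entries must be >= 0")
        if self.counts.sum() == 0:
            raise ValueError("confusion table must contain at least one observation")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.n_total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(LABELS), columns=list(LABELS))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="manual")

    @classmethod
    def from_csv(cls, path) -> "ConfusionTable":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.loc[list(LABELS), list(LABELS)].to_numpy())


@dataclass(frozen=True)
class ClassifiedCorpus:
    """Pipeline-classified counts for one modality sub-corpus."""

    n_pos: int
    n_neg: int
    n_neu: int
    modality: str = ""

    def __post_init__(self):
        if min(self.n_pos, self.n_neg, self.n_neu) < 0:
            raise ValueError("classified counts must be >= 0")
        if self.n_total < 1:
            raise ValueError("classified corpus must contain at least one tweet")

    @property
    def n_total(self) -> int:
        return self.n_pos + self.n_neg + self.n_neu

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.n_pos, self.n_neg, self.n_neu], dtype=np.int64)


def combine_binary(is_positive: bool, is_negative: bool) -> str:
    """Merge the two binary decisions into one three-way label.

    positive & nonnegative -> positive; negative & nonpositive -> negative;
    nonpositive & nonnegative -> neutral.  The contradictory (positive,
    negative) pair falls back to neutral — a conservative tie rule.
    """
    if is_positive and not is_negative:
        return "positive"
    if is_negative and not is_positive:
        return "negative"
    return "neutral"


def split_train_test(
    records: Sequence, labels: Sequence[str], train_fraction: float, seed: int
) -> tuple[list, list, list[str], list[str]]:
    """Label-stratified, seeded, disjoint and exhaustive train/test partition.

    The train size is ``round(train_fraction * n)`` overall; per-stratum
    allocations use largest-remainder rounding so each manual label is
    represented in both partitions.  Returns
    ``(train_records, test_records, train_labels, test_labels)``.
    """
    n = len(records)
    if n != len(labels):
        raise ValueError("records and labels have different lengths")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if n < 2:
        raise ValueError("need at least 2 records to split")

    labels = list(labels)
    strata: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        strata.setdefault(lab, []).append(i)
    for lab, idx in strata.items():
        if len(idx) < 2:
            raise ValueError(f"label stratum {lab!r} has fewer than 2 records")

    n_train_total = int(round(train_fraction * n))
    n_train_total = min(max(n_train_total, len(strata)), n - len(strata))

    # largest-remainder allocation of the train quota across strata,
    # keeping >= 1 record of every stratum on each side
    keys = sorted(strata)
    quotas = {lab: train_fraction * len(strata[lab]) for lab in keys}
    alloc = {lab: int(np.floor(quotas[lab])) for lab in keys}
    for lab in keys:
        alloc[lab] = min(max(alloc[lab], 1), len(strata[lab]) - 1)
    remainders = sorted(
        keys, key=lambda lab: (-(quotas[lab] - np.floor(quotas[lab])), lab)
    )
    i = 0
    while sum(alloc.values()) < n_train_total and i < 10 * len(keys):
        lab = remainders[i % len(keys)]
        if alloc[lab] < len(strata[lab]) - 1:
            alloc[lab] += 1
        i += 1
    while sum(alloc.values()) > n_train_total:
        lab = max(keys, key=lambda L: (alloc[L] - quotas[L], L))
        if alloc[lab] > 1:
            alloc[lab] -= 1
        else:
            break

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lab in keys:
        idx = np.array(strata[lab])
        rng.shuffle(idx)
        train_idx.extend(idx[: alloc[lab]].tolist())
        test_idx.extend(idx[alloc[lab]:].tolist())
    train_idx.sort()
    test_idx.sort()
    return (
        [records[i] for i in train_idx],
        [records[i] for i in test_idx],
        [labels[i] for i in train_idx],
        [labels[i] for i in test_idx],
    )


class DualNaiveBayesSentiment(BaseEstimator, ClassifierMixin):
    """Two binary NB classifiers over one labeled pool, combined three ways.

    The positive-vs-nonpositive and negative-vs-nonnegative models are
    trained on the same documents with dichotomized labels; prediction runs
    both and merges the decisions with :func:`combine_binary`.  Accepts raw
    text (tokenized internally) or pre-tokenized documents.

    Parameters
    ----------
    alpha : float, default=1.0
        Laplace smoothing shared by both binary models.
    """

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    @staticmethod
    def _to_docs(X: Iterable) -> list[list[str]]:
        return [tokenize(x) if isinstance(x, str) else list(x) for x in X]

    def fit(self, X: Iterable, y: Sequence[str]) -> "DualNaiveBayesSentiment":
        y = list(y)
        bad = sorted(set(y) - set(LABELS))
        if bad:
            raise ValueError(f"unknown sentiment labels: {bad}")
        docs = self._to_docs(X)
        y_pos = ["positive" if lab == "positive" else "nonpositive" for lab in y]
        y_neg = ["negative" if lab == "negative" else "nonnegative" for lab in y]
        self.pos_model_ = MultinomialNaiveBayes(
            alpha=self.alpha, tie_break="nonpositive"
        ).fit(docs, y_pos)
        self.neg_model_ = MultinomialNaiveBayes(
            alpha=self.alpha, tie_break="nonnegative"
        ).fit(docs, y_neg)
        self.classes_ = np.array(LABELS, dtype=object)
        return self

    def predict(self, X: Iterable) -> np.ndarray:
        docs = self._to_docs(X)
        is_pos = self.pos_model_.predict(docs) == "positive"
        is_neg = self.neg_model_.predict(docs) == "negative"
        return np.array(
            [combine_binary(p, n) for p, n in zip(is_pos, is_neg)], dtype=object
        )

    def predict_scores(self, X: Iterable) -> pd.DataFrame:
        """Per-classifier joint log-likelihood scores for each document."""
        docs = self._to_docs(X)
        jp = self.pos_model_.joint_log_likelihood(docs)
        jn = self.neg_model_.joint_log_likelihood(docs)
        cols = {}
        for model, jll, tag in ((self.pos_model_, jp, "pos"), (self.neg_model_, jn, "neg")):
            for ci, c in enumerate(model.classes_):
                cols[f"{tag}:{c}"] = jll[:, ci]
        return pd.DataFrame(cols)


def classify_corpus(
    model: DualNaiveBayesSentiment, tweets: Sequence[TweetRecord]
) -> tuple[list[str], ClassifiedCorpus]:
    """Label every tweet and aggregate counts for the modality.

    Each tweet is tokenized once and run through both binary models.
    """
    labels = model.predict([t.text for t in tweets]).tolist()
    modality = tweets[0].modality if tweets else ""
    counts = {lab: labels.count(lab) for lab in LABELS}
    corpus = ClassifiedCorpus(
        n_pos=counts["positive"], n_neg=counts["negative"],
        n_neu=counts["neutral"], modality=modality,
    )
    return labels, corpus


def evaluate(
    model: DualNaiveBayesSentiment,
    test_tweets: Sequence[TweetRecord],
    manual_labels: Sequence[str],
) -> tuple[ConfusionTable, float]:
    """Confusion table (manual x pipeline) and accuracy on a held-out set."""
    if len(test_tweets) == 0:
        raise ValueError("test set is empty")
    if len(test_tweets) != len(manual_labels):
        raise ValueError("test set and manual labels have different lengths")
    predicted = model.predict([t.text for t in test_tweets])
    index = {lab: i for i, lab in enumerate(LABELS)}
    counts = np.zeros((3, 3), dtype=np.int64)
    for truth, pred in zip(manual_labels, predicted):
        counts[index[truth], index[pred]] += 1
    table = ConfusionTable(counts)
    return table, table.accuracy
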
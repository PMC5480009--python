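"""From-scratch multinomial naive Bayes for one binary sentiment decision.

The estimator follows scikit-learn conventions (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) but the
probability model — class log-priors plus Laplace-smoothed per-class token
log-likelihoods over a vocabulary fixed at training — is implemented here
directly.  Documents are ragged token lists, not count matrices, so the
estimator sits upstream of any vectorizer.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

TokenDoc = Sequence[str]

__all__ = ["MultinomialNaiveBayes", "train_nb", "predict_nb"]


class MultinomialNaiveBayes(BaseEstimator, ClassifierMixin):
    """Binary multinomial naive Bayes with Laplace (add-alpha) smoothing.

    Parameters
    ----------
    alpha : float, default=1.0
        Additive smoothing pseudo-count; must be > 0.
    tie_break : str or None, default=None
        Label returned when the two class scores are exactly equal.  The
        sentiment pipeline sets this to the negative-evidence ("non") class
        so ties never manufacture polar sentiment.  ``None`` falls back to
        the lexicographically smaller label.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels.
    class_log_prior_ : ndarray of shape (2,)
        Log of training class frequencies; ``exp`` sums to 1.
    vocabulary_ : dict[str, int]
        Token -> column index, fixed at fit time.
    feature_log_prob_ : ndarray of shape (2, n_vocab)
        Smoothed log P(token | class); per class, ``exp`` sums to 1.
    """

    def __init__(self, alpha: float = 1.0, tie_break: str | None = None):
        self.alpha = alpha
        self.tie_break = tie_break

    # ------------------------------------------------------------------ fit
    def fit(self, X: Iterable[TokenDoc], y: Sequence) -> "MultinomialNaiveBayes":
        """Fit priors and smoothed token likelihoods from token documents.

        P(t | c) = (count(t, c) + alpha) / (tokens in c + alpha * |V|).
        """
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        docs = [list(d) for d in X]
        y = np.asarray(y, dtype=object)
        if len(docs) != len(y):
            raise ValueError("X and y have different lengths")
        classes = np.array(sorted(set(y.tolist())), dtype=object)
        if len(classes) != 2:
            raise ValueError(f"exactly 2 classes required, got {list(classes)}")
        class_counts = np.array([(y == c).sum() for c in classes], dtype=float)
        for c, cc in zip(classes, class_counts):
            if cc == 0:
                raise ValueError(f"class {c!r} has zero documents")

        vocab: dict[str, int] = {}
        for doc in docs:
            for tok in doc:
                if tok not in vocab:
                    vocab[tok] = len(vocab)
        counts = np.zeros((2, len(vocab)), dtype=float)
        for doc, label in zip(docs, y):
            ci = 0 if label == classes[0] else 1
            for tok in doc:
                counts[ci, vocab[tok]] += 1.0

        totals = counts.sum(axis=1, keepdims=True)
        smoothed = counts + self.alpha
        denom = totals + self.alpha * len(vocab)
        self.classes_ = classes
        self.class_log_prior_ = np.log(class_counts / class_counts.sum())
        self.vocabulary_ = vocab
        self.feature_log_prob_ = np.log(smoothed) - np.log(denom)
        return self

    # -------------------------------------------------------------- scoring
    def joint_log_likelihood(self, X: Iterable[TokenDoc]) -> np.ndarray:
        """Per-document unnormalized log-posterior scores, shape (n, 2).

        score(c) = log_prior(c) + sum over in-vocabulary tokens of
        log P(token | c); out-of-vocabulary tokens are skipped.
        """
        self._check_fitted()
        out = []
        for doc in X:
            scores = self.class_log_prior_.copy()
            for tok in doc:
                j = self.vocabulary_.get(tok)
                if j is not None:
                    scores = scores + self.feature_log_prob_[:, j]
            out.append(scores)
        return np.asarray(out).reshape(-1, 2)

    def predict_log_proba(self, X: Iterable[TokenDoc]) -> np.ndarray:
        jll = self.joint_log_likelihood(X)
        norm = np.logaddexp(jll[:, 0], jll[:, 1])
        return jll - norm[:, None]

    def predict(self, X: Iterable[TokenDoc]) -> np.ndarray:
        jll = self.joint_log_likelihood(X)
        tie_label = self.tie_break if self.tie_break is not None else self.classes_[0]
        if tie_label not in set(self.classes_.tolist()):
            raise ValueError(f"tie_break {tie_label!r} is not a fitted class")
        labels = np.where(jll[:, 0] > jll[:, 1], self.classes_[0], self.classes_[1])
        ties = jll[:, 0] == jll[:, 1]
        labels[ties] = tie_label
        return labels.astype(object)

    def _check_fitted(self) -> None:
        if not hasattr(self, "classes_"):
            raise ValueError("model is not fitted; call fit first")

    # -------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        """JSON-serializable snapshot allowing exact reload."""
        self._check_fitted()
        inv_vocab = sorted(self.vocabulary_, key=self.vocabulary_.get)
        return {
            "alpha": self.alpha,
            "tie_break": self.tie_break,
            "classes": [str(c) for c in self.classes_],
            "class_log_prior": self.class_log_prior_.tolist(),
            "vocabulary": inv_vocab,
            "feature_log_prob": self.feature_log_prob_.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MultinomialNaiveBayes":
        model = cls(alpha=data["alpha"], tie_break=data.get("tie_break"))
        model.classes_ = np.array(data["classes"], dtype=object)
        model.class_log_prior_ = np.array(data["class_log_prior"], dtype=float)
        model.vocabulary_ = {tok: i for i, tok in enumerate(data["vocabulary"])}
        model.feature_log_prob_ = np.array(data["feature_log_prob"], dtype=float)
        return model

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "MultinomialNaiveBayes":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def train_nb(
    docs: Iterable[TokenDoc], labels: Sequence, alpha: float = 1.0,
    tie_break: str | None = None,
) -> MultinomialNaiveBayes:
    """Functional wrapper: fit a binary multinomial NB model."""
    return MultinomialNaiveBayes(alpha=alpha, tie_break=tie_break).fit(docs, labels)


def predict_nb(model: MultinomialNaiveBayes, doc: TokenDoc):
    """Classify one token document; returns (label, {class: log-posterior score})."""
    label = model.predict([doc])[0]
    scores = model.joint_log_likelihood([doc])[0]
    return label, {str(c): float(s) for c, s in zip(model.classes_, scores)}
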
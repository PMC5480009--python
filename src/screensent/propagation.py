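"""Contagion-style propagation modeling of message spread.

The rate of propagation — the mean number of times a message is retweeted —
plays the role of an effective reproduction number for information spread.
Retweet-count heterogeneity is captured by a negative-binomial model
(mean ``mu``, dispersion ``k``, variance ``mu + mu**2/k``).  Sentiment
groups are compared by fitting shared vs separate models (AIC and a
likelihood-ratio chi-square with 2 degrees of freedom), and the incidence
of new original tweets is compared with an exact binomial test conditional
on the total, equivalent to testing equality of two Poisson arrival rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "K_CAP",
    "K_FLOOR",
    "NegBinFit",
    "PropagationComparison",
    "IncidenceTest",
    "negbin_loglik",
    "fit_negbin",
    "compare_propagation",
    "incidence_test",
]

K_FLOOR = 1e-4
K_CAP = 1e6  # dispersion at the cap is treated as the Poisson boundary


@dataclass
class NegBinFit:
    """Negative-binomial MLE for one group of retweet counts."""

    mu: float
    k: float
    loglik: float
    aic: float
    n: int
    converged: bool
    degenerate: bool = False  # all-zero sample: mu = 0, k unidentifiable

    def to_dict(self) -> dict:
        return {
            "mu": self.mu, "k": self.k, "loglik": self.loglik, "aic": self.aic,
            "n": self.n, "converged": self.converged, "degenerate": self.degenerate,
        }


@dataclass
class PropagationComparison:
    """Shared vs separate negative-binomial models for two sentiment groups.

    ``delta_aic > 0`` means the separate (sentiment-specific) model is
    preferred; ``p`` is the chi-square upper tail of the likelihood ratio
    at 2 degrees of freedom (both mu and k freed per group).
    """

    fit_shared: NegBinFit
    fit_pos: NegBinFit
    fit_neg: NegBinFit
    delta_aic: float
    lr_stat: float
    df: int
    p: float

    @property
    def separate_preferred(self) -> bool:
        return self.delta_aic > 0

    def to_dict(self) -> dict:
        return {
            "fit_shared": self.fit_shared.to_dict(),
            "fit_pos": self.fit_pos.to_dict(),
            "fit_neg": self.fit_neg.to_dict(),
            "delta_aic": self.delta_aic,
            "lr_stat": self.lr_stat,
            "df": self.df,
            "p": self.p,
            "separate_preferred": self.separate_preferred,
        }


@dataclass(frozen=True)
class IncidenceTest:
    """Exact two-sided test of equal Poisson arrival rates of new tweets."""

    n_new_pos: int
    n_new_neg: int
    p: float

    def to_dict(self) -> dict:
        return {"n_new_pos": self.n_new_pos, "n_new_neg": self.n_new_neg, "p": self.p}


def _validate_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("counts must be non-empty")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts must be numeric")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    return arr.astype(np.int64)


def negbin_loglik(mu: float, k: float, counts) -> float:
    """Log-likelihood of counts under NB(mean=mu, dispersion=k).

    Parameterized so variance = mu + mu**2/k; the scipy ``nbinom`` mapping
    is n = k, p = k / (k + mu).  ``mu = 0`` is the degenerate point mass at
    zero (log-likelihood 0 iff all counts are 0, else -inf).
    """
    arr = _validate_counts(counts)
    if k <= 0:
        raise ValueError(f"dispersion k must be > 0, got {k}")
    if mu < 0:
        raise ValueError(f"mean mu must be >= 0, got {mu}")
    if mu == 0:
        return 0.0 if not np.any(arr) else -math.inf
    return float(stats.nbinom.logpmf(arr, k, k / (k + mu)).sum())


def fit_negbin(counts) -> NegBinFit:
    """Maximum-likelihood negative-binomial fit.

    With both parameters free the MLE of the mean is the sample mean, so
    only the dispersion needs a numeric search: a bounded 1-D maximization
    of the profile log-likelihood over log(k) in [log K_FLOOR, log K_CAP].
    Samples with variance <= mean sit on the Poisson boundary and are
    reported with k = K_CAP; all-zero samples are degenerate (mu = 0).
    """
    arr = _validate_counts(counts)
    n = arr.size
    if n < 2:
        raise ValueError("need at least 2 counts to fit")
    mu = float(arr.mean())
    if mu == 0.0:
        return NegBinFit(mu=0.0, k=K_CAP, loglik=0.0, aic=4.0, n=n,
                         converged=True, degenerate=True)

    var = float(arr.var())
    if var <= mu:
        k = K_CAP
        ll = negbin_loglik(mu, k, arr)
        return NegBinFit(mu=mu, k=k, loglik=ll, aic=4.0 - 2.0 * ll, n=n,
                         converged=True, degenerate=False)

    def neg_profile(log_k: float) -> float:
        return -negbin_loglik(mu, math.exp(log_k), arr)

    res = optimize.minimize_scalar(
        neg_profile,
        bounds=(math.log(K_FLOOR), math.log(K_CAP)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    k = float(math.exp(res.x))
    ll = -float(res.fun)
    # moment start is a good sanity anchor; keep the better of the two
    k_mom = mu * mu / (var - mu)
    if K_FLOOR <= k_mom <= K_CAP:
        ll_mom = negbin_loglik(mu, k_mom, arr)
        if ll_mom > ll:
            k, ll = k_mom, ll_mom
    return NegBinFit(mu=mu, k=k, loglik=ll, aic=4.0 - 2.0 * ll, n=n,
                     converged=bool(res.success), degenerate=False)


def compare_propagation(counts_pos, counts_neg) -> PropagationComparison:
    """Compare rates of propagation between two sentiment groups.

    Fits NB models to each group and to the pooled counts; reports
    delta_aic = AIC(shared) - (AIC(pos) + AIC(neg)), the likelihood-ratio
    statistic 2*(ll_pos + ll_neg - ll_shared) and its chi-square(2) upper
    tail.
    """
    for name, grp in (("positive", counts_pos), ("negative", counts_neg)):
        arr = np.asarray(grp)
        if arr.size < 2:
            raise ValueError(f"{name} group needs at least 2 counts")
    fit_pos = fit_negbin(counts_pos)
    fit_neg = fit_negbin(counts_neg)
    pooled = np.concatenate([np.asarray(counts_pos), np.asarray(counts_neg)])
    fit_shared = fit_negbin(pooled)
    delta_aic = fit_shared.aic - (fit_pos.aic + fit_neg.aic)
    lr = 2.0 * (fit_pos.loglik + fit_neg.loglik - fit_shared.loglik)
    p = float(stats.chi2.sf(max(lr, 0.0), df=2))
    return PropagationComparison(
        fit_shared=fit_shared, fit_pos=fit_pos, fit_neg=fit_neg,
        delta_aic=float(delta_aic), lr_stat=float(lr), df=2, p=p,
    )


def incidence_test(n_new_pos: int, n_new_neg: int) -> IncidenceTest:
    """Exact test of equal Poisson rates for the introduction of new tweets.

    Conditional on the total T, the positive count is Binomial(T, 1/2)
    under equal rates; the two-sided p-value sums the probabilities of all
    outcomes no more likely than the observed one.
    """
    if n_new_pos < 0 or n_new_neg < 0:
        raise ValueError("counts of new tweets must be >= 0")
    total = n_new_pos + n_new_neg
    if total == 0:
        raise ValueError("at least one group must have new tweets")
    p = float(stats.binomtest(n_new_pos, total, 0.5, alternative="two-sided").pvalue)
    return IncidenceTest(n_new_pos=int(n_new_pos), n_new_neg=int(n_new_neg), p=p)
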
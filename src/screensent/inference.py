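"""Misclassification-corrected sentiment proportions by 2-step bootstrap.

Step 1 resamples pipeline-classified labels with replacement from the
observed classified distribution; step 2 probabilistically relabels each
draw with the correction kernel P(true | classified) estimated from the
held-out confusion table's columns.  The replicate distribution of the
corrected negative:positive ratio yields the point estimate (median) and
percentile CI.  Significance comes from a separately constructed null:
same total size and neutral count, but positive and negative in equal
proportion, resampled in one step with classification assumed perfect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pipeline import ClassifiedCorpus, ConfusionTable, LABELS

__all__ = [
    "CorrectionKernel",
    "RatioEstimate",
    "estimate_kernel",
    "bootstrap_proportions",
    "null_ratio_test",
    "replicate_ratio_distribution",
]

#: Abort threshold: fraction of replicates allowed to lose their positive
#: count (infinite ratio) before the regime is declared unstable.
MAX_INFINITE_FRACTION = 0.01


@dataclass
class CorrectionKernel:
    """Columns-conditional relabeling matrix K[r, c] = P(true=r | classified=c),
    rows and columns ordered (positive, negative, neutral)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError(f"kernel must be 3x3, got {self.matrix.shape}")
        if (self.matrix < 0).any():
            raise ValueError("kernel entries must be >= 0")
        colsums = self.matrix.sum(axis=0)
        if np.abs(colsums - 1.0).max() > 1e-9:
            raise ValueError(f"kernel columns must sum to 1, got {colsums}")

    @classmethod
    def identity(cls) -> "CorrectionKernel":
        return cls(np.eye(3))


@dataclass
class RatioEstimate:
    """Corrected negative:positive ratio with percentile CI and bootstrap p."""

    ratio_point: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    n_boot: int
    seed: int
    dropped_replicates: int = 0

    def to_dict(self) -> dict:
        return {
            "ratio_point": self.ratio_point,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_two_sided": self.p_two_sided,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "dropped_replicates": self.dropped_replicates,
        }


def estimate_kernel(table: ConfusionTable) -> CorrectionKernel:
    """Column-normalize the confusion table into P(true | classified).

    A column with zero sum (a pipeline label never produced on the test
    set) falls back to the identity distribution on its own label, so the
    kernel stays a proper stochastic matrix.
    """
    counts = table.counts.astype(float)
    matrix = np.empty((3, 3))
    for c in range(3):
        colsum = counts[:, c].sum()
        if colsum > 0:
            matrix[:, c] = counts[:, c] / colsum
        else:
            matrix[:, c] = 0.0
            matrix[c, c] = 1.0
    return CorrectionKernel(matrix)


def _ratios_from_true_counts(true_counts: np.ndarray) -> np.ndarray:
    """neg/pos ratio per replicate; 0-positive rows map to +inf (0/0 -> nan)."""
    pos = true_counts[:, 0].astype(float)
    neg = true_counts[:, 1].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return neg / pos


def bootstrap_proportions(
    corpus: ClassifiedCorpus,
    kernel: CorrectionKernel,
    n_boot: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, RatioEstimate]:
    """2-step bootstrap of misclassification-corrected sentiment proportions.

    Returns ``(corrected_proportions, RatioEstimate)`` where the proportions
    are replicate means over (positive, negative, neutral) and the estimate
    carries the replicate-ratio median and 2.5/97.5 percentile CI.  The
    p-value slot is NaN here; fill it with :func:`null_ratio_test`.

    Replicates whose corrected positive count is zero have an infinite
    ratio; if more than ``MAX_INFINITE_FRACTION`` of replicates are lost
    this way the regime is unstable and a ``ValueError`` is raised,
    otherwise they are dropped from the ratio summaries (never from the
    proportions) and counted in ``dropped_replicates``.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if corpus.n_pos == 0 and corpus.n_neg == 0:
        raise ValueError("corpus has no polar (positive or negative) tweets")
    rng = np.random.default_rng(seed)
    n = corpus.n_total
    p_obs = corpus.counts / n

    # step 1: resample n classified labels i.i.d. from the observed mix
    classified = rng.multinomial(n, p_obs, size=n_boot)
    # step 2: relabel each classified draw through the kernel column
    true_counts = np.zeros((n_boot, 3), dtype=np.int64)
    for c in range(3):
        true_counts += rng.multinomial(classified[:, c], kernel.matrix[:, c])

    proportions = true_counts / n
    corrected = proportions.mean(axis=0)

    ratios = _ratios_from_true_counts(true_counts)
    finite = np.isfinite(ratios)
    n_dropped = int(n_boot - finite.sum())
    if n_dropped > MAX_INFINITE_FRACTION * n_boot:
        raise ValueError(
            f"{n_dropped}/{n_boot} bootstrap replicates had zero corrected "
            "positive count; the ratio is unstable in this regime"
        )
    ratios = ratios[finite]
    estimate = RatioEstimate(
        ratio_point=float(np.median(ratios)),
        ci_low=float(np.percentile(ratios, 2.5)),
        ci_high=float(np.percentile(ratios, 97.5)),
        p_two_sided=float("nan"),
        n_boot=n_boot,
        seed=seed,
        dropped_replicates=n_dropped,
    )
    return corrected, estimate


def null_ratio_test(
    corpus: ClassifiedCorpus,
    observed_ratio: float,
    n_boot: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided bootstrap p-value against an equal-proportion null.

    The null dataset keeps the observed neutral count and total size but
    splits the polar mass equally: (m, m, n_neu) with m = (n_pos+n_neg)/2.
    When the polar total is odd, the spare unit is assigned to positive or
    negative by a fair coin per replicate, preserving both the exact total
    and the null's symmetry.  Resampling is one-step (classification of the
    null data is taken as perfect).  The p-value uses the add-one rule
    p = min(1, 2 * min(#{ratio >= obs} + 1, #{ratio <= obs} + 1) / (n_boot + 1)).
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    polar = corpus.n_pos + corpus.n_neg
    if polar == 0:
        raise ValueError("corpus has no polar (positive or negative) tweets")
    if not (observed_ratio > 0 and math.isfinite(observed_ratio)):
        raise ValueError(f"observed_ratio must be finite and > 0, got {observed_ratio}")
    rng = np.random.default_rng(seed)
    n = corpus.n_total
    m, spare = divmod(polar, 2)

    if spare == 0:
        pvals = np.array([m, m, corpus.n_neu], dtype=float) / n
        null_counts = rng.multinomial(n, pvals, size=n_boot)
    else:
        coin = rng.integers(0, 2, size=n_boot)
        pvals = np.empty((n_boot, 3))
        pvals[:, 0] = m + coin
        pvals[:, 1] = m + (1 - coin)
        pvals[:, 2] = corpus.n_neu
        pvals /= n
        null_counts = rng.multinomial(n, pvals)

    ratios = _ratios_from_true_counts(null_counts)
    n_ge = int(np.count_nonzero(ratios >= observed_ratio))
    n_le = int(np.count_nonzero(ratios <= observed_ratio))
    return min(1.0, 2.0 * (min(n_ge, n_le) + 1) / (n_boot + 1))


# ----------------------------------------------------------------- exact law
def _compositions(total: int, parts: int):
    """All non-negative integer vectors of length `parts` summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for rest in _compositions(total - head, parts - 1):
            yield (head,) + rest


def replicate_ratio_distribution(
    corpus: ClassifiedCorpus, kernel: CorrectionKernel
) -> dict[float, float]:
    """Exact probability law of one replicate's corrected neg:pos ratio.

    Enumerates the step-1 multinomial over classified counts and, for each,
    the step-2 kernel relabeling (a convolution of three multinomials), and
    accumulates the probability of every achievable ratio — including
    ``inf`` (zero positive, positive negative) and ``nan`` (both zero).
    Only feasible for tiny corpora; used to validate the Monte Carlo
    bootstrap against closed-form enumeration.
    """
    n = corpus.n_total
    p_obs = corpus.counts / n
    law: dict[float, float] = {}
    for classified in _compositions(n, 3):
        p1 = math.exp(stats.multinomial.logpmf(classified, n, p_obs)) if n else 1.0
        if p1 == 0.0:
            continue
        # distribution of true counts given classified counts: convolution
        # over the three kernel columns
        partial: dict[tuple[int, int, int], float] = {(0, 0, 0): 1.0}
        for c in range(3):
            m_c = classified[c]
            if m_c == 0:
                continue
            col = kernel.matrix[:, c]
            nxt: dict[tuple[int, int, int], float] = {}
            for draw in _compositions(m_c, 3):
                pd = math.exp(stats.multinomial.logpmf(draw, m_c, col))
                if pd == 0.0:
                    continue
                for acc, pa in partial.items():
                    key = (acc[0] + draw[0], acc[1] + draw[1], acc[2] + draw[2])
                    nxt[key] = nxt.get(key, 0.0) + pa * pd
            partial = nxt
        for (tp, tn, _tu), p2 in partial.items():
            if tp > 0:
                ratio = tn / tp
            elif tn > 0:
                ratio = math.inf
            else:
                ratio = math.nan
            law[ratio] = law.get(ratio, 0.0) + p1 * p2
    return law
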
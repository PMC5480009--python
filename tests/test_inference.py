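import itertools
import math

import numpy as np
import pytest

from screensent.inference import (
    CorrectionKernel,
    bootstrap_proportions,
    estimate_kernel,
    null_ratio_test,
    replicate_ratio_distribution,
)
from screensent.pipeline import ClassifiedCorpus, ConfusionTable


class TestKernel:
    def test_diagonal_table_gives_identity(self):
        table = ConfusionTable(np.diag([10, 20, 30]))
        assert np.allclose(estimate_kernel(table).matrix, np.eye(3))

    def test_column_normalization(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[:, 0] = [8, 0, 2]  # classified positive column
        counts[:, 1] = [0, 5, 0]
        counts[:, 2] = [0, 0, 5]
        k = estimate_kernel(ConfusionTable(counts)).matrix
        assert k[:, 0] == pytest.approx([0.8, 0.0, 0.2])

    def test_uniform_table_gives_uniform_columns(self):
        k = estimate_kernel(ConfusionTable(np.ones((3, 3), dtype=int))).matrix
        assert np.allclose(k, 1 / 3)

    def test_zero_column_falls_back_to_identity(self):
        counts = np.array([[5, 0, 1], [2, 0, 1], [1, 0, 8]])
        k = estimate_kernel(ConfusionTable(counts)).matrix
        assert k[:, 1] == pytest.approx([0.0, 1.0, 0.0])
        assert np.allclose(k.sum(axis=0), 1.0)

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CorrectionKernel(np.full((3, 3), 0.5))


class TestBootstrap:
    def test_identity_kernel_centers_on_observed(self):
        corpus = ClassifiedCorpus(200, 200, 600)
        corrected, est = bootstrap_proportions(
            corpus, CorrectionKernel.identity(), n_boot=4000, seed=0
        )
        assert corrected == pytest.approx([0.2, 0.2, 0.6], abs=0.01)
        assert est.ci_low <= 1.0 <= est.ci_high
        assert est.ci_low <= est.ratio_point <= est.ci_high

    def test_corrected_proportions_sum_to_one(self):
        corpus = ClassifiedCorpus(30, 50, 120)
        kernel = CorrectionKernel(np.array([
            [0.8, 0.0, 0.1],
            [0.0, 0.9, 0.1],
            [0.2, 0.1, 0.8],
        ]))
        corrected, _ = bootstrap_proportions(corpus, kernel, n_boot=500, seed=1)
        assert corrected.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_kernel_rejected(self):
        """A kernel sending every classified label to true=negative kills
        the positive count in every replicate."""
        kernel = CorrectionKernel(np.array([
            [0.0, 0.0, 0.0], [1.0, 1.0, 1.0], [0.0, 0.0, 0.0]]))
        with pytest.raises(ValueError, match="zero corrected positive"):
            bootstrap_proportions(ClassifiedCorpus(50, 50, 100), kernel,
                                  n_boot=200, seed=2)

    def test_no_polar_tweets_rejected(self):
        with pytest.raises(ValueError, match="polar"):
            bootstrap_proportions(ClassifiedCorpus(0, 0, 10),
                                  CorrectionKernel.identity(), 100, 0)

    def test_deterministic_under_seed(self):
        corpus = ClassifiedCorpus(40, 60, 100)
        a = bootstrap_proportions(corpus, CorrectionKernel.identity(), 300, seed=9)
        b = bootstrap_proportions(corpus, CorrectionKernel.identity(), 300, seed=9)
        assert np.allclose(a[0], b[0])
        assert (a[1].ratio_point, a[1].ci_low, a[1].ci_high) == (
            b[1].ratio_point, b[1].ci_low, b[1].ci_high)


class TestExactReplicateLaw:
    def test_enumeration_matches_brute_force_five_tweets(self):
        """Exact replicate-ratio law on a (3,1,1) corpus with identity kernel
        equals brute-force enumeration of all 5^5 resamples to 1e-12."""
        corpus = ClassifiedCorpus(3, 1, 1)
        law = replicate_ratio_distribution(corpus, CorrectionKernel.identity())

        items = ["positive"] * 3 + ["negative"] + ["neutral"]
        brute: dict[float, float] = {}
        weight = 1.0 / 5**5
        for resample in itertools.product(items, repeat=5):
            pos = resample.count("positive")
            neg = resample.count("negative")
            if pos > 0:
                ratio = neg / pos
            elif neg > 0:
                ratio = math.inf
            else:
                ratio = math.nan
            brute[ratio] = brute.get(ratio, 0.0) + weight

        def normalize(d):
            return {("nan" if (isinstance(k, float) and math.isnan(k)) else k): v
                    for k, v in d.items()}

        law_n, brute_n = normalize(law), normalize(brute)
        assert set(law_n) == set(brute_n)
        for key in brute_n:
            assert law_n[key] == pytest.approx(brute_n[key], abs=1e-12)

    def test_law_sums_to_one(self):
        law = replicate_ratio_distribution(
            ClassifiedCorpus(2, 2, 1),
            CorrectionKernel(np.array([[0.9, 0.0, 0.1],
                                       [0.0, 0.9, 0.1],
                                       [0.1, 0.1, 0.8]])),
        )
        assert sum(law.values()) == pytest.approx(1.0, abs=1e-10)


class TestNullRatioTest:
    def test_observed_at_null_center_gives_large_p(self):
        p = null_ratio_test(ClassifiedCorpus(500, 500, 1000), 1.0,
                            n_boot=4000, seed=0)
        assert p > 0.5

    def test_extreme_ratio_significant(self):
        """Normal-approximation oracle: log-ratio of two counts of ~500 has
        sd ~ sqrt(2/500) = 0.063, so ratio 2.0 (log 0.69, z ~ 11) must give
        p below 0.001."""
        p = null_ratio_test(ClassifiedCorpus(500, 500, 1000), 2.0,
                            n_boot=10_000, seed=1)
        assert p < 0.001

    def test_symmetry_under_group_swap(self):
        corpus = ClassifiedCorpus(300, 500, 400)
        swapped = ClassifiedCorpus(500, 300, 400)
        p1 = null_ratio_test(corpus, 1.4, n_boot=20_000, seed=2)
        p2 = null_ratio_test(swapped, 1 / 1.4, n_boot=20_000, seed=3)
        assert p1 == pytest.approx(p2, abs=0.02)

    def test_odd_polar_total_accepted(self):
        p = null_ratio_test(ClassifiedCorpus(250, 252, 500), 1.0,
                            n_boot=1000, seed=4)
        assert 0.0 < p <= 1.0

    def test_p_never_zero(self):
        p = null_ratio_test(ClassifiedCorpus(500, 500, 0), 50.0,
                            n_boot=500, seed=5)
        assert p >= 2 / 501

    def test_no_polar_rejected(self):
        with pytest.raises(ValueError, match="polar"):
            null_ratio_test(ClassifiedCorpus(0, 0, 10), 1.0, 100, 0)

    def test_nonfinite_observed_rejected(self):
        with pytest.raises(ValueError, match="observed_ratio"):
            null_ratio_test(ClassifiedCorpus(5, 5, 5), math.inf, 100, 0)
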
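import math

import numpy as np
import pytest
from scipy.special import gammaln

from screensent.propagation import (
    K_CAP,
    compare_propagation,
    fit_negbin,
    incidence_test,
    negbin_loglik,
)
from screensent.synthetic import sample_retweet_counts


def reference_logpmf(x, mu, k):
    """Independent NB log-PMF from the gamma-function definition:
    log Gamma(x+k) - log Gamma(k) - log x! + k log(k/(k+mu)) + x log(mu/(k+mu))."""
    x = np.asarray(x, dtype=float)
    return (gammaln(x + k) - gammaln(k) - gammaln(x + 1)
            + k * np.log(k / (k + mu)) + x * np.log(mu / (k + mu)))


class TestLoglik:
    def test_degenerate_zero_mean(self):
        assert negbin_loglik(0.0, 1.0, [0, 0, 0]) == 0.0
        assert negbin_loglik(0.0, 1.0, [0, 1]) == -math.inf

    def test_poisson_limit_closed_form(self):
        """counts=[1], mu=1, k -> inf approaches the Poisson value log(e^-1) = -1."""
        assert negbin_loglik(1.0, 1e9, [1]) == pytest.approx(-1.0, abs=1e-6)

    def test_matches_independent_pmf_oracle(self):
        counts = [0, 1, 2, 3]
        ours = negbin_loglik(1.5, 2.0, counts)
        ref = reference_logpmf(counts, 1.5, 2.0).sum()
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_poisson_limit_per_observation(self):
        """At the dispersion cap the NB log-likelihood matches Poisson within
        1e-4 per observation."""
        from scipy import stats
        counts = np.arange(0, 15)
        nb = negbin_loglik(3.0, K_CAP, counts)
        pois = stats.poisson.logpmf(counts, 3.0).sum()
        assert abs(nb - pois) < 1e-4 * len(counts)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            negbin_loglik(1.0, 0.0, [1])
        with pytest.raises(ValueError):
            negbin_loglik(1.0, 1.0, [-1])
        with pytest.raises(ValueError):
            negbin_loglik(1.0, 1.0, [1.5])


class TestFit:
    def test_all_zero_counts_degenerate(self):
        fit = fit_negbin([0, 0, 0, 0])
        assert fit.mu == 0.0 and fit.degenerate
        assert fit.k == K_CAP
        assert fit.aic == pytest.approx(4.0 - 2.0 * fit.loglik)

    def test_underdispersed_counts_hit_dispersion_cap(self):
        # sample variance exactly equals the mean: Poisson boundary
        counts = [0, 1, 2, 3, 4] * 100
        fit = fit_negbin(counts)
        assert fit.k == K_CAP
        assert fit.mu == pytest.approx(2.0, abs=1e-12)

    def test_poisson_sample_fits_near_poisson(self):
        """A Poisson sample yields a near-equidispersed fit: the NB excess
        variance mu/k is a small fraction of the mean and the likelihood is
        within a whisker of the Poisson likelihood."""
        from scipy import stats
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=3000)
        fit = fit_negbin(counts)
        assert fit.mu / fit.k < 0.05 * fit.mu
        pois_ll = stats.poisson.logpmf(counts, counts.mean()).sum()
        assert fit.loglik >= pois_ll - 1e-6

    def test_parameter_recovery(self):
        counts = sample_retweet_counts(3.0, 0.8, 2000, rng=12)
        fit = fit_negbin(counts)
        assert fit.converged
        assert abs(fit.mu / 3.0 - 1.0) < 0.10
        assert abs(fit.k / 0.8 - 1.0) < 0.20

    def test_mu_is_sample_mean(self):
        counts = sample_retweet_counts(2.0, 1.0, 500, rng=13)
        fit = fit_negbin(counts)
        assert fit.mu == pytest.approx(counts.mean(), abs=1e-8)

    def test_aic_identity(self):
        counts = sample_retweet_counts(1.5, 0.5, 400, rng=14)
        fit = fit_negbin(counts)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik, abs=1e-12)

    def test_matches_statsmodels_mle(self):
        """Cross-check against statsmodels' NB2 maximum likelihood (its
        alpha is 1/k)."""
        import statsmodels.api as sm

        counts = sample_retweet_counts(2.5, 0.7, 1500, rng=15)
        ours = fit_negbin(counts)
        X = np.ones((len(counts), 1))
        sm_fit = sm.NegativeBinomial(counts, X).fit(disp=0)
        sm_mu = math.exp(sm_fit.params[0])
        sm_k = 1.0 / sm_fit.params[1]
        assert ours.mu == pytest.approx(sm_mu, rel=1e-3)
        assert ours.k == pytest.approx(sm_k, rel=0.02)
        assert ours.loglik == pytest.approx(sm_fit.llf, abs=0.01)

    def test_too_few_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_negbin([3])


class TestCompare:
    def test_identical_groups_prefer_shared_model(self):
        counts = sample_retweet_counts(2.0, 1.0, 1000, rng=16)
        cmp = compare_propagation(counts, counts)
        assert cmp.lr_stat == pytest.approx(0.0, abs=1e-4)
        assert cmp.p > 0.99
        assert cmp.delta_aic == pytest.approx(-4.0, abs=1e-4)
        assert not cmp.separate_preferred

    def test_distinct_means_detected(self):
        pos = sample_retweet_counts(1.0, 1.0, 2000, rng=17)
        neg = sample_retweet_counts(3.0, 1.0, 2000, rng=18)
        cmp = compare_propagation(pos, neg)
        assert cmp.p < 1e-6 and cmp.separate_preferred
        assert cmp.fit_neg.mu > cmp.fit_pos.mu

    def test_loglik_nesting(self):
        pos = sample_retweet_counts(1.0, 0.5, 300, rng=19)
        neg = sample_retweet_counts(1.5, 0.5, 300, rng=20)
        cmp = compare_propagation(pos, neg)
        assert cmp.fit_shared.loglik <= cmp.fit_pos.loglik + cmp.fit_neg.loglik + 1e-6
        assert cmp.lr_stat >= -1e-6
        assert 0.0 <= cmp.p <= 1.0 and cmp.df == 2

    def test_small_group_rejected_with_name(self):
        with pytest.raises(ValueError, match="negative"):
            compare_propagation([1, 2, 3], [1])


class TestIncidence:
    def test_balanced_counts_give_p_one(self):
        assert incidence_test(5, 5).p == 1.0

    def test_extreme_split_closed_form(self):
        assert incidence_test(0, 20).p == pytest.approx(2 * 0.5**20, rel=1e-12)

    @pytest.mark.parametrize("a,b", [(3, 9), (0, 7), (10, 2), (1, 1)])
    def test_symmetry(self, a, b):
        assert incidence_test(a, b).p == pytest.approx(incidence_test(b, a).p, rel=1e-12)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            incidence_test(0, 0)
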
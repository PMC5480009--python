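# Methods

This note documents the statistical models, the synthetic data-generating
process, the numerical choices, and the known limitations of `screensent`.

## Sentiment classification

Each modality gets two binary multinomial naive Bayes models trained on the
same labeled pool with dichotomized labels (positive vs nonpositive;
negative vs nonnegative) and combined into a three-way label. Choices:

- **Event model and smoothing.** Multinomial bag-of-words with Laplace
  smoothing, `alpha = 1.0` by default — the canonical configuration for
  short texts. Per class, the smoothed token probabilities sum to one over
  the vocabulary fixed at training.
- **Tokenization.** Lowercase; URLs and @-mentions removed; `#` stripped
  from hashtags keeping the word; split on non-alphanumeric runs; tokens
  shorter than 2 characters dropped. Deliberately minimal: no stemming,
  n-grams, negation scoping or emoji handling.
- **Out-of-vocabulary tokens** are skipped at prediction rather than
  smoothed into the vocabulary, keeping the trained model's support fixed.
- **Ties** in the binary decision break toward the negative-evidence
  ("non") class, so exact ties never manufacture polar sentiment. The
  contradictory (positive, negative) pair of binary outcomes — never
  observed on separable data — maps to neutral for the same reason.
- **Splitting.** The train/test partition (default 75/25) is stratified by
  manual label with largest-remainder rounding per stratum, guaranteeing
  every class appears on both sides even at small n. Each modality is
  split and modeled separately (three independent pipelines of 500 labeled
  tweets each, 375 train / 125 test), rather than pooling one 1200/300
  split across modalities; both designs are defensible, and the
  per-modality design keeps the confusion table matched to the models it
  validates.

## Misclassification-corrected proportions

The held-out confusion table `N[r, c]` (rows manual, columns pipeline) is
column-normalized into the correction kernel `K(r | c) = P(true = r |
classified = c)`. The kernel conditions on the *classified* label — the
direction in which the relabeling step actually uses it. A column never
produced on the test set falls back to the identity distribution on its
own label. The inversion via `P(classified | true)` (a matrix-inverse
correction) is a recognized alternative; the direct columns-conditional
kernel was chosen because it is a proper probability distribution by
construction and never produces negative corrected proportions.

The 2-step bootstrap, per replicate: (1) draw `n` classified labels i.i.d.
from the observed classified distribution; (2) relabel each draw from the
kernel column. Corrected proportions are replicate means (they sum to one
in every replicate); the negative:positive ratio's point estimate is the
replicate median — robust to the ratio's right skew, since the paper-style
single printed ratio does not define its estimator — with a 2.5/97.5
percentile CI. Defaults: `n_boot = 10,000`.

Degenerate replicates with zero corrected-positive count have an infinite
ratio. If more than 1% of replicates are lost this way the regime is
unstable and the estimate aborts with a diagnostic; otherwise they are
dropped from ratio summaries and counted in `dropped_replicates`.

The significance test builds a null dataset with the observed neutral
count and total size but the polar mass split equally, `(m, m, n_neu)`
with `m = (n_pos + n_neg)/2`; an odd polar total assigns the spare unit by
a fair coin per replicate, preserving the exact total and the null's
symmetry. Null resampling is one-step (classification of the constructed
null is taken as perfect), and the two-sided p-value uses the add-one rule
`p = min(1, 2·min(#≥ + 1, #≤ + 1)/(n_boot + 1))`, so it is never exactly
zero. For tiny corpora, `replicate_ratio_distribution` computes the exact
law of a replicate's ratio by multinomial enumeration, which the Monte
Carlo path is tested against.

## Propagation model

Retweet counts per sentiment group follow a negative binomial with mean
`mu` (the rate of propagation) and dispersion `k`, variance
`mu + mu²/k`; small `k` captures the heavy-tailed heterogeneity of
retweeting, and `k → ∞` recovers Poisson. With both parameters free the
MLE of `mu` is the sample mean, so fitting reduces to a bounded 1-D search
for `k` on the profile log-likelihood over `log k ∈ [log 1e-4, log 1e6]`
(`xatol = 1e-10`), with the moment estimate `k = mu²/(s² − mu)` kept if it
beats the optimizer. Samples with variance ≤ mean sit on the Poisson
boundary and report `k` at the cap `1e6`; all-zero samples are degenerate
(`mu = 0`, likelihood 1). At the cap the NB likelihood matches Poisson to
better than 1e-4 per observation.

Sentiment groups are compared by fitting shared vs separate models:
`ΔAIC = AIC_shared − (AIC_pos + AIC_neg)` and the likelihood ratio
`LR = 2(ℓ_pos + ℓ_neg − ℓ_shared)` with a χ² reference at **2 degrees of
freedom** — both `mu` and `k` are freed per group in the separate model.
The alternative nesting with a shared `k` (df = 1) would attribute any
dispersion difference to the mean; freeing both is the more honest
comparison and is slightly conservative in practice because `k` is weakly
identified near the Poisson boundary. `ΔAIC > 0` marks the separate model
as preferred by AIC; note that under a true null AIC prefers the separate
model with probability ≈ `P(χ²₂ > 4) ≈ 13.5%` by construction, so the
likelihood-ratio p-value is the better decision rule when a familywise
error level matters, and it is the rule the study-level regime check uses.

The incidence of new tweets: conditional on the total `T` of new original
tweets, the positive count is Binomial(T, 1/2) under equal Poisson arrival
rates; the p-value is the exact two-sided binomial tail (sum of outcome
probabilities no larger than the observed outcome's). Exact at small
counts, symmetric under group swap.

## Synthetic corpus generator

The generator emulates the structure the pipeline consumes, not natural
language:

- **Sentiment**: i.i.d. from configured proportions `(p_pos, p_neg, p_neu)`
  summing to 1 (tolerance 1e-9).
- **Text**: token count Poisson with configurable mean (default 11,
  minimum 3 — a realistic content-token count for a short message after
  stripping function words); tokens i.i.d. from a mixture putting weight
  `w` (default 0.4) on the sentiment's loaded lexicon and `1 − w` on the
  shared neutral vocabulary. Neutral tweets draw from the neutral
  vocabulary alone. The three built-in lexicons (25 positive-loaded, 25
  negative-loaded, 70 neutral tokens drawn from screening-chatter
  vocabulary) are pairwise disjoint by construction.
- **Retweets**: per-sentiment negative binomial `(mu, k)`.
- **Originality**: per sentiment, the count of new (original) tweets is
  Poisson with the configured arrival rate, capped at the number of
  records carrying that sentiment; a seeded subset of that size is flagged
  original. This reconciles a fixed corpus size and exact sentiment
  proportions with Poisson arrival of new messages.
- **Determinism**: one top-level seed; the sentiment, text, retweet and
  originality stages draw from sub-streams spawned deterministically from
  it, so identical configs reproduce byte-identical corpora.

The default modality presets encode the qualitative regime the package's
study-level checks target: colonoscopy negative-skewed (proportions
0.17/0.28/0.55) with negative messages both arriving more often and
spreading more (`mu` 2.2 vs 1.0); mammography positive-skewed (0.30/0.13)
but with its rarer negative messages spreading more (2.5 vs 1.0); Pap
smear exactly symmetric (0.20/0.20, equal rates and spread). Dispersion
`k = 0.8` throughout — strongly overdispersed, as retweet counts are.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: grammar and word order (bag-of-words only, which
flatters a bag-of-words classifier; held-out accuracy on synthetic corpora
runs ~96–99% versus the ~80% typical of real labeled tweets), sarcasm and
negation, follower-network structure behind retweet cascades, duplicated
or near-duplicated messages, and time stamps beyond per-sentiment arrival
counts.

## Calibration facts established by the test suite

All simulation sizes below are the package's own scaled-down study
conditions (corpora of 800–2,500 tweets, 500 labeled per modality, 600–10,000
bootstrap replicates), chosen to exercise every stage at desk scale.

- The from-scratch classifier's log-posteriors match an independent
  reference implementation to 1e-8 on random corpora.
- The bootstrap replicate-ratio law matches exact enumeration to 1e-12 on
  a 5-tweet corpus.
- With the correction kernel built from the known confusion structure, the
  95% percentile CI covers the true negative:positive ratio in ≥ 90% of
  300 simulated pipelines (measured ≈ 99%: the relabeling step adds
  variance beyond the corpus's own sampling noise, so the interval is
  conservative). When the kernel is instead *estimated* from a 125-tweet
  held-out split, its estimation error is held fixed across replicates and
  coverage drops toward ~90%; propagating kernel uncertainty (e.g. by
  resampling the test set per replicate) is a known limitation left out of
  scope.
- The null ratio test rejects a true equal-proportion null at α = 0.05 in
  5% ± 2% of runs; the propagation comparison detects a 3× rate difference
  essentially always at n = 2,000/group and stays within 8% false
  rejection under equal parameters.

## Known limitations

- The correction kernel treats the held-out confusion table as exact; its
  sampling error is not propagated into the CI (above).
- The constructed null assumes perfectly accurate classification of the
  null dataset, so under a heavily misclassifying classifier the null
  test is anti-conservative relative to the corrected estimate.
- The negative-binomial comparison assumes independent counts; retweet
  cascades of a single viral message violate independence in real feeds.
- The generator's lexical separability overstates real-world classifier
  accuracy; conclusions about end-to-end behavior on real corpora require
  real labeled data.
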
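"""End-to-end study driver: corpus -> classifiers -> corrected proportions
-> propagation -> word frequencies -> machine-readable report.

Mirrors the full analysis chain on synthetic corpora: a labeled subset
stands in for manual annotation, a stratified 75/25 split trains and
validates the dual naive Bayes classifiers, the held-out confusion table
drives the 2-step bootstrap correction, and classified labels feed the
propagation and incidence comparisons.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .frequency import word_frequencies
from .inference import bootstrap_proportions, estimate_kernel, null_ratio_test
from .pipeline import (
    DualNaiveBayesSentiment,
    classify_corpus,
    evaluate,
    split_train_test,
)
from .propagation import compare_propagation, incidence_test
from .synthetic import (
    SENTIMENTS,
    CorpusConfig,
    generate_corpus,
    modality_presets,
)

__all__ = ["run_modality", "run_study", "build_report", "serialize_report"]


def _config_echo(config: CorpusConfig) -> dict:
    return {
        "n_tweets": config.n_tweets,
        "modality": config.modality,
        "true_proportions": list(config.true_proportions),
        "tweet_length": config.tweet_length,
        "mixing_weights": dict(config.lexicons.mixing_weights),
        "retweet_params": {
            s: {"mu": rp.mu, "k": rp.k} for s, rp in config.retweet_params.items()
        },
        "arrival_rates": {s: config.arrival_rates.get(s, 0.0) for s in SENTIMENTS},
        "seed": config.seed,
    }


def run_modality(
    config: CorpusConfig,
    n_labeled: int = 500,
    train_fraction: float = 0.75,
    n_boot: int = 10_000,
    null_boot: int | None = None,
    top_k: int = 25,
    seed: int = 0,
    alpha: float = 1.0,
) -> dict:
    """Run the full pipeline for one modality sub-corpus.

    ``n_labeled`` records (seeded sample) play the role of the manually
    annotated pool; their latent sentiment is the manual label.  Returns a
    JSON-serializable block with every stage's output.
    """
    if null_boot is None:
        null_boot = n_boot
    rng = np.random.default_rng(np.random.SeedSequence([seed, config.seed]))
    split_seed, boot_seed, null_seed = (
        int(s) for s in rng.integers(0, 2**31 - 1, size=3)
    )

    corpus = generate_corpus(config)
    n_labeled = min(n_labeled, len(corpus))
    labeled_idx = rng.choice(len(corpus), size=n_labeled, replace=False)
    labeled = [corpus[i] for i in sorted(labeled_idx)]
    manual = [t.true_sentiment for t in labeled]

    train, test, y_train, y_test = split_train_test(
        labeled, manual, train_fraction, seed=split_seed
    )
    model = DualNaiveBayesSentiment(alpha=alpha).fit([t.text for t in train], y_train)
    table, accuracy = evaluate(model, test, y_test)

    labels, classified = classify_corpus(model, corpus)
    kernel = estimate_kernel(table)
    corrected, estimate = bootstrap_proportions(
        classified, kernel, n_boot=n_boot, seed=boot_seed
    )
    estimate.p_two_sided = null_ratio_test(
        classified, estimate.ratio_point, n_boot=null_boot, seed=null_seed
    )

    by_label = {lab: np.array([t.retweet_count for t, L in zip(corpus, labels) if L == lab])
                for lab in ("positive", "negative")}
    comparison = compare_propagation(by_label["positive"], by_label["negative"])
    n_new = {lab: sum(1 for t, L in zip(corpus, labels) if L == lab and t.is_original)
             for lab in ("positive", "negative")}
    incidence = incidence_test(n_new["positive"], n_new["negative"])

    n_orig_total = sum(1 for t in corpus if t.is_original) or 1
    original_fraction = {
        lab: {
            # share of this sentiment's tweets that are original
            "within_sentiment": (n_new[lab] / labels.count(lab)) if labels.count(lab) else 0.0,
            # share of all original tweets carrying this sentiment
            "within_modality": n_new[lab] / n_orig_total,
        }
        for lab in ("positive", "negative")
    }

    freq = {
        lab: word_frequencies(corpus, labels, lab, top_k=top_k).to_dict()
        for lab in ("positive", "negative")
    }

    return {
        "modality": config.modality,
        "config": _config_echo(config),
        "n_labeled": n_labeled,
        "confusion_table": table.counts.tolist(),
        "accuracy": accuracy,
        "classified_counts": {
            "positive": classified.n_pos,
            "negative": classified.n_neg,
            "neutral": classified.n_neu,
        },
        "corrected_proportions": {
            "positive": float(corrected[0]),
            "negative": float(corrected[1]),
            "neutral": float(corrected[2]),
        },
        "ratio_estimate": estimate.to_dict(),
        "propagation": comparison.to_dict(),
        "incidence": incidence.to_dict(),
        "original_fraction": original_fraction,
        "word_frequencies": freq,
        "seeds": {"split": split_seed, "bootstrap": boot_seed, "null": null_seed},
    }


def build_report(blocks: Sequence[dict], seed: int) -> dict:
    """Assemble per-modality blocks into one study report document.

    A block that raised during its stage may be passed as ``None`` paired
    with its modality name via a (name, None) tuple; it is marked absent
    rather than failing the whole report.
    """
    if not blocks:
        raise ValueError("at least one modality block is required")
    modalities = {}
    for block in blocks:
        if isinstance(block, tuple) and block[1] is None:
            modalities[block[0]] = {"status": "absent"}
        else:
            modalities[block["modality"]] = block
    return {
        "software": {"name": "screensent", "version": __version__},
        "seed": seed,
        "modalities": modalities,
    }


def serialize_report(report: Mapping) -> str:
    """Deterministic serialization: sorted keys, fixed separators."""
    return json.dumps(report, sort_keys=True, indent=2)


def run_study(
    configs: Mapping[str, CorpusConfig] | None = None,
    seed: int = 0,
    n_tweets: int = 2500,
    n_labeled: int = 500,
    n_boot: int = 10_000,
    null_boot: int | None = None,
    top_k: int = 25,
) -> dict:
    """Run all modality pipelines and assemble the study report.

    With ``configs=None`` the default modality presets at ``n_tweets`` per
    sub-corpus are used, seeded from ``seed``.
    """
    if configs is None:
        configs = modality_presets(n_tweets=n_tweets, seed=seed)
    blocks = [
        run_modality(
            cfg, n_labeled=n_labeled, n_boot=n_boot, null_boot=null_boot,
            top_k=top_k, seed=seed,
        )
        for cfg in configs.values()
    ]
    return build_report(blocks, seed=seed)
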
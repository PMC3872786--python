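"""Seeded synthetic-data generators.

Three generators make every stage of the pipeline testable without any
external corpus or norm set:

* a topic-mixture corpus with plantable co-occurrence structure —
  same-topic words co-occur more than cross-topic words by construction;
* rating tables generated as a known linear function of computed features
  plus Gaussian noise (for parameter-recovery tests of the regression
  machinery);
* trial-level lexical-decision RTs with item effects, subject effects, a
  controlled error rate, and plantable fast/slow outliers (for the
  trimming and variance-partition analyses).

Every generator is a pure function of its spec: the same seed yields
identical output.  Ground truth travels alongside the data, never through
the analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CorpusSpec:
    """Topic-mixture corpus layout.

    ``vocab_size`` words are split evenly over ``n_topics`` topics.  Each
    document draws one topic and samples words from it, except that with
    probability ``mixing`` a token is drawn from the full vocabulary
    instead (mixing 0 makes topics perfectly separated).  ``zipf_s > 0``
    tilts within-topic word probabilities toward a power law.
    """

    vocab_size: int = 200
    n_topics: int = 4
    n_documents: int = 200
    doc_length: int = 100
    mixing: float = 0.05
    zipf_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < self.n_topics or self.n_topics < 1:
            raise ValueError("need vocab_size >= n_topics >= 1")
        if min(self.n_documents, self.doc_length) < 1:
            raise ValueError("document count and length must be positive")
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must be in [0, 1]")


def _word_labels(n: int) -> list[str]:
    # purely alphabetic deterministic labels (survive tokenization):
    # waa, wab, ..., wba, ...
    width = 1
    while 26 ** width < n:
        width += 1
    labels = []
    for i in range(n):
        s, x = "", i
        for _ in range(width):
            s = chr(ord("a") + x % 26) + s
            x //= 26
        labels.append("w" + s)
    return labels


def generate_corpus(spec: CorpusSpec
                    ) -> tuple[list[list[str]], dict[str, int]]:
    """Token documents plus the ground-truth word → topic map."""
    rng = np.random.default_rng(spec.seed)
    words = np.array(_word_labels(spec.vocab_size))
    topic_of = {w: i % spec.n_topics for i, w in enumerate(words)}
    topic_words = [words[np.array([topic_of[w] == t for w in words])]
                   for t in range(spec.n_topics)]

    def probs(n: int) -> np.ndarray:
        if spec.zipf_s <= 0:
            return np.full(n, 1.0 / n)
        p = 1.0 / np.arange(1, n + 1) ** spec.zipf_s
        return p / p.sum()

    docs: list[list[str]] = []
    for _ in range(spec.n_documents):
        t = int(rng.integers(spec.n_topics))
        pool = topic_words[t]
        doc = [str(w) for w in rng.choice(pool, size=spec.doc_length,
                                          p=probs(len(pool)))]
        if spec.mixing > 0:
            mix = rng.random(spec.doc_length) < spec.mixing
            n_mix = int(mix.sum())
            if n_mix:
                repl = rng.choice(words, size=n_mix,
                                  p=probs(len(words)))
                for i, j in enumerate(np.flatnonzero(mix)):
                    doc[j] = str(repl[i])
        docs.append(doc)
    return docs, topic_of


@dataclass(frozen=True)
class RatingSpec:
    """Linear generating model for synthetic rating norms.

    ``coefficients`` maps feature-column names to generating βs;
    ``intercept`` sets the scale midpoint; Gaussian noise with
    ``noise_sd`` is added; ``bounds`` records the nominal rating scale
    (ratings are NOT clamped — the generating model is linear).
    """

    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = 4.0
    noise_sd: float = 0.5
    bounds: tuple[float, float] = (1.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def generate_ratings(features: pd.DataFrame, spec: RatingSpec
                     ) -> tuple[pd.DataFrame, dict]:
    """Norm table (word, rating) generated from the features.

    Returns the table and the ground truth (generating intercept and βs,
    the noise draws' sd).
    """
    missing = [c for c in spec.coefficients if c not in features.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    rng = np.random.default_rng(spec.seed)
    y = np.full(len(features), spec.intercept, dtype=float)
    for c, b in spec.coefficients.items():
        y += b * features[c].to_numpy(dtype=float)
    y += rng.normal(0.0, spec.noise_sd, size=len(features))
    table = pd.DataFrame({"word": features.index, "rating": y})
    truth = {"intercept": spec.intercept,
             "coefficients": dict(spec.coefficients),
             "noise_sd": spec.noise_sd}
    return table.reset_index(drop=True), truth


@dataclass(frozen=True)
class RTSpec:
    """Generating model for trial-level lexical-decision RTs.

    rt = baseline + Σ effectᵢ·xᵢ + subject intercept + N(0, residual_sd),
    with per-feature effects in ms per unit.  ``outlier_rate`` of word
    trials are replaced by implausible values (half fast, below
    ``fast_value``; half slow, above ``slow_value``).  ``error_rate``
    flags trials incorrect; ``nonword_rate`` of trials are non-word
    fillers.
    """

    baseline: float = 650.0
    effects: dict[str, float] = field(default_factory=dict)
    subject_sd: float = 40.0
    residual_sd: float = 60.0
    n_subjects: int = 30
    outlier_rate: float = 0.0
    fast_value: float = 150.0
    slow_value: float = 5000.0
    error_rate: float = 0.05
    nonword_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        for name in ("outlier_rate", "error_rate", "nonword_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")


def generate_trials(items: pd.DataFrame, spec: RTSpec
                    ) -> tuple[pd.DataFrame, dict]:
    """Trial table over ``items`` (feature table indexed by word).

    Each subject sees every item once.  Returns the trial table
    (subject, word, is_word, correct, rt) and ground truth: generating
    effects, subject intercepts, and the planted-outlier trial count.
    """
    missing = [c for c in spec.effects if c not in items.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")
    rng = np.random.default_rng(spec.seed)
    words = list(items.index)
    item_effect = np.zeros(len(words))
    for c, b in spec.effects.items():
        item_effect += b * items[c].to_numpy(dtype=float)

    subj_int = rng.normal(0.0, spec.subject_sd, size=spec.n_subjects)
    rows = []
    n_outliers = 0
    for s in range(spec.n_subjects):
        rts = (spec.baseline + item_effect + subj_int[s]
               + rng.normal(0.0, spec.residual_sd, size=len(words)))
        rts = np.maximum(rts, 1.0)
        correct = rng.random(len(words)) >= spec.error_rate
        is_word = rng.random(len(words)) >= spec.nonword_rate
        out = rng.random(len(words)) < spec.outlier_rate
        for i, w in enumerate(words):
            rt = rts[i]
            planted = bool(out[i] and correct[i] and is_word[i])
            if planted:
                n_outliers += 1
                if rng.random() < 0.5:
                    rt = rng.uniform(50.0, spec.fast_value)
                else:
                    rt = rng.uniform(spec.slow_value, spec.slow_value + 2000)
            rows.append((f"s{s:03d}", w, bool(is_word[i]),
                         bool(correct[i]), float(rt), planted))
    trials = pd.DataFrame(
        rows, columns=["subject", "word", "is_word", "correct", "rt",
                       "planted_outlier"])
    truth = {"baseline": spec.baseline, "effects": dict(spec.effects),
             "subject_intercepts": subj_int.tolist(),
             "n_planted_outliers": n_outliers}
    return trials, truth
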
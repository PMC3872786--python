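"""Semantic neighborhood density measures: NCOUNT, INV-NCOUNT, ARC.

A word's neighbors are the vocabulary items whose cosine similarity to it
meets the neighborhood membership threshold θ, which is derived from the
mean and standard deviation of similarities between randomly sampled word
pairs (θ = μ + λσ on the similarity scale, so neighbors are unusually
close words).  NCOUNT is the neighbor count, INV-NCOUNT = 1/(NCOUNT + 1),
and ARC (average radius of co-occurrence) is the mean similarity between
the word and its neighbors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corpus import CoocSpace, ZeroVectorError, similarities_to

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 1.5
DEFAULT_N_PAIRS = 1_000_000


@dataclass(frozen=True)
class PairSampleStats:
    """Mean/SD of cosine similarity over randomly sampled word pairs."""

    mean: float
    sd: float
    n_pairs: int
    seed: int


@dataclass(frozen=True)
class NeighborhoodStats:
    """Per-word neighborhood summary at threshold θ.

    ``arc`` is NaN when the neighborhood is empty (the mean over zero
    neighbors is undefined); downstream tables flag rather than zero-fill.
    """

    word: str
    threshold: float
    ncount: int
    inv_ncount: float
    arc: float


def sample_pair_stats(space: CoocSpace, n_pairs: int = DEFAULT_N_PAIRS,
                      seed: int = 0) -> PairSampleStats:
    """μ and σ of cosine over uniformly sampled distinct word pairs.

    Pairs are distinct within a draw; draws are with replacement across
    pairs.  If ``n_pairs`` meets or exceeds the number of distinct pairs,
    every distinct pair is enumerated exactly once instead.  Zero-vector
    words are excluded from sampling (their cosine is undefined).
    """
    norms = space.row_norms()
    live = np.flatnonzero(norms > 0)
    nv = live.size
    if nv < 2:
        raise ValueError("need at least 2 words with nonzero vectors")
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")

    n_distinct = nv * (nv - 1) // 2
    normed = space.matrix[live].multiply(1.0 / norms[live][:, None]).tocsr()

    if n_pairs >= n_distinct:
        sims_mat = np.asarray((normed @ normed.T).todense())
        iu = np.triu_indices(nv, k=1)
        sims = sims_mat[iu]
        used = n_distinct
    else:
        rng = np.random.default_rng(seed)
        a = rng.integers(0, nv, size=n_pairs)
        b = rng.integers(0, nv - 1, size=n_pairs)
        b = np.where(b >= a, b + 1, b)  # distinct within a pair
        sims = np.asarray(normed[a].multiply(normed[b]).sum(axis=1)).ravel()
        used = n_pairs
    return PairSampleStats(mean=float(np.mean(sims)),
                           sd=float(np.std(sims, ddof=1)),
                           n_pairs=used, seed=seed)


def neighbor_threshold(stats: PairSampleStats,
                       lam: float = DEFAULT_LAMBDA) -> float:
    """Neighborhood membership threshold θ = μ + λσ."""
    return stats.mean + lam * stats.sd


def neighborhood_stats(space: CoocSpace, word: str, threshold: float
                       ) -> NeighborhoodStats:
    """NCOUNT, INV-NCOUNT and ARC for one word at threshold θ.

    Neighbors are vocabulary words (excluding the target itself) with
    cosine ≥ θ; words with zero vectors can never be neighbors.
    """
    sims = similarities_to(space, word)  # raises for OOV / zero vector
    i = space.row_index(word)
    sims[i] = np.nan  # a word is never its own neighbor
    mask = sims >= threshold  # NaN compares False
    ncount = int(mask.sum())
    arc = float(np.mean(sims[mask])) if ncount else math.nan
    return NeighborhoodStats(word=word, threshold=threshold, ncount=ncount,
                             inv_ncount=1.0 / (ncount + 1), arc=arc)


def neighborhood_table(space: CoocSpace, words: list[str] | None = None,
                       lam: float = DEFAULT_LAMBDA,
                       n_pairs: int = DEFAULT_N_PAIRS,
                       seed: int = 0,
                       threshold: float | None = None) -> pd.DataFrame:
    """Neighborhood stats for many words as a DataFrame.

    Columns: word, threshold, ncount, inv_ncount, arc.  Words whose
    vectors are all-zero are skipped with a logged count.
    """
    if threshold is None:
        stats = sample_pair_stats(space, n_pairs=n_pairs, seed=seed)
        threshold = neighbor_threshold(stats, lam)
        logger.info("pair stats: mean=%.4f sd=%.4f -> threshold=%.4f",
                    stats.mean, stats.sd, threshold)
    words = list(words) if words is not None else list(space.vocabulary)
    rows, skipped = [], 0
    for w in words:
        try:
            ns = neighborhood_stats(space, w, threshold)
        except ZeroVectorError:
            skipped += 1
            continue
        rows.append((ns.word, ns.threshold, ns.ncount, ns.inv_ncount, ns.arc))
    if skipped:
        logger.warning("skipped %d words with zero vectors", skipped)
    return pd.DataFrame(
        rows, columns=["word", "threshold", "ncount", "inv_ncount", "arc"])
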
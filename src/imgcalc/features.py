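"""Per-word predictor construction.

Builds the rows fed to the imageability regressions: cosine similarity to
each emotion seed term, the two neighborhood density measures (ARC,
INV-NCOUNT), and the lexical covariates LENGTH (letters), LNFREQUENCY
(natural log of the raw corpus count) and ON (Coltheart's orthographic
neighborhood: same-length words differing in exactly one position).  Also
merges imageability norm tables from multiple sources onto a common 1-7
scale.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources as importlib_resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import CoocSpace, FrequencyTable, ZeroVectorError, similarities_to

logger = logging.getLogger(__name__)


class NormValidationError(ValueError):
    """A rating fell outside its source's declared scale bounds."""


@dataclass(frozen=True)
class EmotionLexicon:
    """Named sets of basic-emotion seed terms plus the model subsets.

    ``sources`` maps theorist set name to terms; ``all_terms`` is their
    78-term union; ``eight_term_model`` / ``full_model_terms`` are the
    subsets selected into the published 8-term and full models.
    """

    sources: dict[str, tuple[str, ...]]
    eight_term_model: tuple[str, ...]
    full_model_terms: tuple[str, ...]

    @property
    def all_terms(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for terms in self.sources.values():
            for t in terms:
                seen.setdefault(t)
        return tuple(sorted(seen))

    @classmethod
    def load(cls) -> "EmotionLexicon":
        ref = importlib_resources.files("imgcalc.resources") / "emotion_lexicon.json"
        data = json.loads(ref.read_text())
        return cls(
            sources={k: tuple(v) for k, v in data["sources"].items()},
            eight_term_model=tuple(data["eight_term_model"]),
            full_model_terms=tuple(data["full_model_terms"]),
        )


def emotion_similarities(space: CoocSpace, word: str,
                         terms: Sequence[str]) -> pd.Series:
    """Cosine similarity of ``word`` to each seed term, in input order.

    Terms missing from the vocabulary (or with zero vectors) are excluded
    and reported in the series' attrs under ``missing_terms``.
    """
    out: dict[str, float] = {}
    missing: list[str] = []
    sims = similarities_to(space, word)  # raises for OOV word
    for t in terms:
        if t not in space:
            missing.append(t)
            continue
        s = sims[space.row_index(t)]
        if math.isnan(s):
            missing.append(t)
            continue
        out[t] = float(s)
    ser = pd.Series(out, dtype=float)
    ser.attrs["missing_terms"] = missing
    if missing:
        logger.info("emotion terms unavailable for %r: %s", word, missing)
    return ser


def emotion_similarity_table(space: CoocSpace, words: Sequence[str],
                             terms: Sequence[str]) -> pd.DataFrame:
    """Word-by-term cosine similarity table; unavailable terms dropped.

    Column order follows the input term order restricted to terms present
    in the space with nonzero vectors.
    """
    norms = space.row_norms()
    usable = [t for t in terms
              if t in space and norms[space.row_index(t)] > 0]
    dropped = [t for t in terms if t not in usable]
    if dropped:
        logger.warning("dropping %d emotion terms not usable in this space: %s",
                       len(dropped), dropped)
    rows, kept = [], []
    for w in words:
        try:
            sims = similarities_to(space, w)
        except (KeyError, ZeroVectorError):
            continue
        rows.append([sims[space.row_index(t)] for t in usable])
        kept.append(w)
    return pd.DataFrame(rows, index=kept, columns=usable)


# ---------------------------------------------------------------------------
# lexical covariates


def orthographic_neighborhood(word: str, lexicon: Iterable[str]) -> int:
    """Coltheart's N: lexicon words of equal length differing in one letter."""
    n = 0
    L = len(word)
    for other in lexicon:
        if len(other) != L or other == word:
            continue
        diffs = sum(a != b for a, b in zip(word, other))
        if diffs == 1:
            n += 1
    return n


def lexical_covariates(word: str, freq: FrequencyTable,
                       lexicon: Iterable[str]) -> tuple[int, float, int]:
    """(LENGTH, LNFREQUENCY, ON) for one word.

    LNFREQUENCY is ln of the raw corpus count; a zero or missing count
    makes the word unusable and raises KeyError.
    """
    count = freq.get(word, 0)
    if count < 1:
        raise KeyError(f"word {word!r} has no corpus count")
    return len(word), math.log(count), orthographic_neighborhood(word, lexicon)


# ---------------------------------------------------------------------------
# norms


def merge_norms(sources: Sequence[tuple[pd.DataFrame, tuple[float, float]]]
                ) -> pd.DataFrame:
    """Merge rating tables from several sources onto a common 1-7 scale.

    Each source is (table with columns word/rating, (lo, hi) scale bounds).
    Ratings are affinely mapped from [lo, hi] onto [1, 7], then averaged
    (unweighted) across sources per word.  Returns columns word, rating,
    n_sources.  Order of sources does not affect the result.
    """
    frames = []
    for i, (table, (lo, hi)) in enumerate(sources):
        if hi <= lo:
            raise NormValidationError(f"source {i}: bad scale bounds ({lo}, {hi})")
        t = table[["word", "rating"]].copy()
        bad = t[(t["rating"] < lo) | (t["rating"] > hi)]
        if not bad.empty:
            w = bad.iloc[0]["word"]
            raise NormValidationError(
                f"rating out of declared bounds [{lo}, {hi}] for word "
                f"{w!r} in source {i}")
        t["rating"] = (t["rating"] - lo) / (hi - lo) * 6.0 + 1.0
        frames.append(t)
    allrows = pd.concat(frames, ignore_index=True)
    merged = (allrows.groupby("word", sort=True)["rating"]
              .agg(rating="mean", n_sources="size").reset_index())
    return merged


# ---------------------------------------------------------------------------
# assembly


def assemble_features(words: Sequence[str], space: CoocSpace,
                      neighborhoods: pd.DataFrame, freq: FrequencyTable,
                      lexicon: Iterable[str], terms: Sequence[str]
                      ) -> pd.DataFrame:
    """Inner-join all predictor components into one table.

    One row per word with columns: the emotion-term similarities (named by
    term), arc, inv_ncount, length, lnfrequency, on.  Rows with any
    missing component (empty neighborhood ARC, zero counts, zero vectors)
    are dropped with a logged count.  Duplicate input words are
    deduplicated.
    """
    words = list(dict.fromkeys(words))
    sim = emotion_similarity_table(space, words, terms)

    nb = neighborhoods.set_index("word")[["arc", "inv_ncount"]]

    lex_rows = {}
    lexicon = list(lexicon)
    for w in words:
        try:
            length, lnfreq, on = lexical_covariates(w, freq, lexicon)
        except KeyError:
            continue
        lex_rows[w] = (length, lnfreq, on)
    lex = pd.DataFrame.from_dict(
        lex_rows, orient="index", columns=["length", "lnfrequency", "on"])

    out = sim.join(nb, how="inner").join(lex, how="inner")
    out = out.dropna()
    dropped = len(words) - len(out)
    if dropped:
        logger.warning("assemble_features: dropped %d of %d words with "
                       "missing components", dropped, len(words))
    if out.empty:
        logger.warning("assemble_features: empty join")
    out.index.name = "word"
    return out
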
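"""Weighted, PPMI-normalized word co-occurrence spaces.

The space is built in the HAL family of co-occurrence models: a sliding
window of a few positions behind and ahead of each target word, a
distance-dependent weighting of context hits, PPMI association
normalization, and cosine similarity between word vectors.  Columns
("dimension words") are the most frequent vocabulary items; rows cover the
whole vocabulary, so rare words still get vectors over frequent contexts.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z]+")

WEIGHTING_SCHEMES = ("inverse_ramp", "ramp", "flat")


class ConfigError(ValueError):
    """Invalid space configuration."""


class EmptyCorpusError(ValueError):
    """No tokens to build a space from."""


class ZeroVectorError(ValueError):
    """Cosine similarity is undefined for an all-zero vector."""


@dataclass(frozen=True)
class SpaceConfig:
    """Hyperparameters of a co-occurrence space.

    Defaults follow the standard HAL/HiDEx-style parameterization: a
    5-behind/5-ahead window, inverse-ramp distance weighting, the 10,000
    most frequent words as context dimensions, PPMI normalization, and
    cosine similarity.
    """

    window_behind: int = 5
    window_ahead: int = 5
    weighting_scheme: str = "inverse_ramp"
    context_size: int = 10_000
    normalization: str = "ppmi"
    similarity: str = "cosine"
    min_word_count: int = 1
    concatenate_windows: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_behind < 1 or self.window_ahead < 1:
            raise ConfigError("window lengths must be >= 1")
        if self.context_size < 1:
            raise ConfigError("context_size must be >= 1")
        if self.weighting_scheme not in WEIGHTING_SCHEMES:
            raise ConfigError(
                f"unknown weighting scheme {self.weighting_scheme!r}; "
                f"choose one of {WEIGHTING_SCHEMES}"
            )
        if self.normalization not in ("ppmi", "none"):
            raise ConfigError("normalization must be 'ppmi' or 'none'")
        if self.similarity != "cosine":
            raise ConfigError("only cosine similarity is supported")


@dataclass
class FrequencyTable:
    """Raw corpus counts per word plus the total token count."""

    counts: dict[str, int]
    total: int

    @classmethod
    def from_tokens(cls, docs: Iterable[Sequence[str]]) -> "FrequencyTable":
        counts: dict[str, int] = {}
        total = 0
        for doc in docs:
            for tok in doc:
                counts[tok] = counts.get(tok, 0) + 1
                total += 1
        return cls(counts=counts, total=total)

    def __getitem__(self, word: str) -> int:
        return self.counts[word]

    def get(self, word: str, default: int = 0) -> int:
        return self.counts.get(word, default)


@dataclass
class CoocSpace:
    """A sparse word-by-dimension co-occurrence matrix with its provenance.

    Rows are ordered by ``vocabulary``; columns by ``dimensions``
    (the ``context_size`` most frequent vocabulary items, frequency ties
    broken lexicographically).  ``matrix`` holds weighted counts, or PPMI
    values once :func:`ppmi_normalize` has run (``normalized`` records
    which).
    """

    vocabulary: list[str]
    dimensions: list[str]
    matrix: sp.csr_matrix
    config: SpaceConfig
    frequency: FrequencyTable
    normalized: bool = False
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _row_norms: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def row_index(self, word: str) -> int:
        try:
            return self._index[word]
        except KeyError:
            raise KeyError(f"word not in vocabulary: {word!r}") from None

    def vector(self, word: str) -> np.ndarray:
        return np.asarray(self.matrix[self.row_index(word)].todense()).ravel()

    def row_norms(self) -> np.ndarray:
        if self._row_norms is None:
            self._row_norms = np.sqrt(
                np.asarray(self.matrix.multiply(self.matrix).sum(axis=1)).ravel()
            )
        return self._row_norms

    # -- persistence --------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Write the matrix as Matrix Market + a JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / "space.mtx"), self.matrix.tocoo())
        sidecar = {
            "vocabulary": self.vocabulary,
            "dimensions": self.dimensions,
            "config": asdict(self.config),
            "frequency": {"counts": self.frequency.counts,
                          "total": self.frequency.total},
            "normalized": self.normalized,
        }
        (outdir / "space.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, indir: str | Path) -> "CoocSpace":
        indir = Path(indir)
        matrix = sp.csr_matrix(scipy.io.mmread(str(indir / "space.mtx")))
        meta = json.loads((indir / "space.json").read_text())
        return cls(
            vocabulary=meta["vocabulary"],
            dimensions=meta["dimensions"],
            matrix=matrix,
            config=SpaceConfig(**meta["config"]),
            frequency=FrequencyTable(counts=meta["frequency"]["counts"],
                                     total=meta["frequency"]["total"]),
            normalized=meta["normalized"],
        )


# ---------------------------------------------------------------------------
# tokenization and counting


def tokenize(text: str) -> list[str]:
    """Lowercased alphabetic tokens; punctuation and digits are stripped."""
    return _TOKEN_RE.findall(text.lower())


def tokenize_documents(texts: Iterable[str]) -> list[list[str]]:
    """Tokenize each document separately (documents are window barriers)."""
    return [tokenize(t) for t in texts]


def read_corpus(path: str | Path) -> list[list[str]]:
    """Read a corpus: one document per line, or a directory of .txt files."""
    path = Path(path)
    if path.is_dir():
        texts = [p.read_text(encoding="utf-8")
                 for p in sorted(path.glob("*.txt"))]
    else:
        texts = path.read_text(encoding="utf-8").splitlines()
    return tokenize_documents(texts)


def count_frequencies(docs: Iterable[Sequence[str]]) -> FrequencyTable:
    """Exact token counts over a tokenized document stream."""
    return FrequencyTable.from_tokens(docs)


# ---------------------------------------------------------------------------
# window weights


def window_weights(scheme: str, length: int) -> np.ndarray:
    """Per-distance weights for d = 1..length.

    inverse_ramp: w(d) = 1/d  (nearest positions dominate)
    ramp:         w(d) = length - d + 1
    flat:         w(d) = 1
    """
    if length < 1:
        raise ConfigError("window length must be >= 1")
    d = np.arange(1, length + 1, dtype=float)
    if scheme == "inverse_ramp":
        return 1.0 / d
    if scheme == "ramp":
        return length - d + 1.0
    if scheme == "flat":
        return np.ones_like(d)
    raise ConfigError(f"unknown weighting scheme {scheme!r}")


# ---------------------------------------------------------------------------
# matrix construction


def _ordered_vocabulary(freq: FrequencyTable, min_count: int) -> list[str]:
    # descending frequency, ties lexicographic — dimension words are a prefix
    items = [(w, c) for w, c in freq.counts.items() if c >= min_count]
    excluded = len(freq.counts) - len(items)
    if excluded:
        logger.warning("excluding %d words below min_word_count", excluded)
    items.sort(key=lambda wc: (-wc[1], wc[0]))
    return [w for w, _ in items]


def build_cooc(docs: Sequence[Sequence[str]], config: SpaceConfig) -> CoocSpace:
    """Accumulate the weighted co-occurrence matrix (pre-normalization).

    Entry (w, c) sums weight(d) over every occurrence of dimension word c
    at distance d within ``window_behind`` before or ``window_ahead`` after
    an occurrence of w.  Windows never cross document boundaries.  With
    ``concatenate_windows`` the behind and ahead halves occupy separate
    column blocks instead of being summed.
    """
    docs = [d for d in docs if d]
    freq = count_frequencies(docs)
    if freq.total == 0:
        raise EmptyCorpusError("corpus contains no tokens")

    vocab = _ordered_vocabulary(freq, config.min_word_count)
    csize = config.context_size
    if csize > len(vocab):
        warnings.warn(
            f"context_size {csize} exceeds vocabulary size {len(vocab)}; "
            "using full vocabulary", stacklevel=2)
        csize = len(vocab)
    dims = vocab[:csize]

    widx = {w: i for i, w in enumerate(vocab)}
    didx = {w: i for i, w in enumerate(dims)}
    wb = window_weights(config.weighting_scheme, config.window_behind)
    wa = window_weights(config.weighting_scheme, config.window_ahead)

    ncols = 2 * len(dims) if config.concatenate_windows else len(dims)
    ahead_off = len(dims) if config.concatenate_windows else 0

    cells: dict[tuple[int, int], float] = {}
    for doc in docs:
        ids = [widx.get(t, -1) for t in doc]
        dids = [didx.get(t, -1) for t in doc]
        n = len(doc)
        for i, wi in enumerate(ids):
            if wi < 0:
                continue
            for d in range(1, config.window_behind + 1):
                j = i - d
                if j < 0:
                    break
                cj = dids[j]
                if cj >= 0:
                    key = (wi, cj)
                    cells[key] = cells.get(key, 0.0) + wb[d - 1]
            for d in range(1, config.window_ahead + 1):
                j = i + d
                if j >= n:
                    break
                cj = dids[j]
                if cj >= 0:
                    key = (wi, cj + ahead_off)
                    cells[key] = cells.get(key, 0.0) + wa[d - 1]

    if cells:
        rows, cols = zip(*cells.keys())
        vals = list(cells.values())
    else:
        rows, cols, vals = (), (), ()
    matrix = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(vocab), ncols)
    ).tocsr()
    return CoocSpace(vocabulary=vocab, dimensions=dims, matrix=matrix,
                     config=config, frequency=freq)


def ppmi_normalize(space: CoocSpace) -> CoocSpace:
    """Positive pointwise mutual information transform of the weighted counts.

    Each cell becomes max(0, ln(p(w,c) / (p(w) p(c)))) with probabilities
    taken from the weighted-count marginals.  Natural log; base only
    rescales vectors and cosine is scale-invariant.  Zero cells stay zero.
    """
    X = space.matrix.tocoo(copy=True)
    total = X.data.sum()
    if total == 0:
        raise ValueError("cannot PPMI-normalize an all-zero matrix")
    row_marg = np.asarray(space.matrix.sum(axis=1)).ravel()
    col_marg = np.asarray(space.matrix.sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(X.data * total / (row_marg[X.row] * col_marg[X.col]))
    X.data = np.maximum(pmi, 0.0)
    out = X.tocsr()
    out.eliminate_zeros()
    return CoocSpace(vocabulary=space.vocabulary, dimensions=space.dimensions,
                     matrix=out, config=space.config, frequency=space.frequency,
                     normalized=True)


def build_space(docs: Sequence[Sequence[str]], config: SpaceConfig | None = None
                ) -> CoocSpace:
    """Build and (per config) PPMI-normalize a co-occurrence space."""
    config = config or SpaceConfig()
    space = build_cooc(docs, config)
    if config.normalization == "ppmi":
        space = ppmi_normalize(space)
    return space


# ---------------------------------------------------------------------------
# similarity


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; in [0, 1] for non-negative vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroVectorError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def pairwise_cosine(space: CoocSpace, words: Sequence[str] | None = None
                    ) -> tuple[np.ndarray, list[str]]:
    """Dense cosine-similarity matrix between the given words (all if None).

    Zero-vector words get NaN similarities rather than raising, so callers
    can filter; a warning reports how many rows were degenerate.
    """
    if words is None:
        words = space.vocabulary
    idx = [space.row_index(w) for w in words]
    sub = space.matrix[idx]
    norms = np.sqrt(np.asarray(sub.multiply(sub).sum(axis=1)).ravel())
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero vectors in cosine block",
                      stacklevel=2)
    safe = np.where(zero, 1.0, norms)
    normed = sp.diags(1.0 / safe) @ sub
    sims = np.asarray((normed @ normed.T).todense())
    sims[zero, :] = np.nan
    sims[:, zero] = np.nan
    return sims, list(words)


def similarities_to(space: CoocSpace, word: str) -> np.ndarray:
    """Cosine of ``word`` against every vocabulary row (NaN for zero rows)."""
    i = space.row_index(word)
    v = space.matrix[i]
    nv = np.sqrt(v.multiply(v).sum())
    if nv == 0:
        raise ZeroVectorError(f"word {word!r} has an all-zero vector")
    norms = space.row_norms()
    dots = np.asarray((space.matrix @ v.T).todense()).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = dots / (norms * nv)
    sims[norms == 0] = np.nan
    return sims
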
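"""Shared fixtures: toy corpora, hand-built spaces, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

import imgcalc as ic
from imgcalc.corpus import CoocSpace, FrequencyTable, SpaceConfig

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


def make_space(words: list[str], matrix: np.ndarray,
               counts: dict[str, int] | None = None,
               dims: list[str] | None = None) -> CoocSpace:
    """Hand-built space: rows = words, columns = dims (default: words)."""
    matrix = np.asarray(matrix, dtype=float)
    if counts is None:
        counts = {w: 10 for w in words}
    cfg = SpaceConfig(context_size=matrix.shape[1], normalization="none")
    return CoocSpace(vocabulary=list(words),
                     dimensions=list(dims or words[:matrix.shape[1]]),
                     matrix=sp.csr_matrix(matrix), config=cfg,
                     frequency=FrequencyTable(counts=counts,
                                              total=sum(counts.values())))


def brute_force_cooc(docs: list[list[str]], vocab: list[str],
                     dims: list[str], scheme: str,
                     behind: int, ahead: int) -> np.ndarray:
    """Quadratic double-loop co-occurrence oracle (independent of the
    sliding-window implementation)."""
    def weight(d: int, length: int) -> float:
        return {"inverse_ramp": 1.0 / d,
                "ramp": length - d + 1.0,
                "flat": 1.0}[scheme]

    widx = {w: i for i, w in enumerate(vocab)}
    didx = {w: i for i, w in enumerate(dims)}
    M = np.zeros((len(vocab), len(dims)))
    for doc in docs:
        for i, w in enumerate(doc):
            if w not in widx:
                continue
            for j, c in enumerate(doc):
                if j == i or c not in didx:
                    continue
                if i - behind <= j < i:  # context behind the target
                    M[widx[w], didx[c]] += weight(i - j, behind)
                elif i < j <= i + ahead:  # context ahead
                    M[widx[w], didx[c]] += weight(j - i, ahead)
    return M


def brute_force_on(word: str, lexicon: list[str]) -> int:
    """Independent orthographic-neighborhood oracle."""
    return sum(
        1 for other in lexicon
        if other != word and len(other) == len(word)
        and sum(a != b for a, b in zip(word, other)) == 1
    )


@pytest.fixture(scope="session")
def topic_docs():
    docs, topic_of = ic.generate_corpus(ic.CorpusSpec(
        vocab_size=120, n_topics=4, n_documents=150, doc_length=60,
        mixing=0.05, seed=7))
    return docs, topic_of


@pytest.fixture(scope="session")
def topic_space(topic_docs):
    docs, _ = topic_docs
    return ic.build_space(docs, SpaceConfig(context_size=120, seed=7))


@pytest.fixture(scope="session")
def mixed_space():
    """Space with substantial topic mixing: smoother similarity structure
    (no exactly-zero cross-topic similarity columns)."""
    docs, _ = ic.generate_corpus(ic.CorpusSpec(
        vocab_size=120, n_topics=6, n_documents=200, doc_length=60,
        mixing=0.3, seed=7))
    return ic.build_space(docs, SpaceConfig(context_size=120, seed=7))


@pytest.fixture(scope="session")
def raw_topic_space(topic_docs):
    docs, _ = topic_docs
    return ic.build_cooc(docs, SpaceConfig(context_size=120,
                                           normalization="none", seed=7))
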
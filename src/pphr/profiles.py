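"""Physician profiles: TF-IDF keywords over per-physician question pools.

A physician's pseudo-document is the concatenation of the token lists of
every question addressed to them.  TF-IDF scores each term t in document d
as TF(t, d) x IDF(t), with

    TF(t, d)  = count(t in d) / |d|            (relative frequency; ``raw``
                                                count is the alternative)
    IDF(t)    = ln((1 + N) / (1 + df(t))) + 1   (``smooth``, the default)
              = ln(N / df(t))                   (``plain``)

The top 20 terms by weight form the profile; the profile text (keywords
joined in descending-weight order) is embedded, and pairwise cosine between
profile vectors is the physician-physician similarity that drives candidate
expansion.  The TF normalization constant does not change within-document
term ranking, so the extracted keyword sets agree with a raw-count
vectorizer under the same IDF.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .embed import EmbeddingMatrix, embed_texts

__all__ = [
    "PhysicianProfile",
    "PhysicianSimilarity",
    "aggregate_by_physician",
    "tfidf_top_keywords",
    "build_profiles",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhysicianProfile:
    """Top TF-IDF keywords of one physician plus their profile embedding."""

    physician_code: str
    keywords: tuple[tuple[str, float], ...]  # (term, weight), weight desc
    profile_text: str
    profile_vector: np.ndarray


@dataclass
class PhysicianSimilarity:
    """Symmetric physician-physician cosine matrix with unit diagonal."""

    codes: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.codes)
        if self.matrix.shape != (n, n):
            raise ValueError("similarity matrix must be square over codes")
        self._index = {c: i for i, c in enumerate(self.codes)}

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def sim(self, code_i: str, code_j: str) -> float:
        return float(self.matrix[self._index[code_i], self._index[code_j]])

    def neighbors(self, code: str) -> list[tuple[str, float]]:
        """All other physicians with their similarity to ``code``, desc."""
        i = self._index[code]
        pairs = [
            (c, float(self.matrix[i, j]))
            for j, c in enumerate(self.codes)
            if j != i
        ]
        return sorted(pairs, key=lambda p: (-p[1], p[0]))


def aggregate_by_physician(tokenized, records) -> dict[str, list[str]]:
    """Concatenate each physician's question tokens into one pseudo-document.

    ``tokenized`` is a list of TokenizedQuestion; ``records`` supplies the
    question -> physician mapping.  A tokenized question whose id has no
    record is an error.
    """
    q2p = {r.question_id: r.physician_code for r in records}
    docs: dict[str, list[str]] = {}
    for tq in tokenized:
        if tq.question_id not in q2p:
            raise KeyError(
                f"tokenized question {tq.question_id!r} has no matching record"
            )
        docs.setdefault(q2p[tq.question_id], []).extend(tq.tokens)
    return docs


def tfidf_top_keywords(
    documents: dict[str, list[str]],
    top_n: int = 20,
    tf_mode: str = "relative",
    idf_mode: str = "smooth",
) -> dict[str, list[tuple[str, float]]]:
    """Top ``top_n`` TF-IDF keywords per document, weights descending.

    Ties in weight break by ascending term so extraction is deterministic.
    An empty document yields an empty keyword list (with a warning).
    """
    if not documents:
        raise ValueError("need at least one document")
    if tf_mode not in {"relative", "raw"}:
        raise ValueError(f"unknown tf_mode: {tf_mode!r}")
    if idf_mode not in {"smooth", "plain"}:
        raise ValueError(f"unknown idf_mode: {idf_mode!r}")

    n_docs = len(documents)
    df: Counter[str] = Counter()
    for tokens in documents.values():
        df.update(set(tokens))

    def idf(term: str) -> float:
        if idf_mode == "smooth":
            return math.log((1 + n_docs) / (1 + df[term])) + 1.0
        return math.log(n_docs / df[term])

    out: dict[str, list[tuple[str, float]]] = {}
    for code, tokens in documents.items():
        if not tokens:
            logger.warning("physician %s has an empty document; no keywords", code)
            out[code] = []
            continue
        counts = Counter(tokens)
        length = len(tokens)
        weights = {
            t: (c / length if tf_mode == "relative" else float(c)) * idf(t)
            for t, c in counts.items()
        }
        ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
        out[code] = [(t, float(w)) for t, w in ranked[:top_n]]
    return out


def build_profiles(
    keywords: dict[str, list[tuple[str, float]]], backend
) -> tuple[dict[str, PhysicianProfile], PhysicianSimilarity]:
    """Embed keyword profiles and compute pairwise physician similarity.

    Physicians with an empty keyword list get no profile (and can never be
    expansion targets); this is logged, not an error.
    """
    codes = sorted(c for c, kws in keywords.items() if kws)
    skipped = sorted(set(keywords) - set(codes))
    if skipped:
        logger.warning(
            "physicians without keywords excluded from profiles: %s", skipped
        )
    if not codes:
        raise ValueError("no physician has a non-empty keyword list")
    texts = [" ".join(t for t, _ in keywords[c]) for c in codes]
    matrix: EmbeddingMatrix = embed_texts(texts, backend, ids=codes)
    profiles = {
        c: PhysicianProfile(
            physician_code=c,
            keywords=tuple(keywords[c]),
            profile_text=texts[i],
            profile_vector=matrix.vectors[i],
        )
        for i, c in enumerate(codes)
    }
    sim = matrix.vectors @ matrix.vectors.T
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return profiles, PhysicianSimilarity(codes=codes, matrix=sim)
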
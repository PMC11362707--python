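"""Interchangeable text-embedding backends behind one contract.

Every backend maps a list of texts to L2-normalized fixed-dimension vectors;
retrieval then reduces to cosine similarity, which on unit vectors is a dot
product.  Three backends:

``hash_ngram``
    The default and the one the test suite relies on: character n-grams are
    hashed (keyed BLAKE2b, so the mapping is stable across platforms and
    Python processes) into ``dim`` count buckets, then L2-normalized.  Fully
    deterministic, needs no model download, and preserves enough lexical
    signal for retrieval over keyword-dominated clinical questions.

``transformer``
    Adapter for a pretrained sentence encoder via ``sentence-transformers``
    (default model ``distiluse-base-multilingual-cased``).  Raises
    :class:`BackendUnavailableError` when the library or model is absent —
    never a silent fallback.

``paragraph_vector``
    Adapter for gensim Doc2Vec, trained on the given corpus with a fixed
    seed.  Same unavailability contract.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EmbeddingMatrix",
    "BackendUnavailableError",
    "HashNgramBackend",
    "TransformerBackend",
    "ParagraphVectorBackend",
    "get_backend",
    "embed_texts",
    "cosine",
    "similarity_search",
]


class BackendUnavailableError(RuntimeError):
    """The requested embedding backend cannot run in this environment."""


@dataclass
class EmbeddingMatrix:
    """Ids plus one unit-norm vector per id, with backend provenance."""

    ids: list[str]
    vectors: np.ndarray
    backend_tag: str

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or len(self.ids) != self.vectors.shape[0]:
            raise ValueError("ids and vectors must align (one row per id)")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms <= 0):
            raise ValueError("every vector must have strictly positive norm")

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __len__(self) -> int:
        return len(self.ids)

    def vector_for(self, item_id: str) -> np.ndarray:
        return self.vectors[self.ids.index(item_id)]


class HashNgramBackend:
    """Deterministic character-n-gram hashing vectorizer.

    Each overlapping character n-gram of the (de-spaced when requested)
    text is hashed into one of ``dim`` buckets; bucket counts are
    L2-normalized.  The hash is keyed BLAKE2b with ``seed`` as key, so the
    bucket assignment is a documented function of (token, seed, dim) only.
    """

    def __init__(self, dim: int = 512, ngram: int = 3, seed: int = 0,
                 strip_spaces: bool = False):
        if dim < 1 or ngram < 1:
            raise ValueError("dim and ngram must be positive")
        self.dim = dim
        self.ngram = ngram
        self.seed = seed
        self.strip_spaces = strip_spaces
        self._key = int(seed).to_bytes(8, "little", signed=True)

    @property
    def tag(self) -> str:
        return f"hash_ngram(dim={self.dim},n={self.ngram},seed={self.seed})"

    def _bucket(self, token: str) -> int:
        digest = hashlib.blake2b(
            token.encode("utf-8"), digest_size=8, key=self._key
        ).digest()
        return int.from_bytes(digest, "little") % self.dim

    def bucket_counts(self, text: str) -> dict[int, int]:
        """Raw bucket counts for one text (before normalization)."""
        s = text.replace(" ", "") if self.strip_spaces else text
        counts: dict[int, int] = {}
        for i in range(max(len(s) - self.ngram + 1, 0)):
            b = self._bucket(s[i : i + self.ngram])
            counts[b] = counts.get(b, 0) + 1
        if not counts and s:
            # shorter than one n-gram: hash the whole text
            counts[self._bucket(s)] = 1
        return counts

    def encode(self, texts: list[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim), dtype=np.float64)
        for row, text in enumerate(texts):
            for bucket, count in self.bucket_counts(text).items():
                out[row, bucket] = count
            norm = np.linalg.norm(out[row])
            if norm == 0:
                raise ValueError(f"text {row} produced an empty embedding")
            out[row] /= norm
        return out


class TransformerBackend:
    """Pretrained sentence-encoder adapter (optional dependency)."""

    def __init__(self, model_id: str = "distiluse-base-multilingual-cased"):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:
            raise BackendUnavailableError(
                "transformer backend requires the sentence-transformers "
                "package and a local copy of the model; install the "
                "'transformer' extra"
            ) from exc
        try:
            self._model = SentenceTransformer(model_id)
        except Exception as exc:  # no local model, no network, ...
            raise BackendUnavailableError(
                f"could not load sentence encoder {model_id!r}: {exc}"
            ) from exc
        self.model_id = model_id

    @property
    def tag(self) -> str:
        return f"transformer({self.model_id})"

    def encode(self, texts: list[str]) -> np.ndarray:
        vecs = np.asarray(self._model.encode(list(texts)), dtype=np.float64)
        norms = np.linalg.norm(vecs, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("encoder produced a zero vector")
        return vecs / norms


class ParagraphVectorBackend:
    """Doc2Vec adapter trained on the given corpus (optional dependency).

    Hyperparameters are configuration with documented defaults, not claims:
    dim 128, window 5, 40 epochs, min_count 1, fixed seed, single worker for
    reproducibility.
    """

    def __init__(self, dim: int = 128, window: int = 5, epochs: int = 40,
                 seed: int = 2023):
        try:
            import gensim  # noqa: F401
        except ImportError as exc:
            raise BackendUnavailableError(
                "paragraph_vector backend requires gensim; install the "
                "'paragraph-vector' extra"
            ) from exc
        self.dim = dim
        self.window = window
        self.epochs = epochs
        self.seed = seed

    @property
    def tag(self) -> str:
        return f"paragraph_vector(dim={self.dim},seed={self.seed})"

    def encode(self, texts: list[str]) -> np.ndarray:
        from gensim.models.doc2vec import Doc2Vec, TaggedDocument

        docs = [
            TaggedDocument(words=t.split(), tags=[i])
            for i, t in enumerate(texts)
        ]
        model = Doc2Vec(
            docs, vector_size=self.dim, window=self.window,
            epochs=self.epochs, min_count=1, seed=self.seed, workers=1,
        )
        vecs = np.asarray(
            [model.dv[i] for i in range(len(texts))], dtype=np.float64
        )
        norms = np.linalg.norm(vecs, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("paragraph-vector produced a zero vector")
        return vecs / norms


def get_backend(name: str, **kwargs):
    """Instantiate a backend by name: hash_ngram | transformer | paragraph_vector."""
    if name == "hash_ngram":
        return HashNgramBackend(**kwargs)
    if name == "transformer":
        return TransformerBackend(**kwargs)
    if name == "paragraph_vector":
        return ParagraphVectorBackend(**kwargs)
    raise ValueError(f"unknown embedding backend: {name!r}")


def embed_texts(texts: list[str], backend, ids: list[str] | None = None) -> EmbeddingMatrix:
    """Encode texts into an :class:`EmbeddingMatrix` (unit-norm rows)."""
    if len(texts) == 0:
        raise ValueError("no texts to embed")
    if ids is None:
        ids = [str(i) for i in range(len(texts))]
    return EmbeddingMatrix(
        ids=list(ids), vectors=backend.encode(list(texts)), backend_tag=backend.tag
    )


def cosine(u, v) -> float:
    """Cosine similarity u.v / (|u||v|); symmetric, scale-invariant."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal dimension")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for zero-norm vectors")
    return float(np.dot(u, v) / (nu * nv))


def similarity_search(
    query, index: EmbeddingMatrix, top_m: int
) -> list[tuple[str, float]]:
    """Top ``top_m`` items of ``index`` by cosine with ``query``.

    Ties broken by ascending id, so the ranking is deterministic.  Asking
    for more items than the index holds returns the full ranking with a
    warning.
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    q = np.asarray(query, dtype=np.float64)
    nq = np.linalg.norm(q)
    if nq == 0:
        raise ValueError("cosine undefined for zero-norm query")
    scores = index.vectors @ (q / nq)
    norms = np.linalg.norm(index.vectors, axis=1)
    scores = scores / norms
    if top_m > len(index):
        warnings.warn(
            f"top_m={top_m} exceeds index size {len(index)}; returning all",
            stacklevel=2,
        )
        top_m = len(index)
    order = sorted(range(len(index)), key=lambda i: (-scores[i], index.ids[i]))
    return [(index.ids[i], float(scores[i])) for i in order[:top_m]]
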
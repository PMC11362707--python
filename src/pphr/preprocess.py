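"""Text normalization, tokenization and stop-word filtering.

The pipeline turns each free-text consultation question into a reliable token
list: Unicode NFKC normalization (full-width forms to half-width), case
folding, whitespace collapsing; then either whitespace/pluggable-segmenter
word tokenization or segmenter-free overlapping character n-grams; then an
order-preserving stop-word filter.

A part-of-speech hook is available for stop-word-class filtering but the
default pipeline does not tag: no downstream stage consumes tags.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "TokenizedQuestion",
    "normalize",
    "tokenize",
    "remove_stopwords",
    "load_stopwords",
    "preprocess_text",
    "preprocess_records",
]


@dataclass(frozen=True)
class TokenizedQuestion:
    question_id: str
    tokens: tuple[str, ...]


def normalize(text: str) -> str:
    """Case-fold, NFKC-normalize and collapse whitespace; idempotent."""
    text = unicodedata.normalize("NFKC", text)
    text = text.casefold()
    return " ".join(text.split())


def tokenize(
    text: str,
    mode: str = "word",
    ngram: int = 2,
    segmenter: Callable[[str], Iterable[str]] | None = None,
) -> list[str]:
    """Split normalized text into tokens.

    ``word`` mode uses ``segmenter`` when given (e.g. a Chinese word
    segmenter), else whitespace splitting; ``chargram`` mode emits
    overlapping character n-grams of the de-spaced text, which needs no
    segmenter at all.  Deterministic; empty text yields an empty list.
    """
    if mode == "word":
        if segmenter is not None:
            return [t for t in segmenter(text) if t and not t.isspace()]
        return text.split()
    if mode == "chargram":
        if ngram < 1:
            raise ValueError("ngram must be >= 1")
        s = text.replace(" ", "")
        return [s[i : i + ngram] for i in range(len(s) - ngram + 1)]
    raise ValueError(f"unknown tokenize mode: {mode!r}")


def remove_stopwords(tokens: Sequence[str], stoplist: set[str]) -> list[str]:
    """Order-preserving filter; result shares no token with ``stoplist``."""
    return [t for t in tokens if t not in stoplist]


def load_stopwords(path: str | Path) -> set[str]:
    """Read a stop-word list: one token per line, UTF-8, blank lines ignored."""
    out = set()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            tok = line.strip()
            if tok:
                out.add(tok)
    return out


def preprocess_text(
    text: str,
    mode: str = "word",
    ngram: int = 2,
    stoplist: set[str] | None = None,
    segmenter: Callable[[str], Iterable[str]] | None = None,
    pos_filter: Callable[[Sequence[str]], Sequence[str]] | None = None,
) -> list[str]:
    """Full pipeline: normalize, tokenize, optional POS filter, stop-words.

    A question whose tokens are all filtered away falls back to its
    normalized raw text as a single token, so every record stays embeddable.
    """
    norm = normalize(text)
    tokens: Sequence[str] = tokenize(norm, mode=mode, ngram=ngram, segmenter=segmenter)
    if pos_filter is not None:
        tokens = pos_filter(tokens)
    if stoplist:
        tokens = remove_stopwords(tokens, stoplist)
    tokens = [t for t in tokens if t]
    if not tokens and norm:
        tokens = [norm]
    return list(tokens)


def preprocess_records(
    records,
    mode: str = "word",
    ngram: int = 2,
    stoplist: set[str] | None = None,
    segmenter: Callable[[str], Iterable[str]] | None = None,
) -> list[TokenizedQuestion]:
    """Tokenize every record's question text (see :func:`preprocess_text`)."""
    return [
        TokenizedQuestion(
            question_id=r.question_id,
            tokens=tuple(
                preprocess_text(
                    r.question_text,
                    mode=mode,
                    ngram=ngram,
                    stoplist=stoplist,
                    segmenter=segmenter,
                )
            ),
        )
        for r in records
    ]
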
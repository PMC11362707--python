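"""Synthetic consultation corpora with known ground truth.

Real web-consultation corpora are private, so every stage of the pipeline
is exercised against generated corpora whose structure mirrors what the
method assumes about the real data:

* questions cluster into topics (here: bags of topic-specific keywords,
  since the pipeline consumes token statistics, not grammar);
* each physician specializes in 1-2 topics and receives questions drawn
  from those topics;
* response status is Bernoulli with a per-physician rate drawn uniformly
  from a configured range;
* response times are right-skewed lognormal minutes, with the physician's
  log-mean tied negatively to their response rate (active physicians answer
  faster), emulating the rate-time correlation seen on real platforms.

The generator is fully reproducible from its seed, and the returned
:class:`GroundTruth` records every latent quantity (question topics,
physician specialties, true rates) so tests can score recovery exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ConsultationRecord

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "ground_truth_relevance"]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs.

    Defaults model a mid-sized platform: 8 topics, 40 physicians each
    specialized in 1-2 topics, 4000 questions of 6-15 keywords with 10%
    off-topic noise, response rates uniform on [0.3, 0.95], and lognormal
    response times (mu 4.5, sigma 1.3 in log-minutes, i.e. median ~90 min
    and mean ~3.5 h, matching the skew of real consultation delays).
    ``time_rate_slope`` shifts a physician's log-mean by
    ``slope * (mean_rate - rate)``: higher-rate physicians respond faster.
    """

    n_topics: int = 8
    vocab_per_topic: int = 40
    shared_vocab: int = 30
    n_physicians: int = 40
    topics_per_physician: tuple[int, int] = (1, 2)
    n_questions: int = 4000
    tokens_per_question: tuple[int, int] = (6, 15)
    noise_rate: float = 0.1
    response_rate_range: tuple[float, float] = (0.3, 0.95)
    response_time_lognormal: tuple[float, float] = (4.5, 1.3)
    time_rate_slope: float = 2.0
    word_len: tuple[int, int] = (5, 8)
    seed: int = 2023

    def __post_init__(self) -> None:
        if min(self.n_topics, self.vocab_per_topic, self.n_physicians,
               self.n_questions) < 1:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate must lie in [0, 1)")
        lo, hi = self.response_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("response_rate_range must satisfy 0 <= lo <= hi <= 1")
        if not (1 <= self.topics_per_physician[0] <= self.topics_per_physician[1]
                <= self.n_topics):
            raise ValueError("topics_per_physician out of range")


@dataclass(frozen=True)
class GroundTruth:
    """Latent state behind a generated corpus."""

    question_topic: dict[str, int]
    question_physician: dict[str, str]
    physician_topics: dict[str, tuple[int, ...]]
    physician_rate: dict[str, float]
    topic_vocab: dict[int, tuple[str, ...]]
    shared_vocab: tuple[str, ...]


def _make_vocab(rng: np.random.Generator, cfg: SyntheticConfig):
    """Distinct random-letter words so hashed n-gram profiles separate topics."""
    needed = cfg.n_topics * cfg.vocab_per_topic + cfg.shared_vocab
    words: list[str] = []
    seen: set[str] = set()
    lo, hi = cfg.word_len
    attempts = 0
    while len(words) < needed:
        attempts += 1
        if attempts > 100 * needed:
            raise ValueError(
                "vocabulary too small for requested distinctness; "
                "increase word_len or reduce vocab sizes"
            )
        length = int(rng.integers(lo, hi + 1))
        w = "".join(_LETTERS[i] for i in rng.integers(0, len(_LETTERS), length))
        if w not in seen:
            seen.add(w)
            words.append(w)
    topic_vocab = {
        t: tuple(words[t * cfg.vocab_per_topic : (t + 1) * cfg.vocab_per_topic])
        for t in range(cfg.n_topics)
    }
    shared = tuple(words[cfg.n_topics * cfg.vocab_per_topic :])
    return topic_vocab, shared


def generate(cfg: SyntheticConfig) -> tuple[list[ConsultationRecord], GroundTruth]:
    """Draw a corpus and its ground truth; byte-reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    topic_vocab, shared = _make_vocab(rng, cfg)
    all_topic_words = [w for t in range(cfg.n_topics) for w in topic_vocab[t]]

    codes = [f"P{i:03d}" for i in range(cfg.n_physicians)]
    lo_t, hi_t = cfg.topics_per_physician
    physician_topics = {}
    for c in codes:
        n_t = int(rng.integers(lo_t, hi_t + 1))
        physician_topics[c] = tuple(
            sorted(int(t) for t in rng.choice(cfg.n_topics, size=n_t, replace=False))
        )
    lo_r, hi_r = cfg.response_rate_range
    physician_rate = {c: float(rng.uniform(lo_r, hi_r)) for c in codes}
    mean_rate = (lo_r + hi_r) / 2.0
    mu, sigma = cfg.response_time_lognormal
    physician_mu = {
        c: mu + cfg.time_rate_slope * (mean_rate - physician_rate[c]) for c in codes
    }

    records: list[ConsultationRecord] = []
    question_topic: dict[str, int] = {}
    question_physician: dict[str, str] = {}
    lo_n, hi_n = cfg.tokens_per_question
    noise_pool = list(shared) + all_topic_words
    for q in range(cfg.n_questions):
        qid = f"Q{q:06d}"
        code = codes[int(rng.integers(0, cfg.n_physicians))]
        topic = int(rng.choice(physician_topics[code]))
        n_tok = int(rng.integers(lo_n, hi_n + 1))
        tokens = []
        vocab = topic_vocab[topic]
        for _ in range(n_tok):
            if cfg.noise_rate > 0 and rng.random() < cfg.noise_rate:
                tokens.append(noise_pool[int(rng.integers(0, len(noise_pool)))])
            else:
                tokens.append(vocab[int(rng.integers(0, len(vocab)))])
        responded = bool(rng.random() < physician_rate[code])
        rt = (
            float(np.exp(rng.normal(physician_mu[code], sigma)))
            if responded
            else None
        )
        records.append(
            ConsultationRecord(
                question_id=qid,
                patient_code=f"U{int(rng.integers(0, max(cfg.n_questions // 3, 1))):06d}",
                physician_code=code,
                question_text=" ".join(tokens),
                response_status=responded,
                department=f"topic-{physician_topics[code][0]}",
                response_time_min=rt,
            )
        )
        question_topic[qid] = topic
        question_physician[qid] = code

    truth = GroundTruth(
        question_topic=question_topic,
        question_physician=question_physician,
        physician_topics=physician_topics,
        physician_rate=physician_rate,
        topic_vocab=topic_vocab,
        shared_vocab=shared,
    )
    return records, truth


def ground_truth_relevance(truth: GroundTruth, query_id: str) -> set[str]:
    """Physicians sharing at least one topic with the query's topic.

    The oracle relevant set for synthetic precision/recall: exactly the
    specialists of the query's topic.
    """
    if query_id not in truth.question_topic:
        raise KeyError(f"unknown query: {query_id!r}")
    topic = truth.question_topic[query_id]
    return {
        code
        for code, topics in truth.physician_topics.items()
        if topic in topics
    }
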
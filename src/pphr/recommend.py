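"""The three-step hybrid physician recommender.

Step 1 (PFB — patient feature–based): embed the new question, retrieve the
``top_m`` most similar historical questions, group them by physician; each
physician's ``init_score`` is the maximum similarity among their matched
questions and ``n`` counts the matches.  The best ``top_k`` physicians by
init_score become the direct candidate set.

Step 2 (PPH — patient-physician hybrid): every direct candidate i proposes
each other physician j with

    physician_score_j = init_score_i x expand_score_(i,j)

where expand_score is the physician-profile cosine similarity.  A proposal
is retained only when the product exceeds the expansion threshold (default
0.7); direct candidates carry expand_score = 1 and pass through unchanged.
Expansion is single-hop: expanded candidates do not seed further expansion.

Step 3 (PPHR): candidates are re-ranked by

    score_i = response_rate_i ** rate_exponent x sum(occurrence scores_i)

where a direct candidate contributes one occurrence per matched question
(each valued at its physician_score, i.e. n x max-similarity under the
default ``n_max`` aggregation, or the sum of the raw per-question
similarities under ``sum``) and an expanded candidate contributes one
occurrence per gate-passing seed.  The exact published form of this ranking
combines the same three quantities (similarity, occurrence count n and
response rate); the multiplicative rule here is the package's documented
reconstruction, and every output records the variant used.

Modes: ``PFB`` ranks by init_score only; ``PPH`` by the occurrence sum with
no response rate; ``PPHR`` is the full model.  All three share Step 1
retrieval so ablations isolate exactly one mechanism.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .embed import EmbeddingMatrix, similarity_search
from .profiles import PhysicianSimilarity
from .response import PhysicianStats

__all__ = [
    "Candidate",
    "RankedItem",
    "Recommendation",
    "candidates_from_matches",
    "generate_candidates",
    "expand_candidates",
    "rank_candidates",
    "Engine",
]

logger = logging.getLogger(__name__)

MODES = ("PFB", "PPH", "PPHR")
DEFAULT_THRESHOLD = 0.7
DEFAULT_TOP_M = 50
DEFAULT_K = 14


@dataclass(frozen=True)
class Candidate:
    """A physician under consideration for one query.

    ``physician_score`` is always ``init_score x expand_score`` exactly;
    direct candidates have ``expand_score == 1``.  ``occurrence_scores``
    holds one entry per matched question (direct) or per retaining seed
    (expanded) and feeds the Step-3 aggregation.
    """

    physician_code: str
    init_score: float
    expand_score: float
    physician_score: float
    n: int
    origin: str  # "direct" | "expanded"
    seed_code: str | None = None
    occurrence_scores: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.origin not in {"direct", "expanded"}:
            raise ValueError(f"bad origin: {self.origin!r}")
        if self.physician_score != self.init_score * self.expand_score:
            raise ValueError("physician_score must equal init_score * expand_score")
        if self.origin == "direct" and self.expand_score != 1.0:
            raise ValueError("direct candidates must have expand_score = 1")


@dataclass(frozen=True)
class RankedItem:
    physician_code: str
    score: float
    physician_score: float
    origin: str


@dataclass(frozen=True)
class Recommendation:
    """Ranked top-k physicians for one query.

    ``pool`` retains the full scored candidate set before top-k truncation;
    the evaluation module needs it to define the per-query relevant set.
    """

    query_id: str
    ranked: tuple[RankedItem, ...]
    k: int
    mode: str
    pool: tuple[Candidate, ...] = ()

    def codes(self) -> list[str]:
        return [item.physician_code for item in self.ranked]

    def truncated(self, k: int) -> "Recommendation":
        """The same ranking cut to a smaller k (pool unchanged)."""
        return replace(self, ranked=self.ranked[:k], k=min(k, len(self.ranked)))


def candidates_from_matches(
    matches: list[tuple[str, float]],
    question_to_physician: dict[str, str],
    top_k_physicians: int,
) -> list[Candidate]:
    """Group retrieved (question_id, similarity) pairs into direct candidates.

    init_score is the max similarity over the physician's matched questions,
    n their count; the top ``top_k_physicians`` physicians by init_score are
    kept (ties by ascending code).
    """
    per_phys: dict[str, list[float]] = {}
    for qid, sim in matches:
        if qid not in question_to_physician:
            raise KeyError(f"retrieved question {qid!r} has no physician mapping")
        per_phys.setdefault(question_to_physician[qid], []).append(float(sim))
    cands = []
    for code, sims in per_phys.items():
        best = max(sims)
        cands.append(
            Candidate(
                physician_code=code,
                init_score=best,
                expand_score=1.0,
                physician_score=best,
                n=len(sims),
                origin="direct",
                occurrence_scores=tuple(sorted(sims, reverse=True)),
            )
        )
    cands.sort(key=lambda c: (-c.init_score, c.physician_code))
    return cands[:top_k_physicians]


def generate_candidates(
    query_vector,
    question_index: EmbeddingMatrix,
    question_to_physician: dict[str, str],
    top_m_questions: int = DEFAULT_TOP_M,
    top_k_physicians: int = DEFAULT_K,
) -> list[Candidate]:
    """Step 1: retrieve similar questions and form the direct candidate set."""
    if len(question_index) == 0:
        raise ValueError("empty question index")
    if top_k_physicians < 1 or top_m_questions < top_k_physicians:
        raise ValueError("require top_m_questions >= top_k_physicians >= 1")
    matches = similarity_search(query_vector, question_index, top_m_questions)
    return candidates_from_matches(matches, question_to_physician, top_k_physicians)


def expand_candidates(
    direct: list[Candidate],
    similarity: PhysicianSimilarity,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[Candidate]:
    """Step 2: single-hop semantic expansion through physician similarity.

    For each direct candidate i and other physician j not already direct,
    j is proposed with physician_score = init_score_i x sim(i, j) and kept
    iff that product exceeds ``threshold``.  When several seeds retain the
    same j, the reported (init, expand, physician_score) triple comes from
    the best seed and every retaining seed contributes one occurrence term.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    direct_codes = {c.physician_code for c in direct}
    proposals: dict[str, list[tuple[float, float, float, str]]] = {}
    for cand in direct:
        if cand.physician_code not in similarity:
            logger.warning(
                "physician %s missing from similarity matrix; cannot seed expansion",
                cand.physician_code,
            )
            continue
        for other, sim in similarity.neighbors(cand.physician_code):
            if other in direct_codes:
                continue
            product = cand.init_score * sim
            if product > threshold:
                proposals.setdefault(other, []).append(
                    (product, cand.init_score, sim, cand.physician_code)
                )
    expanded = []
    for code, props in proposals.items():
        props.sort(key=lambda p: -p[0])
        best_product, best_init, best_sim, best_seed = props[0]
        expanded.append(
            Candidate(
                physician_code=code,
                init_score=best_init,
                expand_score=best_sim,
                physician_score=best_init * best_sim,
                n=1,
                origin="expanded",
                seed_code=best_seed,
                occurrence_scores=tuple(p[0] for p in props),
            )
        )
    expanded.sort(key=lambda c: (-c.physician_score, c.physician_code))
    return list(direct) + expanded


def _occurrence_sum(cand: Candidate, aggregation: str) -> float:
    if cand.origin == "direct":
        if aggregation == "n_max":
            return cand.n * cand.physician_score
        return float(sum(cand.occurrence_scores))
    return float(sum(cand.occurrence_scores))


def rank_candidates(
    candidates: list[Candidate],
    stats: dict[str, PhysicianStats],
    k: int,
    rate_exponent: float = 1.0,
    aggregation: str = "n_max",
    use_response_rate: bool = True,
    query_id: str = "",
    mode: str = "PPHR",
) -> Recommendation:
    """Step 3: response-rate-weighted ranking of the candidate pool.

    A candidate without stats is treated as response_rate 0 (and logged):
    a physician the corpus has never seen answer cannot be promoted.  Ties
    break by descending physician_score, then ascending code.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if aggregation not in {"n_max", "sum"}:
        raise ValueError(f"unknown aggregation: {aggregation!r}")
    scored = []
    for cand in candidates:
        agg = _occurrence_sum(cand, aggregation)
        if use_response_rate:
            st = stats.get(cand.physician_code)
            if st is None:
                logger.warning(
                    "no stats for physician %s; response_rate treated as 0",
                    cand.physician_code,
                )
                rate = 0.0
            else:
                rate = st.response_rate
            score = (rate ** rate_exponent) * agg if rate > 0 else 0.0
        else:
            score = agg
        scored.append((score, cand))
    scored.sort(key=lambda sc: (-sc[0], -sc[1].physician_score, sc[1].physician_code))
    ranked = tuple(
        RankedItem(
            physician_code=c.physician_code,
            score=float(s),
            physician_score=c.physician_score,
            origin=c.origin,
        )
        for s, c in scored[:k]
    )
    return Recommendation(
        query_id=query_id, ranked=ranked, k=len(ranked), mode=mode,
        pool=tuple(candidates),
    )


class Engine:
    """Built recommender state: question index, profiles, stats, config.

    Construct with :meth:`build`, query with :meth:`recommend`, persist with
    :meth:`save` / :meth:`load`.
    """

    def __init__(
        self,
        question_index: EmbeddingMatrix,
        question_to_physician: dict[str, str],
        similarity: PhysicianSimilarity,
        stats: dict[str, PhysicianStats],
        backend,
        config: dict,
    ):
        self.question_index = question_index
        self.question_to_physician = question_to_physician
        self.similarity = similarity
        self.stats = stats
        self.backend = backend
        self.config = config

    @classmethod
    def build(cls, records, backend, config: dict | None = None) -> "Engine":
        """Assemble the full engine from a training corpus.

        Runs preprocessing, question embedding, winsorized response stats,
        physician keyword profiling and profile similarity in one pass.
        """
        from .preprocess import load_stopwords, preprocess_records
        from .profiles import aggregate_by_physician, build_profiles, tfidf_top_keywords
        from .response import compute_physician_stats, fit_winsor_bounds

        cfg = dict(DEFAULT_CONFIG)
        if config:
            cfg.update(config)
        stoplist = (
            load_stopwords(cfg["stopwords_path"]) if cfg.get("stopwords_path") else None
        )
        tokenized = preprocess_records(
            records,
            mode=cfg["tokenizer_mode"],
            ngram=cfg["tokenizer_ngram"],
            stoplist=stoplist,
        )
        texts = [" ".join(tq.tokens) for tq in tokenized]
        ids = [tq.question_id for tq in tokenized]
        from .embed import embed_texts

        index = embed_texts(texts, backend, ids=ids)
        q2p = {r.question_id: r.physician_code for r in records}

        times = [
            r.response_time_min
            for r in records
            if r.response_status and r.response_time_min is not None
        ]
        bounds = fit_winsor_bounds(times) if times else None
        stats = compute_physician_stats(records, bounds)

        docs = aggregate_by_physician(tokenized, records)
        keywords = tfidf_top_keywords(
            docs,
            top_n=cfg["profile_top_n"],
            tf_mode=cfg["tfidf_tf_mode"],
            idf_mode=cfg["tfidf_idf_mode"],
        )
        _, similarity = build_profiles(keywords, backend)
        eng = cls(index, q2p, similarity, stats, backend, cfg)
        eng._stoplist = stoplist
        eng.winsor_bounds = bounds
        return eng

    def _query_vector(self, query_text: str):
        from .preprocess import preprocess_text

        tokens = preprocess_text(
            query_text,
            mode=self.config["tokenizer_mode"],
            ngram=self.config["tokenizer_ngram"],
            stoplist=getattr(self, "_stoplist", None),
        )
        return self.backend.encode([" ".join(tokens)])[0]

    def recommend(
        self,
        query_text: str,
        k: int | None = None,
        mode: str = "PPHR",
        query_id: str = "",
    ) -> Recommendation:
        """Rank the top-k physicians for a new free-text question."""
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        cfg = self.config
        k = cfg["k"] if k is None else k
        qvec = self._query_vector(query_text)
        top_k = max(k, cfg["k"])
        direct = generate_candidates(
            qvec,
            self.question_index,
            self.question_to_physician,
            # the similar-question pool must cover at least top_k physicians
            top_m_questions=max(cfg["top_m"], top_k),
            top_k_physicians=top_k,
        )
        if mode == "PFB":
            return self._rank_pfb(direct, k, query_id)
        pool = expand_candidates(direct, self.similarity, cfg["threshold"])
        return rank_candidates(
            pool,
            self.stats,
            k=k,
            rate_exponent=cfg["rate_exponent"],
            aggregation=cfg["aggregation"],
            use_response_rate=(mode == "PPHR"),
            query_id=query_id,
            mode=mode,
        )

    def _rank_pfb(self, direct: list[Candidate], k: int, query_id: str) -> Recommendation:
        ordered = sorted(direct, key=lambda c: (-c.init_score, c.physician_code))
        ranked = tuple(
            RankedItem(
                physician_code=c.physician_code,
                score=c.init_score,
                physician_score=c.physician_score,
                origin=c.origin,
            )
            for c in ordered[:k]
        )
        return Recommendation(
            query_id=query_id, ranked=ranked, k=len(ranked), mode="PFB",
            pool=tuple(direct),
        )

    # --- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist engine state: NPY vectors + JSON/CSV sidecars + config."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "question_vectors.npy", self.question_index.vectors)
        (d / "question_index.json").write_text(
            json.dumps(
                {
                    "ids": self.question_index.ids,
                    "dim": self.question_index.dim,
                    "backend_tag": self.question_index.backend_tag,
                },
                ensure_ascii=False,
            ),
            encoding="utf-8",
        )
        (d / "question_to_physician.json").write_text(
            json.dumps(self.question_to_physician, ensure_ascii=False),
            encoding="utf-8",
        )
        np.save(d / "similarity.npy", self.similarity.matrix)
        (d / "similarity_codes.json").write_text(
            json.dumps(self.similarity.codes, ensure_ascii=False), encoding="utf-8"
        )
        import pandas as pd

        rows = [
            {
                "physician_code": s.physician_code,
                "n_total": s.n_total,
                "n_responded": s.n_responded,
                "response_rate": s.response_rate,
                "total_response_time_min": s.total_response_time_min,
                "mean_response_time_min": s.mean_response_time_min,
            }
            for s in self.stats.values()
        ]
        # CSV is the human-readable export; JSON round-trips floats exactly
        pd.DataFrame(rows).to_csv(d / "stats.csv", index=False)
        (d / "stats.json").write_text(
            json.dumps(rows, ensure_ascii=False), encoding="utf-8"
        )
        (d / "config.json").write_text(
            json.dumps(self.config, ensure_ascii=False, indent=2), encoding="utf-8"
        )

    @classmethod
    def load(cls, directory: str | Path, backend) -> "Engine":
        d = Path(directory)
        if not (d / "config.json").exists():
            raise FileNotFoundError(
                f"no engine state in {d}; run the build step first"
            )
        meta = json.loads((d / "question_index.json").read_text(encoding="utf-8"))
        index = EmbeddingMatrix(
            ids=meta["ids"],
            vectors=np.load(d / "question_vectors.npy"),
            backend_tag=meta["backend_tag"],
        )
        q2p = json.loads((d / "question_to_physician.json").read_text(encoding="utf-8"))
        similarity = PhysicianSimilarity(
            codes=json.loads((d / "similarity_codes.json").read_text(encoding="utf-8")),
            matrix=np.load(d / "similarity.npy"),
        )
        stats = {}
        for row in json.loads((d / "stats.json").read_text(encoding="utf-8")):
            stats[str(row["physician_code"])] = PhysicianStats(
                physician_code=str(row["physician_code"]),
                n_total=int(row["n_total"]),
                n_responded=int(row["n_responded"]),
                response_rate=float(row["response_rate"]),
                total_response_time_min=float(row["total_response_time_min"]),
                mean_response_time_min=(
                    None
                    if row["mean_response_time_min"] is None
                    else float(row["mean_response_time_min"])
                ),
            )
        config = json.loads((d / "config.json").read_text(encoding="utf-8"))
        return cls(index, q2p, similarity, stats, backend, config)


DEFAULT_CONFIG = {
    "tokenizer_mode": "word",
    "tokenizer_ngram": 2,
    "stopwords_path": None,
    "profile_top_n": 20,
    "tfidf_tf_mode": "relative",
    "tfidf_idf_mode": "smooth",
    "top_m": DEFAULT_TOP_M,
    "threshold": DEFAULT_THRESHOLD,
    "k": DEFAULT_K,
    "rate_exponent": 1.0,
    "aggregation": "n_max",
}
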
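"""Evaluation suite for top-k physician recommendation.

Two complementary test protocols:

* **Labelled queries** (test set 1): each query carries the code of a
  physician who vetted it as within their expertise.  A recommendation is a
  hit when that physician appears in the top-k list; the hit ratio is the
  fraction of hits, and the mean ranking averages the 1-based position of
  the true physician over the hit queries only (the rank of a miss is
  undefined).

* **Unlabelled queries** (test set 2): a recommended physician counts as
  relevant when their physician_score exceeds 0.7.  Per query, recommended
  relevant physicians are TP, recommended non-relevant are FP, and relevant
  physicians left out of the top-k (drawn from the full scored candidate
  pool) are FN.  Precision, recall and F1 are micro-averaged over queries:

      precision = TP / (TP + FP)      recall = TP / (TP + FN)
      F1 = 2 P R / (P + R)

The high-quality-service proportion (hqos_prop) is the fraction of
recommended slots whose physician's winsorized mean response time beats the
corpus-level mean response time — N_f fast physicians out of N recommended.

A K-sweep computes the full metric grid for K = 2, 4, ..., 20 across the
PFB / PPH / PPHR ablations from one shared retrieval pool, so the curves
are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .recommend import Recommendation
from .response import PhysicianStats

__all__ = [
    "EvalReport",
    "hit_ratio_and_rank",
    "precision_recall_f1",
    "f1_score",
    "hqos_prop",
    "k_sweep",
    "aggregate_stats",
    "relative_improvement",
    "compare_ratings",
]

logger = logging.getLogger(__name__)

DEFAULT_K_VALUES = tuple(range(2, 21, 2))
RELEVANCE_THRESHOLD = 0.7


@dataclass
class EvalReport:
    """Metric grid over (mode, K) plus per-physician hit/rank statistics."""

    per_k: pd.DataFrame  # columns: mode, k, precision, recall, f1, hqos_prop, hit_ratio
    per_physician: dict[str, dict[str, tuple[float, float | None]]] = field(
        default_factory=dict
    )  # mode -> code -> (hit_ratio, mean_rank)
    footer: str = (
        "Rounding: metrics carried at full precision; tables render 2-4 "
        "decimals. F1 is the harmonic mean of the unrounded precision and "
        "recall, so an F1 recomputed from the rounded pair may differ in "
        "the last printed digit."
    )

    def to_csv(self, path) -> None:
        self.per_k.to_csv(path, index=False, float_format="%.6f")


def hit_ratio_and_rank(
    recs: dict[str, Recommendation], truth: dict[str, str]
) -> dict[str, tuple[float, float | None]]:
    """Per-physician hit ratio and mean 1-based rank over hit queries.

    ``truth`` maps query_id to the vetted physician's code.  Queries are
    grouped by that physician; a physician with zero hits gets mean rank
    None.
    """
    missing = set(recs) - set(truth)
    if missing:
        raise ValueError(f"queries without truth labels: {sorted(missing)[:5]}")
    per: dict[str, dict[str, list]] = {}
    for qid, rec in recs.items():
        code = truth[qid]
        slot = per.setdefault(code, {"queries": [], "ranks": []})
        slot["queries"].append(qid)
        codes = rec.codes()
        if code in codes:
            slot["ranks"].append(codes.index(code) + 1)
    out = {}
    for code, slot in per.items():
        n_q = len(slot["queries"])
        hits = len(slot["ranks"])
        out[code] = (
            hits / n_q,
            (sum(slot["ranks"]) / hits) if hits else None,
        )
    return out


def precision_recall_f1(
    recs: dict[str, Recommendation],
    relevance_threshold: float = RELEVANCE_THRESHOLD,
) -> tuple[float, float, float]:
    """Micro-averaged precision / recall / F1 under the score-threshold rule.

    Relevant physicians for a query are those whose physician_score in the
    full candidate pool exceeds the threshold; the recommended list is the
    (truncated) top-k.  Zero denominators yield 0 with a warning.
    """
    tp = fp = fn = 0
    for rec in recs.values():
        relevant = {
            c.physician_code
            for c in rec.pool
            if c.physician_score > relevance_threshold
        }
        recommended = set(rec.codes())
        tp += len(recommended & relevant)
        fp += len(recommended - relevant)
        fn += len(relevant - recommended)
    if tp + fp == 0 or tp + fn == 0:
        logger.warning("degenerate precision/recall denominator; reporting 0")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall, f1_score(precision, recall)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR / (P + R); 0 when both inputs are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def hqos_prop(
    recs: dict[str, Recommendation],
    stats: dict[str, PhysicianStats],
    global_mean_rt_min: float,
) -> float:
    """Fraction of recommended slots held by faster-than-average physicians.

    A physician is fast when their mean response time is strictly below the
    corpus mean; a physician with no responded requests is not fast.
    """
    if global_mean_rt_min <= 0:
        raise ValueError("global mean response time must be positive")
    n_fast = 0
    n_slots = 0
    for rec in recs.values():
        for item in rec.ranked:
            n_slots += 1
            st = stats.get(item.physician_code)
            if (
                st is not None
                and st.mean_response_time_min is not None
                and st.mean_response_time_min < global_mean_rt_min
            ):
                n_fast += 1
    if n_slots == 0:
        raise ValueError("no recommended physicians (N = 0)")
    return n_fast / n_slots


def k_sweep(
    engine,
    test1: list[tuple[str, str]] | None,
    test1_truth: dict[str, str] | None,
    test2: list[tuple[str, str]] | None,
    global_mean_rt_min: float,
    k_values=DEFAULT_K_VALUES,
    modes=("PFB", "PPH", "PPHR"),
    relevance_threshold: float = RELEVANCE_THRESHOLD,
) -> EvalReport:
    """Full metric grid over modes and K.

    ``test1``/``test2`` are lists of (query_id, query_text); test1 queries
    need truth labels.  For each mode the engine is queried once at
    max(k_values) and the ranking truncated per K, so every cell of the
    grid shares one retrieval pool (the fixed-pool convention).
    """
    k_values = sorted(k_values)
    k_max = k_values[-1]
    rows = []
    per_physician: dict[str, dict] = {}
    for mode in modes:
        recs1_full = (
            {
                qid: engine.recommend(text, k=k_max, mode=mode, query_id=qid)
                for qid, text in test1
            }
            if test1
            else {}
        )
        recs2_full = (
            {
                qid: engine.recommend(text, k=k_max, mode=mode, query_id=qid)
                for qid, text in test2
            }
            if test2
            else {}
        )
        if recs1_full and test1_truth:
            per_physician[mode] = hit_ratio_and_rank(recs1_full, test1_truth)
        for k in k_values:
            row = {"mode": mode, "k": k}
            if recs2_full:
                recs2 = {q: r.truncated(k) for q, r in recs2_full.items()}
                p, r, f1 = precision_recall_f1(recs2, relevance_threshold)
                row.update(
                    precision=p,
                    recall=r,
                    f1=f1,
                    hqos_prop=hqos_prop(recs2, engine.stats, global_mean_rt_min),
                )
            if recs1_full and test1_truth:
                recs1 = {q: r.truncated(k) for q, r in recs1_full.items()}
                hits = sum(
                    1
                    for qid, rec in recs1.items()
                    if test1_truth[qid] in rec.codes()
                )
                row["hit_ratio"] = hits / len(recs1)
            rows.append(row)
    columns = ["mode", "k", "precision", "recall", "f1", "hqos_prop", "hit_ratio"]
    frame = pd.DataFrame(rows)
    frame = frame.reindex(columns=[c for c in columns if c in frame.columns])
    return EvalReport(per_k=frame, per_physician=per_physician)


def aggregate_stats(values) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation.

    With a single value the SD is reported as 0.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd


def relative_improvement(a: float, b: float) -> float:
    """Percentage change of ``a`` over baseline ``b``: 100 (a - b) / b."""
    if b == 0:
        raise ValueError("baseline must be nonzero")
    return 100.0 * (a - b) / b


def compare_ratings(ratings_a, ratings_b, alternative: str = "two-sided"):
    """Mann-Whitney U rank-sum comparison of two rating samples.

    Returns (U statistic, p-value); exact distribution for small samples
    without ties, normal approximation otherwise (scipy's ``auto``).
    """
    a = np.asarray(list(ratings_a), dtype=float)
    b = np.asarray(list(ratings_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both rating samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)
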
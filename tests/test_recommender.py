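import math

import numpy as np
import pytest

from pphr import (
    Candidate,
    EmbeddingMatrix,
    PhysicianSimilarity,
    candidates_from_matches,
    expand_candidates,
    generate_candidates,
    rank_candidates,
)
from pphr.response import PhysicianStats


def stats_for(code, rate, mean_rt=60.0, n_total=100):
    n_resp = round(rate * n_total)
    return PhysicianStats(
        physician_code=code, n_total=n_total, n_responded=n_resp,
        response_rate=n_resp / n_total,
        total_response_time_min=(mean_rt or 0.0) * n_resp,
        mean_response_time_min=mean_rt,
    )


# the worked retrieval example: ten similar questions, one physician each
TOP10_MATCHES = [
    ("394946", 0.9766, "178"),
    ("559249", 0.9765, "423"),
    ("317643", 0.9618, "141"),
    ("409326", 0.9419, "164"),
    ("238700", 0.9214, "456"),
    ("2416", 0.9004, "707"),
    ("173519", 0.8990, "304"),
    ("551580", 0.8976, "330"),
    ("466072", 0.8906, "632"),
    ("93556", 0.8861, "391"),
]


class TestCandidateGeneration:
    def test_worked_retrieval_example(self):
        matches = [(q, s) for q, s, _ in TOP10_MATCHES]
        q2p = {q: p for q, _, p in TOP10_MATCHES}
        cands = {c.physician_code: c for c in
                 candidates_from_matches(matches, q2p, top_k_physicians=10)}
        assert len(cands) == 10
        assert cands["141"].init_score == pytest.approx(0.9618)
        assert cands["423"].init_score == pytest.approx(0.9765)
        assert all(c.n == 1 and c.expand_score == 1.0 for c in cands.values())

    def test_multiple_matches_take_max_and_count(self):
        matches = [("q1", 0.9), ("q2", 0.8), ("q3", 0.75)]
        q2p = {"q1": "A", "q2": "A", "q3": "A"}
        (cand,) = candidates_from_matches(matches, q2p, top_k_physicians=5)
        assert cand.n == 3
        assert cand.init_score == 0.9
        assert cand.physician_score == 0.9  # direct: expand_score is 1

    def test_single_indexed_question(self):
        index = EmbeddingMatrix(ids=["q1"], vectors=np.array([[1.0, 0.0]]),
                                backend_tag="t")
        (cand,) = generate_candidates(np.array([1.0, 0.0]), index, {"q1": "A"},
                                      top_m_questions=1, top_k_physicians=1)
        assert cand.physician_code == "A" and cand.n == 1
        assert cand.init_score == pytest.approx(1.0)

    def test_keeps_top_k_physicians_by_init_score(self):
        matches = [("q1", 0.9), ("q2", 0.8), ("q3", 0.7)]
        q2p = {"q1": "A", "q2": "B", "q3": "C"}
        cands = candidates_from_matches(matches, q2p, top_k_physicians=2)
        assert [c.physician_code for c in cands] == ["A", "B"]

    def test_empty_index_errors(self):
        index = EmbeddingMatrix(ids=["q1"], vectors=np.array([[1.0]]),
                                backend_tag="t")
        with pytest.raises(ValueError, match="top_m_questions"):
            generate_candidates(np.array([1.0]), index, {}, 1, 2)


def sim_matrix(codes, pairs):
    """Dense symmetric similarity with unit diagonal from sparse pairs."""
    n = len(codes)
    m = np.zeros((n, n))
    np.fill_diagonal(m, 1.0)
    idx = {c: i for i, c in enumerate(codes)}
    for (a, b), s in pairs.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = s
    return PhysicianSimilarity(codes=list(codes), matrix=m)


def direct(code, init, n=1):
    return Candidate(physician_code=code, init_score=init, expand_score=1.0,
                     physician_score=init, n=n, origin="direct",
                     occurrence_scores=(init,) * n)


class TestExpansion:
    def test_product_structure_of_expanded_score(self):
        sim = sim_matrix(["141", "166"], {("141", "166"): 0.9335})
        out = expand_candidates([direct("141", 0.9618)], sim)
        exp = {c.physician_code: c for c in out if c.origin == "expanded"}
        assert exp["166"].physician_score == pytest.approx(0.9618 * 0.9335)
        assert round(exp["166"].physician_score, 4) == 0.8978
        assert exp["166"].seed_code == "141"

    def test_gate_blocks_products_at_or_below_threshold(self):
        sim = sim_matrix(["A", "B"], {("A", "B"): 0.7})
        out = expand_candidates([direct("A", 0.9)], sim)  # 0.63 <= 0.7
        assert all(c.origin == "direct" for c in out)

    def test_unit_similarity_propagates_init_score_exactly(self):
        sim = sim_matrix(["A", "B"], {("A", "B"): 1.0})
        out = expand_candidates([direct("A", 0.85)], sim)
        exp = next(c for c in out if c.physician_code == "B")
        assert exp.physician_score == 0.85

    def test_direct_candidates_pass_through_unchanged(self):
        sim = sim_matrix(["A", "B", "C"], {("A", "B"): 0.95, ("A", "C"): 0.9})
        seeds = [direct("A", 0.96), direct("B", 0.8)]
        out = expand_candidates(seeds, sim)
        assert out[:2] == seeds

    def test_multiple_seeds_keep_best_and_all_occurrences(self):
        sim = sim_matrix(["A", "B", "C"], {("A", "C"): 0.9, ("B", "C"): 0.95})
        out = expand_candidates([direct("A", 0.96), direct("B", 0.9)], sim)
        exp = next(c for c in out if c.physician_code == "C")
        # best seed is A (0.96*0.9 = 0.864 > 0.9*0.95 = 0.855)
        assert exp.physician_score == pytest.approx(0.864)
        assert sorted(exp.occurrence_scores) == pytest.approx([0.855, 0.864])

    def test_missing_physician_skipped_with_warning(self, caplog):
        sim = sim_matrix(["B", "C"], {("B", "C"): 0.99})
        out = expand_candidates([direct("A", 0.99)], sim)
        assert out == [direct("A", 0.99)]
        assert any("similarity matrix" in r.message for r in caplog.records)

    def test_bad_threshold_rejected(self):
        sim = sim_matrix(["A"], {})
        with pytest.raises(ValueError, match="threshold"):
            expand_candidates([direct("A", 0.9)], sim, threshold=0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        # enumerate every (seed, neighbour) product by hand and apply the
        # gate; the implementation must agree bit-for-bit
        rng = np.random.default_rng(seed)
        codes = [f"P{i}" for i in range(8)]
        m = rng.uniform(0, 1, size=(8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        sim = PhysicianSimilarity(codes=codes, matrix=m)
        directs = [direct(c, float(rng.uniform(0.5, 1.0)))
                   for c in rng.choice(codes, size=3, replace=False)]
        out = expand_candidates(directs, sim, threshold=0.7)

        direct_codes = {c.physician_code for c in directs}
        expected = {}
        for d in directs:
            for j, other in enumerate(codes):
                if other in direct_codes or other == d.physician_code:
                    continue
                product = d.init_score * sim.sim(d.physician_code, other)
                if product > 0.7:
                    expected.setdefault(other, []).append(product)
        got = {c.physician_code: c for c in out if c.origin == "expanded"}
        assert set(got) == set(expected)
        for code, products in expected.items():
            assert got[code].physician_score == max(products)
            assert sorted(got[code].occurrence_scores) == sorted(products)
            # the defining product identity holds exactly
            assert got[code].physician_score == got[code].init_score * got[code].expand_score


class TestRanking:
    def test_zero_response_rate_scores_zero(self):
        cands = [direct("A", 0.9), direct("B", 0.5)]
        stats = {"A": stats_for("A", 0.0), "B": stats_for("B", 0.5)}
        rec = rank_candidates(cands, stats, k=2)
        assert rec.ranked[0].physician_code == "B"
        assert rec.ranked[1].score == 0.0

    def test_monotone_in_response_rate(self):
        cands = [direct("A", 0.8), direct("B", 0.8)]
        stats = {"A": stats_for("A", 0.9), "B": stats_for("B", 0.3)}
        rec = rank_candidates(cands, stats, k=2)
        assert rec.codes() == ["A", "B"]

    def test_hand_arithmetic_default_rule(self):
        # 10 equal matches at 0.9618 and rate 0.747: R * n * max
        cand = direct("A", 0.9618, n=10)
        stats = {"A": stats_for("A", 0.747, n_total=1000)}
        rec = rank_candidates([cand], stats, k=1)
        assert rec.ranked[0].score == pytest.approx(0.747 * 10 * 0.9618)
        assert rec.ranked[0].score == pytest.approx(7.185, abs=5e-4)

    def test_missing_stats_treated_as_zero_rate(self, caplog):
        rec = rank_candidates([direct("A", 0.9)], {}, k=1)
        assert rec.ranked[0].score == 0.0
        assert any("no stats" in r.message for r in caplog.records)

    def test_scores_non_increasing_and_codes_unique(self):
        cands = [direct(f"P{i}", 0.5 + 0.05 * i) for i in range(8)]
        stats = {c.physician_code: stats_for(c.physician_code, 0.5) for c in cands}
        rec = rank_candidates(cands, stats, k=8)
        scores = [i.score for i in rec.ranked]
        assert scores == sorted(scores, reverse=True)
        assert len(set(rec.codes())) == len(rec.ranked)

    def test_ranking_invariant_under_monotone_transform(self):
        cands = [direct(f"P{i}", 0.6 + 0.04 * i) for i in range(6)]
        stats = {c.physician_code: stats_for(c.physician_code, 0.2 + 0.1 * i)
                 for i, c in enumerate(cands)}
        rec = rank_candidates(cands, stats, k=6)
        order = rec.codes()
        transformed = sorted(rec.ranked, key=lambda it: -math.exp(it.score))
        assert [i.physician_code for i in transformed] == order

    def test_k_below_one_errors(self):
        with pytest.raises(ValueError, match="k"):
            rank_candidates([direct("A", 0.9)], {}, k=0)


class TestEngineModes:
    def test_eq5_exactness_across_engine_pool(self, expansion_engine, expansion_corpus):
        records, _ = expansion_corpus
        rec = expansion_engine.recommend(records[0].question_text, k=6, mode="PPHR")
        assert any(c.origin == "expanded" for c in rec.pool)
        for c in rec.pool:
            assert c.physician_score == c.init_score * c.expand_score

    def test_flat_rates_and_identity_similarity_neutralize_steps_2_and_3(
        self, small_engine, small_corpus
    ):
        # with every response rate equal, the rate factor is a constant
        # monotone transform, so the full model ranks exactly like the
        # rate-free ablation; with an identity similarity matrix no
        # expansion fires, so the candidate pool is the direct (PFB) one
        import copy

        records, _ = small_corpus
        eng = copy.copy(small_engine)
        eng.stats = {c: stats_for(c, 0.8) for c in small_engine.stats}
        n = len(eng.similarity.codes)
        eng.similarity = PhysicianSimilarity(codes=list(eng.similarity.codes),
                                             matrix=np.eye(n))
        for r in records[:10]:
            pfb = eng.recommend(r.question_text, k=5, mode="PFB")
            pph = eng.recommend(r.question_text, k=5, mode="PPH")
            pphr = eng.recommend(r.question_text, k=5, mode="PPHR")
            assert pphr.codes() == pph.codes()
            assert {c.physician_code for c in pphr.pool} == \
                {c.physician_code for c in pfb.pool}

    def test_expansion_never_removes_direct_candidates(self, expansion_engine,
                                                       expansion_corpus):
        records, _ = expansion_corpus
        for r in records[:10]:
            pfb = expansion_engine.recommend(r.question_text, k=6, mode="PFB")
            pph = expansion_engine.recommend(r.question_text, k=6, mode="PPH")
            pool_codes = {c.physician_code for c in pph.pool}
            assert {c.physician_code for c in pfb.pool} <= pool_codes

    def test_specialist_recovered_at_zero_noise(self, small_engine, small_corpus):
        records, truth = small_corpus
        hits = 0
        for r in records[:50]:
            rec = small_engine.recommend(r.question_text, k=5, mode="PPHR")
            topic = truth.question_topic[r.question_id]
            specialists = {c for c, t in truth.physician_topics.items() if topic in t}
            hits += bool(set(rec.codes()) & specialists)
        assert hits / 50 > 0.9

    def test_deterministic_for_fixed_corpus_and_config(self, small_corpus, backend):
        from pphr import Engine

        records, _ = small_corpus
        a = Engine.build(records, backend)
        b = Engine.build(records, backend)
        q = records[3].question_text
        assert a.recommend(q, k=8) == b.recommend(q, k=8)

    def test_unknown_mode_rejected(self, small_engine):
        with pytest.raises(ValueError, match="mode"):
            small_engine.recommend("fever", mode="HYBRID")

    def test_save_load_round_trip(self, small_engine, small_corpus, backend, tmp_path):
        from pphr import Engine

        records, _ = small_corpus
        small_engine.save(tmp_path / "state")
        loaded = Engine.load(tmp_path / "state", backend)
        q = records[5].question_text
        assert loaded.recommend(q, k=6) == small_engine.recommend(q, k=6)
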
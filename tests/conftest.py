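import pytest

from pphr import ConsultationRecord, Engine, HashNgramBackend, SyntheticConfig, generate


def make_record(qid, phys="D1", text="glucose tolerance test", responded=True,
                rt=20.0, **kw):
    return ConsultationRecord(
        question_id=qid,
        patient_code=kw.pop("patient_code", "U1"),
        physician_code=phys,
        question_text=text,
        response_status=responded,
        response_time_min=rt if responded else None,
        **kw,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """3 topics, 12 single/dual-topic physicians, 800 clean questions."""
    cfg = SyntheticConfig(n_topics=3, n_physicians=12, n_questions=800,
                          noise_rate=0.0, seed=7)
    return generate(cfg)


@pytest.fixture(scope="session")
def backend():
    return HashNgramBackend(dim=512, ngram=3, seed=0)


@pytest.fixture(scope="session")
def small_engine(small_corpus, backend):
    records, _ = small_corpus
    return Engine.build(records, backend)


@pytest.fixture(scope="session")
def expansion_corpus():
    """Many single-topic physicians with near-identical profiles, so the
    candidate-expansion gate actually fires at the 0.7 threshold."""
    cfg = SyntheticConfig(
        n_topics=4, vocab_per_topic=10, n_physicians=32,
        topics_per_physician=(1, 1), n_questions=1600, noise_rate=0.0,
        word_len=(9, 12), seed=7,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def expansion_engine(expansion_corpus):
    records, _ = expansion_corpus
    backend = HashNgramBackend(dim=1024, ngram=3, seed=0)
    return Engine.build(records, backend, {"top_m": 12, "k": 6})
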
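# Methods

## Problem and model

The package targets expert routing on web-based medical consultation
platforms: given a free-text patient question and a history of
(question, physician, response) records, return the K physicians most
suited to answer.  The model combines three signals:

* **Question similarity.**  Texts are normalized (NFKC, case-fold,
  whitespace collapse), tokenized (pluggable segmenter or character
  n-grams), stop-word filtered, and embedded to unit-norm vectors; cosine
  similarity `u·v / (‖u‖‖v‖)` drives retrieval.  A physician's `init_score`
  for a query is the maximum similarity over their matched historical
  questions, with `n` the number of matches.
* **Physician profiles.**  Each physician's pseudo-document (all tokens of
  questions addressed to them) is scored by TF-IDF; the top 20 terms,
  joined in descending-weight order, are embedded with the same encoder,
  and pairwise profile cosines form the physician-physician similarity.
  Expansion proposes colleague *j* of direct candidate *i* at
  `physician_score = init_score_i × sim(i, j)` and retains the proposal iff
  the product exceeds the 0.7 threshold.  Expansion is single-hop; when
  several seeds retain the same colleague, the reported triple comes from
  the best seed and every retaining seed contributes one occurrence term.
* **Response behaviour.**  Response rate `R = N_R / N` per physician;
  response times winsorized to the corpus 5th/95th percentile bounds
  (linear-interpolation quantiles) before any averaging.  The corpus-level
  mean response time — the mean of winsorized per-request times over all
  answered requests, not a mean of per-physician means — separates fast
  from slow physicians in the service-quality metric.

### Final ranking rule

The published form of the final scoring equation is not recoverable from
its source (rendered only as a figure); what is fixed is that it combines
the similarity score, the occurrence count `n`, and the response rate.
This package therefore documents its reconstruction explicitly:

    score_i = R_i ** rate_exponent × Σ (occurrence scores of i)

with two switchable aggregations — `n_max` (default: a direct candidate
contributes `n × physician_score`) and `sum` (the raw per-question
similarities are summed) — and `rate_exponent` defaulting to 1.  The
default reproduces the magnitude structure of the worked example the
method publishes (final scores of 2.5–7.2 for physician_scores of
0.73–0.98).  Every persisted engine state and report records the variant
used.  Because the rule is a reconstruction, conclusions that depend on
the *exact* interleaving of candidates with very different `n` should be
checked under both aggregations.

Ties everywhere break deterministically: descending score, then descending
physician_score, then ascending physician code; retrieval ties break by
ascending question id.

## Ablations

`PFB` ranks direct candidates by `init_score` alone; `PPH` adds expansion
and ranks by the occurrence sum without the rate factor; `PPHR` is the full
model.  All three share the same retrieval pool per query, so each ablation
isolates exactly one mechanism.  Under equal response rates the PPHR order
equals the PPH order exactly (the rate is a constant monotone factor); PFB
differs from both whenever occurrence counts vary, since it ignores `n`.

## Embedding backends

The default backend hashes overlapping character n-grams (default n = 3)
into `dim` buckets (default 512) with a keyed BLAKE2b hash and
L2-normalizes the counts.  It is fully deterministic, platform-stable, and
needs no model artifacts, which makes every pipeline stage testable
offline; it captures lexical overlap, not meaning, so paraphrases with
disjoint vocabulary score near zero — a deliberate trade-off for a test
and reference backend.  Adapters for pretrained sentence encoders
(`sentence-transformers`, default model
`distiluse-base-multilingual-cased`) and corpus-trained Doc2Vec (`gensim`,
dim 128 / window 5 / 40 epochs / fixed seed, single worker) raise an
explicit `BackendUnavailableError` when their optional dependency or model
is absent — never a silent fallback.  Retrieval scores queries against the
stored index on demand rather than materializing the N×N question
similarity matrix; the results are identical to the exhaustive sort.

## TF-IDF variants

TF is relative frequency (`count/|d|`) by default, switchable to raw
counts; IDF is the smoothed `ln((1+N)/(1+df)) + 1` by default, switchable
to plain `ln(N/df)`.  The TF normalization constant cannot change
within-document keyword ranking, so extracted keyword sets agree with a
raw-count vectorizer under the same IDF (asserted against scikit-learn in
the tests).  Keyword weights are used only to rank and order terms; they do
not scale the profile embedding.

## Synthetic corpus generator

Real consultation corpora are private, so the generator emulates the
structural properties the method relies on, with defaults chosen once as a
plausible mid-sized platform:

| parameter | default | meaning |
| --- | --- | --- |
| n_topics / vocab_per_topic | 8 / 40 | disjoint keyword vocabularies per medical topic |
| n_physicians, topics_per_physician | 40, 1–2 | specialists with narrow scopes |
| n_questions, tokens_per_question | 4000, 6–15 | bag-of-keywords questions |
| noise_rate | 0.10 | off-topic token fraction |
| response_rate_range | (0.30, 0.95) | per-physician Bernoulli response rates |
| response_time_lognormal | μ=4.5, σ=1.3 (log-minutes) | median ≈ 90 min, mean ≈ 3.5 h, right-skewed |
| time_rate_slope | 2.0 | log-mean shift tying high rates to fast replies |

Questions are bags of topic keywords, not grammatical sentences: the
pipeline consumes token statistics and embeddings only, so fluency is
irrelevant to the contracts under test.  Words are random letter strings
(5–8 characters) so hashed n-gram embeddings separate topics.  The
negative rate-time coupling mirrors the empirical correlation between
responsiveness and speed on real platforms and is what makes rate
weighting improve the service-quality metric.  What passing tests on this
generator do **not** show: robustness to paraphrase (the default backend
is lexical), to the colloquial noise of real patient text, or to the scale
(hundreds of thousands of records) of production corpora.

## Numerical and design choices

* Quantiles: numpy linear interpolation, documented so winsor bounds are
  reproducible from the stated fractions.
* The expansion threshold applies to the *product* `physician_score`, not
  to the profile similarity alone.
* A candidate without response statistics is ranked with rate 0 (logged):
  an unobserved physician is never promoted by the rate factor.
* Mean ranking averages over hit queries only; the rank of a miss is
  undefined.
* Recall's relevant set for a query is every scored candidate (before
  top-K truncation) with `physician_score > 0.7`; metrics are
  micro-averaged over queries, and the K-sweep truncates one fixed pool
  per mode so curves are comparable.
* Physicians whose corpus is entirely stop-worded get no profile and can
  never be expansion targets (logged); questions that become empty after
  filtering fall back to their normalized raw text so they stay
  embeddable.
* Engine state persists response stats as JSON (floats round-trip
  bit-exactly) alongside a human-readable CSV; reports are deterministic
  to the byte for a fixed corpus, config and seed.
* Test-set construction takes the vetted query→physician label map as an
  input; the vetting itself is a human procedure outside the package.
* Rating comparison uses the Mann-Whitney U rank-sum test
  (scipy, exact for small tie-free samples); rating collection is out of
  scope.

## Problem sizes used in tests and the acceptance script

Engine-level checks run on corpora of 600–1600 questions with 12–32
physicians and 256–1024-dimension hashed embeddings; parameter recovery
uses a 10,000-question corpus; the service-quality dominance property
averages 20 seeded corpora.  These sizes give stable statistics for every
asserted property while keeping the whole suite fast.

## Known limitations

The default backend is lexical, so semantic paraphrase retrieval requires
the transformer adapter and a local model.  The final ranking rule is a
documented reconstruction (above).  Expansion does not chain beyond one
hop.  No department-level routing, personalization, online learning, or
multimodal input.
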
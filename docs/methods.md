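# Methods

This note records the models implemented, the defaults chosen where the
deployed system's parameters are unrecoverable, what the synthetic
generators do and do not emulate, and the numerical conventions.

## Document embeddings

A document is tokenized to lowercased Unicode word tokens; punctuation,
underscores and hyphens split tokens (so "COVID-19" yields `covid`, `19`).
One tokenization rule is used everywhere — matching, summarization, FAQ
indexing and query processing — so embeddings of identical text are
bit-identical.

The embedding of a text with in-vocabulary tokens t₁…t_m is the mean of
`a/(a + p(t)) · v_t`, with `a = 10⁻³` (the conventional SIF smoothing value;
weights are insensitive to the exact choice over 10⁻⁴–10⁻²). Out-of-
vocabulary policy: a token missing from the frequency table gets p = 0 and
hence the maximal weight 1 (rare domain terms are never down-weighted); a
token missing from the vector table is skipped. A text with no embeddable
token yields an all-zero vector flagged degenerate; degenerate texts score 0
at their similarity level, are excluded from component fitting and from
retrieval, and never raise.

Common-component removal subtracts the projection onto the top right
singular vector(s) of the stacked embedding matrix (default: 1 component).
Components are fitted on the batch being processed — all titles and bodies
of both corpora in `match_corpus`, all questions in `index_faq` — never on a
single text: rank-1 removal fitted on one pair would annihilate identical
documents, which must instead score 1.0. A vector that becomes numerically
zero after removal is reflagged degenerate.

## Matching and summarization

Pair score = `w_title·cos(titles) + w_body·cos(bodies)` with equal default
weights — the least-assumptive combination of the two levels, configurable.
Cosines are clipped to [−1, 1] against floating-point overshoot. The default
pre-feedback threshold is 0.5; thresholds outside [−1, 1] are accepted as
sentinels (above 1 delivers nothing, below −1 everything), which the CLI
uses for cold starts and dry runs. Output is sorted by combined score
descending with (guideline_id, article_id) as the deterministic tie-break.

Summarization is centroid-ranking extractive: sentences (split on `.`/`!`/`?`
followed by whitespace) are embedded individually and ranked by cosine to
the full-text embedding; the top-k are returned in original order, earlier
sentences winning ties. This is a deliberately simple, auditable stand-in
for heavier extractive summarizers; it is not tuned for fluency.

## Feedback threshold

The update rule re-estimates the threshold as the observed score maximizing
Youden's J = TPR − FPR, treating relevant votes as positives and predicting
"deliver" when score ≥ cut. Ties take the lowest cut, favoring recall of
information. Candidate cuts are exactly the observed scores — the optimum of
J over all reals is always attained at one. One-class degenerate inputs
resolve gracefully: all-relevant returns the minimum observed score,
all-irrelevant the maximum. A burn-in of 5 labels prevents thrashing on the
first votes; every update (including frozen ones) appends a history row
(day, threshold, n_labels). The rule is intentionally swappable — it is one
reasonable instantiation of "set the threshold from user reviews", not a
claim about the deployed system.

Trend fitting is ordinary least squares of daily vote counts against day
index (slope ± standard error, via `scipy.stats.linregress`); a
`cumulative=True` flag fits running totals instead, since either reading of
a cumulative-feedback plot is defensible. The vote ratio is the plain
relevant/irrelevant quotient and is an error, not 0 or ∞, when the
denominator is zero.

## Triage

Definitions, with `resp = cough OR sob`:

* A ⇔ fever AND resp AND travel_history_14d
* B ⇔ (fever OR cough OR sob) AND close_contact_14d
* C ⇔ fever AND resp AND hospitalization_required AND NOT alternate_diagnosis

"Any acute respiratory illness" in B is interpreted as (fever OR cough OR
sob) and isolated in a single predicate so the expansion can be changed in
one place. C follows the verbatim surveillance definition and does not
require travel/contact context. Answers are forced-choice booleans; there is
no "don't know". Cohort percentages are truncated — `floor(10⁴·count/n)/100`
— not rounded; that is the convention the published marginals follow, and
the one value in the source table inconsistent with it (hospitalization)
truncates to 7.76 here.

## Spelling correction

Symmetric delete with `max_edit_distance ∈ {1, 2}` (default 2): the index
maps every ≤2-deletion variant of every dictionary word back to its
originators; lookup generates only the variants of the query token.
Candidates are verified with the optimal-string-alignment variant of
Damerau–Levenshtein distance (adjacent transpositions cost 1), the standard
companion of symmetric delete, and ranked by (distance ↑, effective
frequency ↓, word ↑). An in-dictionary token is returned unchanged (distance
0 dominates), as is a token with no candidate. Domain boosting multiplies
the frequency of lexicon words by `domain_boost` (default 10) at ranking
time inside `correct()`; the standalone `boost_domain()` materializes a
boosted dictionary for callers who want to persist one — use one mechanism
or the other, not both. Correction is per-token; no word segmentation or
compound handling.

## FAQ retrieval

Embedding nearest-neighbor retrieval over stored questions, with the query
spell-corrected first and components fitted on the question set. This
preserves the request–response contract of the original chatbot with a
desk-scale, fully testable mechanism; it deliberately replaces the
trained-sequence-model answerer of the deployed system, whose weights are a
training contribution out of scope here. Ties in score break by corpus
order; a query that embeds to nothing returns an empty result with a reason.

## Synthetic data

`gen_word_vectors`: per topic, unit vectors `normalize(centroid + σ·N(0,I))`
around a random unit centroid (σ = 0.1), plus an isotropic "common" pool of
the same size as one topic's vocabulary. Frequencies are Zipf with exponent
1.0; the common pool occupies the top ranks, emulating stopword-like shared
vocabulary and giving SIF down-weighting real work. `gen_corpus` draws
bag-of-words titles (6 tokens) and bodies (40 tokens), each token coming
from the common pool with probability `shared_vocab_fraction` (default 0.2)
and otherwise from the document's topic; topics are assigned round-robin.
Defaults (3 topics, 50 words/topic, dimension 25) are sized so that topical
structure is clear but not degenerate.

`gen_feedback` votes Bernoulli with P(relevant) a logistic function of the
pair's combined score (midpoint 0.5, steepness 8, clamped to [0.05, 0.95]
so votes stay noisy); day indices batch presentation order. The
feedback-cycle experiment (`run_feedback_cycle`, 4 guidelines × 12 articles)
delivers everything on day 0 (cold start), collects one vote per pair,
updates the threshold once, and compares the same-topic precision of
delivered pairs before and after.

`gen_respondents` draws the seven answers independently with the observed
marginal prevalences of the deployed 3567-respondent cohort as defaults.
Independence is a simplification: real symptom/exposure answers are
correlated, so joint quantities of the generator — notably its suspect
fraction — characterize the generator, not any study population.

What the generators do **not** emulate: natural language (documents are
bags of symbols, so lexical matching is easier than on real news), Hindi or
any multilingual content, adversarial misinformation, per-user heterogeneity
in voting, or correlated questionnaire answers. Passing tests therefore
demonstrate correctness of the mechanisms and their contracts, not
field performance on real news streams.

## Numerical conventions and limitations

* All randomness flows through `numpy.random.default_rng(seed)`; every
  generator is a pure function of its spec including the seed.
* SVD-based component removal uses `numpy.linalg.svd` on the stacked matrix;
  orthogonality after removal holds to ≤1e−9 and is tested at that
  tolerance.
* Problem sizes in tests and the acceptance script (corpora of 4×12
  documents, 50 replicate feedback cycles, 500-token fuzz sets, 5000-person
  synthetic cohorts) are chosen so the full suite runs in seconds while
  keeping binomial error bars well inside the asserted bounds.
* Deployment-scale observables (download counts, active users, the printed
  trend slopes of the live vote series) depend on data that only the
  deployment could produce and are intentionally not reproduced; the
  package substitutes property-level checks (e.g. precision improves under
  feedback) for them.
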
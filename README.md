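# infodemic

An offline, testable re-implementation of the computational core of a
vernacular infodemic-management suite: the kind of mobile-health backend
that, during the COVID-19 pandemic, matched daily consumer news to WHO
guidance, triaged self-reported symptoms against WHO surveillance case
definitions, and answered free-text questions from verified FAQ corpora.
It is aimed at public-health informatics researchers who want to study or
extend these mechanisms without a live deployment: every stage runs on
seeded synthetic data with known ground truth.

## What it computes

**Guideline–news matching.** A text is embedded as its smooth-inverse-
frequency (SIF) vector: for tokens *t* with word vectors *v_t* and background
relative frequency *p(t)*,

```
emb(d) = (1/m) Σ_t  a/(a + p(t)) · v_t ,      a = 10⁻³ by default,
```

followed by removal of the corpus's top singular direction (common-component
removal, fitted on the batch of documents being matched). Each
guideline–article pair gets a two-level score — cosine similarity of title
embeddings and of body embeddings, combined 50/50 — and is delivered when
the combined score clears the relevance threshold.

**Relevance feedback.** Users vote each delivered pair relevant/irrelevant.
The threshold is re-estimated as the observed score maximizing Youden's
J = TPR − FPR (relevant votes as positives), lowest cut on ties, frozen
until 5 labels exist. Engagement metrics: per-day vote counts, the
relevant/irrelevant ratio, and OLS trend slopes ± standard errors.

**Symptom triage.** The WHO Interim Guidance suspect-case definitions A/B/C
over 7 boolean answers (travel, contact, fever, cough, shortness of breath,
hospitalization, alternative diagnosis), plus cohort summaries with
percentages truncated to two decimals.

**Spell-corrected FAQ retrieval.** Queries are corrected token-by-token with
a symmetric-delete index verified by Damerau–Levenshtein distance (candidates
ranked by distance, then domain-boosted frequency, then lexicographically),
then embedded and matched to the nearest stored FAQ question by cosine.

**Synthetic generators.** Topic-clustered word vectors, corpora with
controlled topical overlap, vote streams whose P(relevant) rises with
similarity, and respondent cohorts with configurable prevalences — all pure
functions of a seed.

## Worked example

Generate a synthetic world, match news to guidelines, and inspect feedback
metrics:

```
$ infodemic simulate vectors --seed 1 --out demo
wrote 200 vectors and frequencies to demo
$ infodemic simulate corpus --seed 1 --out demo
wrote 4 guidelines, 12 articles to demo
$ infodemic match --guidelines demo/guidelines.jsonl --articles demo/articles.jsonl \
    --vectors demo/vectors.txt --freqs demo/freqs.csv --threshold 0.5 --out demo/scores.csv
wrote 48 pair scores to demo/scores.csv
$ head -4 demo/scores.csv
guideline_id,article_id,title_sim,body_sim,combined,is_relevant
g2,a5,0.9734598477725477,0.9920730162188816,0.9827664319957146,True
g1,a7,0.9630669367303378,0.9792468798934802,0.971156908311909,True
g1,a10,0.9536478945100857,0.9862379146807962,0.969942904595441,True
```

The top pairs are same-topic guideline–article matches: title and body
cosine similarities near 0.97–0.99 combine to scores above the 0.5
threshold, so these pairs would be delivered to users. A simulated feedback
cycle then adapts the threshold from its cold-start value:

```
$ infodemic simulate feedback --seed 1 --out demo
wrote 48 events to demo; threshold moved -1.000 -> 0.122
$ infodemic metrics --feedback demo/feedback.csv
day,relevant,irrelevant,ratio
0,18,2,9.000
1,6,14,0.429
2,2,6,0.333
relevant_slope: -8.0000 (+/- 2.3094)
irrelevant_slope: 2.0000 (+/- 5.7735)
```

Here pairs are presented in descending score order, so relevant votes
concentrate on day 0 and the Youden update lands the threshold (0.122)
between the same-topic and cross-topic score clusters. `triage`, `spellfix`
and `qa` subcommands cover the remaining stages; `infodemic --help` lists
all options.

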
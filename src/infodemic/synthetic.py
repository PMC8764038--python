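"""Seeded generators for every input the pipeline consumes.

Real deployment data (vernacular news scraped daily, WHO guideline texts,
user vote streams, questionnaire submissions) is not redistributable, so
each stage is exercised on synthetic counterparts with known ground truth:

* topic-clustered word vectors: per topic, unit vectors concentrated around
  a random centroid (centroid + Gaussian noise, renormalized), plus an
  isotropic "common" pool emulating stopword-like shared vocabulary that is
  also given the top frequency ranks, so SIF down-weighting has something to
  do;
* guideline/news corpora as bags of words drawn mostly from a topic's
  vocabulary, with a controlled fraction from the common pool, and a
  ground-truth same-topic label per pair;
* feedback vote streams where P(relevant) is an increasing (logistic)
  function of the pair's similarity score;
* respondent cohorts with independent per-item Bernoulli prevalences
  (defaults are the observed marginal rates of the 3567-respondent cohort;
  independence is a generator simplification — real answers are correlated,
  so the generator's joint distribution, e.g. its suspect fraction, is a
  property of the generator, not of any study population).

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .embeddings import (
    Document,
    SIFConfig,
    SIFEmbedder,
    TokenFrequencyTable,
    WordVectorTable,
)
from .feedback import (
    IRRELEVANT,
    RELEVANT,
    FeedbackEvent,
    ThresholdState,
    update_threshold,
)
from .matcher import MatchConfig, MatchScore, match_corpus
from .qa import QAEntry


class ParameterError(ValueError):
    """Invalid generator specification."""


# ---------------------------------------------------------------------------
# Word vectors and corpora
# ---------------------------------------------------------------------------


@dataclass
class TopicModelSpec:
    """Controls the synthetic vocabulary: topics, overlap, geometry, seed."""

    n_topics: int = 3
    vocab_per_topic: int = 50
    shared_vocab_fraction: float = 0.2
    dimension: int = 25
    seed: int = 0
    noise: float = 0.1
    zipf_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.n_topics < 1 or self.vocab_per_topic < 1:
            raise ParameterError("n_topics and vocab_per_topic must be positive")
        if not 0.0 <= self.shared_vocab_fraction <= 1.0:
            raise ParameterError("shared_vocab_fraction must be in [0, 1]")
        if self.dimension < 2:
            raise ParameterError(f"dimension must be >= 2, got {self.dimension}")
        if self.noise < 0:
            raise ParameterError("noise must be non-negative")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def topic_word(topic: int, i: int) -> str:
    return f"topic{topic}word{i}"


def shared_word(i: int) -> str:
    return f"common{i}"


def gen_word_vectors(
    spec: TopicModelSpec,
) -> tuple[WordVectorTable, TokenFrequencyTable]:
    """Topic-clustered unit word vectors plus Zipf-distributed frequencies.

    Shared-pool words are isotropic random directions and occupy the top
    Zipf ranks (most frequent); topic words follow in shuffled order.
    """
    rng = np.random.default_rng(spec.seed)
    centroids = [_unit(rng.normal(size=spec.dimension))
                 for _ in range(spec.n_topics)]
    entries: dict[str, np.ndarray] = {}
    for t, c in enumerate(centroids):
        for i in range(spec.vocab_per_topic):
            entries[topic_word(t, i)] = _unit(
                c + spec.noise * rng.normal(size=spec.dimension)
            )
    n_shared = spec.vocab_per_topic
    shared = [shared_word(i) for i in range(n_shared)]
    for w in shared:
        entries[w] = _unit(rng.normal(size=spec.dimension))
    wv = WordVectorTable(dimension=spec.dimension, entries=entries)

    topic_words = [w for w in entries if not w.startswith("common")]
    rng.shuffle(topic_words)
    ordered = shared + topic_words  # shared words take the top (frequent) ranks
    scale = 1000.0
    counts = {
        w: max(1, round(scale / (rank ** spec.zipf_exponent)))
        for rank, w in enumerate(ordered, start=1)
    }
    return wv, TokenFrequencyTable(counts=counts)


def _draw_words(rng: np.random.Generator, spec: TopicModelSpec,
                topic: int, n_words: int) -> list[str]:
    words = []
    for _ in range(n_words):
        if rng.random() < spec.shared_vocab_fraction:
            words.append(shared_word(int(rng.integers(spec.vocab_per_topic))))
        else:
            words.append(topic_word(topic,
                                    int(rng.integers(spec.vocab_per_topic))))
    return words


def gen_corpus(
    spec: TopicModelSpec,
    n_guidelines: int,
    n_articles: int,
    title_len: int = 6,
    body_len: int = 40,
) -> tuple[list[Document], list[Document], dict[tuple[str, str], bool]]:
    """Bag-of-words guideline and article corpora with same-topic truth labels.

    Topics are assigned round-robin so every topic is represented on both
    sides whenever counts allow.
    """
    if n_guidelines < 1 or n_articles < 1:
        raise ParameterError("corpus sizes must be >= 1")
    rng = np.random.default_rng(spec.seed + 1)
    guidelines, articles = [], []
    g_topics, a_topics = {}, {}
    for g in range(n_guidelines):
        topic = g % spec.n_topics
        g_topics[f"g{g}"] = topic
        guidelines.append(Document(
            id=f"g{g}",
            title=" ".join(_draw_words(rng, spec, topic, title_len)),
            body=" ".join(_draw_words(rng, spec, topic, body_len)),
            source="guideline",
        ))
    for a in range(n_articles):
        topic = a % spec.n_topics
        a_topics[f"a{a}"] = topic
        articles.append(Document(
            id=f"a{a}",
            title=" ".join(_draw_words(rng, spec, topic, title_len)),
            body=" ".join(_draw_words(rng, spec, topic, body_len)),
            source="news",
        ))
    truth = {
        (gid, aid): g_topics[gid] == a_topics[aid]
        for gid in g_topics for aid in a_topics
    }
    return guidelines, articles, truth


def gen_faq(spec: TopicModelSpec, n_entries: int,
            question_len: int = 8) -> list[QAEntry]:
    """Synthetic FAQ corpus: one bag-of-words question per entry, topics cycled.

    Questions are sampled without replacement within each entry and suffixed
    with a unique marker word drawn from the topic vocabulary, keeping stored
    questions distinct.
    """
    if n_entries < 1:
        raise ParameterError("n_entries must be >= 1")
    rng = np.random.default_rng(spec.seed + 2)
    entries = []
    seen = set()
    for i in range(n_entries):
        topic = i % spec.n_topics
        words = [topic_word(topic, int(j)) for j in
                 rng.choice(spec.vocab_per_topic,
                            size=min(question_len, spec.vocab_per_topic),
                            replace=False)]
        q = " ".join(words)
        if q in seen:  # vanishingly unlikely; perturb deterministically
            q = q + " " + topic_word(topic, i % spec.vocab_per_topic)
        seen.add(q)
        entries.append(QAEntry(question=q,
                               answer=f"verified guidance text {i}",
                               source="WHO-FAQ" if i % 2 == 0 else "CDC-FAQ"))
    return entries


# ---------------------------------------------------------------------------
# Feedback streams
# ---------------------------------------------------------------------------

VoteModel = Callable[[bool, float], float]


def logistic_vote_model(same_topic: bool, score: float,
                        midpoint: float = 0.5, steepness: float = 8.0,
                        floor: float = 0.05, ceiling: float = 0.95) -> float:
    """P(relevant vote) as a logistic function of the similarity score.

    Increasing in score, bounded away from 0 and 1 so votes stay noisy.
    The topic label is accepted for signature compatibility but the default
    model conditions on the score alone.
    """
    p = floor + (ceiling - floor) / (1.0 + np.exp(-steepness * (score - midpoint)))
    return float(p)


def gen_feedback(
    scored_pairs: Sequence[tuple[tuple[str, str], float, bool]],
    model: VoteModel,
    seed: int,
    pairs_per_day: int = 20,
) -> list[FeedbackEvent]:
    """Bernoulli votes for shown pairs; day index batches presentation order."""
    rng = np.random.default_rng(seed)
    events = []
    for i, ((gid, aid), score, same_topic) in enumerate(scored_pairs):
        p = model(same_topic, score)
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"vote model returned {p}, outside [0, 1]")
        vote = RELEVANT if rng.random() < p else IRRELEVANT
        events.append(FeedbackEvent(guideline_id=gid, article_id=aid,
                                    vote=vote, day=i // pairs_per_day))
    return events


# ---------------------------------------------------------------------------
# Triage cohorts
# ---------------------------------------------------------------------------

#: Observed marginal positive rates of the deployed self-assessment cohort.
DEFAULT_PREVALENCES = {
    "travel_history_14d": 0.1309,
    "close_contact_14d": 0.0913,
    "fever": 0.0905,
    "cough": 0.1558,
    "sob": 0.1028,
    "hospitalization_required": 0.0777,
    "alternate_diagnosis": 0.1107,
}


@dataclass
class CohortSpec:
    """Cohort size and per-item Bernoulli prevalences (independent draws)."""

    n: int = 1000
    prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError(f"cohort size must be positive, got {self.n}")
        unknown = set(self.prevalence) - set(DEFAULT_PREVALENCES)
        if unknown:
            raise ParameterError(f"unknown prevalence fields: {sorted(unknown)}")
        for f, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"prevalence for {f!r} must be in [0,1]")


def gen_respondents(spec: CohortSpec) -> list["TriageResponse"]:
    """Independent Bernoulli draws per questionnaire item, seeded."""
    from .triage import FIELD_ORDER, TriageResponse

    rng = np.random.default_rng(spec.seed)
    prev = {**{f: 0.0 for f in FIELD_ORDER}, **spec.prevalence}
    draws = {f: rng.random(spec.n) < prev[f] for f in FIELD_ORDER}
    return [
        TriageResponse(**{f: bool(draws[f][i]) for f in FIELD_ORDER})
        for i in range(spec.n)
    ]


# ---------------------------------------------------------------------------
# Token corruption (spell-correction / retrieval benchmarks)
# ---------------------------------------------------------------------------

_ALPHABET = string.ascii_lowercase + string.digits


def random_edit(token: str, rng: np.random.Generator) -> str:
    """One random character edit (insert/delete/substitute/transpose).

    Always returns a string different from the input; single-character
    tokens never receive a deletion.
    """
    if not token:
        raise ParameterError("cannot corrupt an empty token")
    for _ in range(100):
        ops = ["insert", "substitute"]
        if len(token) >= 2:
            ops += ["delete", "transpose"]
        op = ops[int(rng.integers(len(ops)))]
        if op == "insert":
            i = int(rng.integers(len(token) + 1))
            out = token[:i] + _ALPHABET[int(rng.integers(len(_ALPHABET)))] + token[i:]
        elif op == "delete":
            i = int(rng.integers(len(token)))
            out = token[:i] + token[i + 1:]
        elif op == "substitute":
            i = int(rng.integers(len(token)))
            out = token[:i] + _ALPHABET[int(rng.integers(len(_ALPHABET)))] + token[i + 1:]
        else:
            i = int(rng.integers(len(token) - 1))
            out = token[:i] + token[i + 1] + token[i] + token[i + 2:]
        if out != token:
            return out
    raise RuntimeError("failed to produce a distinct edit")  # pragma: no cover


# ---------------------------------------------------------------------------
# End-to-end feedback-cycle experiment
# ---------------------------------------------------------------------------


@dataclass
class RetrievalBenchmarkResult:
    """Self-retrieval and one-edit-misspelling recovery rates (fractions)."""

    self_retrieval_rate: float
    misspell_top1_rate: float
    n_entries: int
    n_queries: int


def run_retrieval_benchmark(
    seed: int,
    spec: TopicModelSpec | None = None,
    n_entries: int = 30,
    n_queries: int = 100,
) -> RetrievalBenchmarkResult:
    """FAQ retrieval benchmark over a synthetic corpus.

    Self-retrieval: each stored question, queried verbatim, must come back at
    rank 1 with score 1.  Misspelling recovery: queries are stored questions
    with one random character edit in one token, passed through spell
    correction (dictionary = the generator's vocabulary with its Zipf
    frequencies); success means the edited question's own entry at rank 1.
    """
    from .qa import answer_query, index_faq
    from .spellfix import Corrector, FrequencyDictionary

    spec = spec or TopicModelSpec(seed=seed)
    if spec.seed != seed:
        spec = TopicModelSpec(**{**spec.__dict__, "seed": seed})
    wv, freqs = gen_word_vectors(spec)
    faq = gen_faq(spec, n_entries)
    embedder = SIFEmbedder(wv, freqs, SIFConfig())
    index = index_faq(faq, embedder)

    n_self = 0
    for i, entry in enumerate(faq):
        resp = answer_query(entry.question, index, corrector=None, k=1)
        if (resp.results and resp.results[0].entry is faq[i]
                and abs(resp.results[0].score - 1.0) < 1e-9):
            n_self += 1

    rng = np.random.default_rng(seed + 3)
    corrector = Corrector(FrequencyDictionary(counts=dict(freqs.counts)))
    n_hit = 0
    for _ in range(n_queries):
        i = int(rng.integers(n_entries))
        from .embeddings import tokenize

        tokens = tokenize(faq[i].question)
        j = int(rng.integers(len(tokens)))
        tokens[j] = random_edit(tokens[j], rng)
        resp = answer_query(" ".join(tokens), index, corrector=corrector, k=1)
        if resp.results and resp.results[0].entry is faq[i]:
            n_hit += 1
    return RetrievalBenchmarkResult(
        self_retrieval_rate=n_self / len(faq),
        misspell_top1_rate=n_hit / n_queries,
        n_entries=n_entries,
        n_queries=n_queries,
    )


@dataclass
class FeedbackCycleResult:
    """Precision of delivered pairs before and after one threshold update."""

    precision_before: float
    precision_after: float
    threshold_before: float
    threshold_after: float
    n_pairs: int
    n_delivered_after: int


def run_feedback_cycle(
    seed: int,
    spec: TopicModelSpec | None = None,
    n_guidelines: int = 4,
    n_articles: int = 12,
    vote_model: VoteModel = logistic_vote_model,
) -> FeedbackCycleResult:
    """Simulate one cold-start feedback cycle and measure precision change.

    Day 0 delivers every pair unfiltered (cold start: no learned threshold
    yet), collects one vote per pair, and re-estimates the threshold from the
    labeled scores.  Precision is the fraction of delivered pairs whose
    ground truth is same-topic, before and after the update.
    """
    spec = spec or TopicModelSpec(seed=seed)
    if spec.seed != seed:
        spec = TopicModelSpec(**{**spec.__dict__, "seed": seed})
    wv, freqs = gen_word_vectors(spec)
    guidelines, articles, truth = gen_corpus(spec, n_guidelines, n_articles)
    embedder = SIFEmbedder(wv, freqs, SIFConfig())
    cold_start = MatchConfig(threshold=-1.0)
    scores = match_corpus(guidelines, articles, embedder, cold_start)

    delivered0 = scores  # threshold -1 delivers everything
    precision_before = float(np.mean(
        [truth[(s.guideline_id, s.article_id)] for s in delivered0]))

    shown = [((s.guideline_id, s.article_id), s.combined,
              truth[(s.guideline_id, s.article_id)]) for s in delivered0]
    events = gen_feedback(shown, vote_model, seed=seed + 10_000)
    labeled = [(s.combined, e.vote) for s, e in zip(delivered0, events)]

    state = ThresholdState(threshold=cold_start.threshold)
    state = update_threshold(state, labeled, day=0)

    delivered1 = [s for s in scores if s.combined >= state.threshold]
    precision_after = float(np.mean(
        [truth[(s.guideline_id, s.article_id)] for s in delivered1])) \
        if delivered1 else 0.0
    return FeedbackCycleResult(
        precision_before=precision_before,
        precision_after=precision_after,
        threshold_before=cold_start.threshold,
        threshold_after=state.threshold,
        n_pairs=len(scores),
        n_delivered_after=len(delivered1),
    )
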
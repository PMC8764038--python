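"""FAQ retrieval: spell-correct the query, embed it, return nearest questions.

The chatbot's request-response cycle is realized as embedding
nearest-neighbor retrieval over a stored question/answer corpus (e.g. the
WHO and CDC coronavirus FAQs): stored questions are SIF-embedded once at
index time (with common components fitted on the question set); an incoming
query is tokenized, spell-corrected token by token, embedded with the same
fitted components, and scored against every indexed question by cosine
similarity.  The top-k entries are returned, ties broken by corpus order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .embeddings import SIFEmbedder, tokenize
from .matcher import InputError, cosine
from .spellfix import Corrector

logger = logging.getLogger("infodemic.qa")


@dataclass
class QAEntry:
    """One stored question/answer pair with its source label."""

    question: str
    answer: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.question or not self.answer:
            raise InputError("question and answer must be non-empty")


@dataclass
class QueryResult:
    """One retrieved entry with its similarity score and 1-based rank."""

    entry: QAEntry
    score: float
    rank: int


@dataclass
class QueryResponse:
    """Ranked results; ``no_answer_reason`` set when retrieval was impossible."""

    results: list[QueryResult]
    no_answer_reason: str | None = None


class FAQIndex:
    """Question embeddings for a corpus; degenerate questions are excluded."""

    def __init__(self, corpus: Sequence[QAEntry], embedder: SIFEmbedder) -> None:
        if not corpus:
            raise InputError("FAQ corpus must be non-empty")
        self.corpus = list(corpus)
        self.embedder = embedder
        embedder.fit(e.question for e in self.corpus)
        self.vectors = [embedder.embed(e.question, doc_id=str(i))
                        for i, e in enumerate(self.corpus)]
        self.active = [i for i, v in enumerate(self.vectors)
                       if not v.is_degenerate]
        for i, v in enumerate(self.vectors):
            if v.is_degenerate:
                logger.warning("question %d (%r) has no embeddable token; "
                               "excluded from retrieval",
                               i, self.corpus[i].question[:60])

    def __len__(self) -> int:
        return len(self.corpus)


def index_faq(corpus: Sequence[QAEntry], embedder: SIFEmbedder) -> FAQIndex:
    """Build the question-embedding index for a corpus."""
    return FAQIndex(corpus, embedder)


def answer_query(
    query: str,
    index: FAQIndex,
    corrector: Corrector | None = None,
    k: int = 3,
) -> QueryResponse:
    """Spell-correct, embed and rank ``query`` against the indexed questions.

    Returns the top-k entries by cosine score (ties broken by corpus order).
    A query with no embeddable token yields an empty result with a reason,
    never an exception.
    """
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    tokens = tokenize(query)
    if corrector is not None:
        tokens = corrector.correct_tokens(tokens)
    qvec = index.embedder.embed(" ".join(tokens))
    if qvec.is_degenerate:
        return QueryResponse(
            results=[],
            no_answer_reason="query has no embeddable token after correction",
        )
    scored = [(cosine(qvec.vector, index.vectors[i].vector), i)
              for i in index.active]
    # score descending, corpus order on ties
    scored.sort(key=lambda t: (-t[0], t[1]))
    results = [
        QueryResult(entry=index.corpus[i], score=s, rank=r)
        for r, (s, i) in enumerate(scored[:k], start=1)
    ]
    return QueryResponse(results=results)


def read_faq_jsonl(path: str | Path) -> list[QAEntry]:
    """Read a FAQ corpus from JSON-lines with keys question/answer/source."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            entries.append(QAEntry(
                question=rec["question"],
                answer=rec["answer"],
                source=rec.get("source", ""),
            ))
    return entries


def write_faq_jsonl(entries: Iterable[QAEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(json.dumps(
                {"question": e.question, "answer": e.answer, "source": e.source}
            ) + "\n")
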
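"""Guideline-news matching: two-level cosine similarity and extractive summaries.

Each guideline-article pair is scored at two levels — title against title and
body against body — by cosine similarity of their SIF embeddings, and the two
similarities are combined by a convex weighting (equal weights by default).
A pair is delivered to users when the combined score clears the relevance
threshold; the feedback module owns threshold updates.

Delivered text is abbreviated by a centroid-ranking extractive summarizer:
sentences are embedded individually and ranked by cosine similarity to the
embedding of the whole text, and the top-k are returned in original order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .embeddings import Document, DocumentVector, ParameterError, SIFEmbedder

_SENTENCE_RE = re.compile(r"(?<=[.!?])\s+")


class DegenerateVectorError(ValueError):
    """Cosine of a zero-norm vector is undefined."""


class InputError(ValueError):
    """Empty corpus or otherwise unusable input."""


@dataclass
class MatchConfig:
    """Combination weights and relevance threshold for pair scoring."""

    w_title: float = 0.5
    w_body: float = 0.5
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.w_title < 0 or self.w_body < 0:
            raise ParameterError("weights must be non-negative")
        if abs(self.w_title + self.w_body - 1.0) > 1e-9:
            raise ParameterError(
                f"weights must sum to 1, got {self.w_title} + {self.w_body}"
            )
        if not np.isfinite(self.threshold):
            raise ParameterError(f"threshold must be finite, got {self.threshold}")
        # thresholds outside [-1, 1] are allowed as sentinels: above 1 delivers
        # nothing, below -1 delivers everything


@dataclass
class MatchScore:
    """Similarity of one guideline-article pair and its relevance decision."""

    guideline_id: str
    article_id: str
    title_sim: float
    body_sim: float
    combined: float
    is_relevant: bool


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two nonzero vectors, clipped to [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ParameterError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateVectorError("cosine of a zero-norm vector is undefined")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _level_sim(a: DocumentVector, b: DocumentVector) -> float:
    """Cosine at one level; degenerate embeddings on either side score 0."""
    if a.is_degenerate or b.is_degenerate:
        return 0.0
    return cosine(a.vector, b.vector)


def score_pair(
    guideline: Document,
    article: Document,
    embedder: SIFEmbedder,
    cfg: MatchConfig | None = None,
) -> MatchScore:
    """Score one pair: title cosine, body cosine, weighted combination."""
    cfg = cfg or MatchConfig()
    gt = embedder.embed(guideline.title, f"{guideline.id}:title")
    at = embedder.embed(article.title, f"{article.id}:title")
    gb = embedder.embed(guideline.body, f"{guideline.id}:body")
    ab = embedder.embed(article.body, f"{article.id}:body")
    title_sim = _level_sim(gt, at)
    body_sim = _level_sim(gb, ab)
    combined = cfg.w_title * title_sim + cfg.w_body * body_sim
    return MatchScore(
        guideline_id=guideline.id,
        article_id=article.id,
        title_sim=title_sim,
        body_sim=body_sim,
        combined=combined,
        is_relevant=combined >= cfg.threshold,
    )


def match_corpus(
    guidelines: Sequence[Document],
    articles: Sequence[Document],
    embedder: SIFEmbedder,
    cfg: MatchConfig | None = None,
) -> list[MatchScore]:
    """Score every (guideline, article) pair.

    Common components are fitted on the whole batch (titles and bodies of
    both corpora together) before scoring.  Output is sorted by combined
    score descending, ties broken by (guideline_id, article_id).
    """
    cfg = cfg or MatchConfig()
    if not guidelines or not articles:
        raise InputError("guideline and article corpora must both be non-empty")
    texts = [d.title for d in [*guidelines, *articles]] + \
            [d.body for d in [*guidelines, *articles]]
    embedder.fit(texts)
    scores = [score_pair(g, a, embedder, cfg) for g in guidelines for a in articles]
    scores.sort(key=lambda s: (-s.combined, s.guideline_id, s.article_id))
    return scores


def scores_to_frame(scores: Sequence[MatchScore]) -> pd.DataFrame:
    """Tabulate match scores (the CSV schema the CLI writes)."""
    return pd.DataFrame(
        [
            {
                "guideline_id": s.guideline_id,
                "article_id": s.article_id,
                "title_sim": s.title_sim,
                "body_sim": s.body_sim,
                "combined": s.combined,
                "is_relevant": s.is_relevant,
            }
            for s in scores
        ]
    )


def split_sentences(text: str) -> list[str]:
    """Split on terminal punctuation (. ! ?) followed by whitespace."""
    parts = [s.strip() for s in _SENTENCE_RE.split(text)]
    return [s for s in parts if s]


def summarize_extractive(text: str, k: int, embedder: SIFEmbedder) -> list[str]:
    """Top-k sentences by cosine to the full-text embedding, original order.

    Texts with <= k sentences are returned whole; degenerate sentences (no
    in-vocabulary token) rank last.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    sentences = split_sentences(text)
    if len(sentences) <= k:
        return sentences
    doc_vec = embedder.embed(text)
    if doc_vec.is_degenerate:
        return sentences[:k]
    ranked = []
    for i, sent in enumerate(sentences):
        sv = embedder.embed(sent)
        score = 0.0 if sv.is_degenerate else cosine(sv.vector, doc_vec.vector)
        ranked.append((score, i))
    # highest similarity wins; earlier sentence wins ties
    top = sorted(ranked, key=lambda t: (-t[0], t[1]))[:k]
    return [sentences[i] for _, i in sorted(top, key=lambda t: t[1])]
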
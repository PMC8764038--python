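"""Feedback-adaptive relevance threshold and engagement metrics.

Users vote each delivered guideline-article pair "relevant" or "irrelevant".
Votes drive two things:

* the relevance threshold, re-estimated as the cosine cut that maximizes
  Youden's J = TPR - FPR over the observed scores (relevant votes are the
  positives), ties broken by the lowest such cut so recall of information is
  favored; the threshold is frozen until at least 5 labeled pairs exist;
* engagement metrics: daily relevant/irrelevant counts, their ratio, and
  ordinary-least-squares trend slopes with standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("infodemic.feedback")

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"

#: Labeled pairs required before the threshold may move (burn-in).
MIN_LABELS_FOR_UPDATE = 5


class UndefinedRatioError(ZeroDivisionError):
    """Vote ratio with zero irrelevant votes is undefined."""


class InsufficientDataError(ValueError):
    """Too few observations for a trend fit."""


@dataclass
class FeedbackEvent:
    """One user vote on a delivered pair."""

    guideline_id: str
    article_id: str
    vote: str
    day: int

    def __post_init__(self) -> None:
        if self.vote not in (RELEVANT, IRRELEVANT):
            raise ValueError(f"vote must be {RELEVANT!r} or {IRRELEVANT!r}, "
                             f"got {self.vote!r}")
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")


@dataclass
class ThresholdState:
    """Current relevance cutoff plus its update history.

    history rows are (day, threshold, n_events_used).
    """

    threshold: float = 0.5
    history: list[tuple[int, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not -1.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [-1, 1], got {self.threshold}")


def youden_threshold(labeled_pairs: Sequence[tuple[float, str]]) -> float:
    """The observed score maximizing J = TPR - FPR, lowest cut on ties.

    A pair is predicted relevant when its score >= cut.  One-class inputs
    degenerate gracefully: all-relevant returns the minimum observed score
    (J = TPR, maximal while retaining every positive); all-irrelevant
    returns the maximum observed score (J = -FPR, least harm available).
    """
    scores = np.array([s for s, _ in labeled_pairs], dtype=float)
    votes = np.array([v == RELEVANT for _, v in labeled_pairs], dtype=bool)
    n_pos = int(votes.sum())
    n_neg = len(votes) - n_pos
    best_cut, best_j = None, -np.inf
    for cut in sorted(set(scores.tolist())):
        pred = scores >= cut
        tpr = (pred & votes).sum() / n_pos if n_pos else 0.0
        fpr = (pred & ~votes).sum() / n_neg if n_neg else 0.0
        j = tpr - fpr
        if j > best_j:  # strict: ties keep the earlier (lower) cut
            best_cut, best_j = float(cut), j
    assert best_cut is not None
    return best_cut


def update_threshold(
    state: ThresholdState,
    labeled_pairs: Sequence[tuple[float, str]],
    day: int,
) -> ThresholdState:
    """Return a new state with the Youden-J optimal threshold and history row.

    With fewer than :data:`MIN_LABELS_FOR_UPDATE` labels the threshold is
    unchanged (history still records the attempt).  Empty input is a no-op
    with a warning.
    """
    if not labeled_pairs:
        logger.warning("update_threshold called with no labeled pairs; no-op")
        return state
    for score, vote in labeled_pairs:
        if not -1.0 <= score <= 1.0:
            raise ValueError(f"score {score} outside [-1, 1]")
        if vote not in (RELEVANT, IRRELEVANT):
            raise ValueError(f"unknown vote {vote!r}")
    n = len(labeled_pairs)
    if n < MIN_LABELS_FOR_UPDATE:
        new_threshold = state.threshold
    else:
        new_threshold = youden_threshold(labeled_pairs)
    return ThresholdState(
        threshold=new_threshold,
        history=[*state.history, (day, new_threshold, n)],
    )


@dataclass
class VoteTimeSeries:
    """Per-day (relevant, irrelevant) counts, contiguous from ``start_day``."""

    relevant: list[int]
    irrelevant: list[int]
    start_day: int = 0

    def __post_init__(self) -> None:
        if len(self.relevant) != len(self.irrelevant):
            raise ValueError("relevant and irrelevant series differ in length")
        if any(c < 0 for c in [*self.relevant, *self.irrelevant]):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.relevant)

    @property
    def days(self) -> list[int]:
        return list(range(self.start_day, self.start_day + len(self)))

    def _idx(self, day: int) -> int:
        idx = day - self.start_day
        if not 0 <= idx < len(self):
            raise IndexError(f"day {day} outside series [{self.start_day}, "
                             f"{self.start_day + len(self) - 1}]")
        return idx

    def counts(self, day: int) -> tuple[int, int]:
        i = self._idx(day)
        return self.relevant[i], self.irrelevant[i]

    @classmethod
    def from_events(cls, events: Iterable[FeedbackEvent]) -> "VoteTimeSeries":
        """Aggregate events into contiguous daily counts (missing days zero)."""
        events = list(events)
        if not events:
            raise ValueError("no feedback events")
        lo = min(e.day for e in events)
        hi = max(e.day for e in events)
        rel = [0] * (hi - lo + 1)
        irr = [0] * (hi - lo + 1)
        for e in events:
            if e.vote == RELEVANT:
                rel[e.day - lo] += 1
            else:
                irr[e.day - lo] += 1
        return cls(relevant=rel, irrelevant=irr, start_day=lo)


def vote_ratio(series: VoteTimeSeries, day: int) -> float:
    """relevant/irrelevant count ratio on ``day``; errors on zero denominator."""
    rel, irr = series.counts(day)
    if irr == 0:
        raise UndefinedRatioError(
            f"day {day}: zero irrelevant votes, ratio undefined"
        )
    return rel / irr


def fit_trend(
    series: VoteTimeSeries,
    which: Literal["relevant", "irrelevant"] = RELEVANT,
    cumulative: bool = False,
) -> tuple[float, float]:
    """OLS slope and standard error of daily counts against day index.

    ``cumulative=True`` fits the running total instead of daily arrivals.
    """
    if len(series) < 3:
        raise InsufficientDataError(
            f"trend fit needs >= 3 days, got {len(series)}"
        )
    y = np.asarray(series.relevant if which == RELEVANT else series.irrelevant,
                   dtype=float)
    if cumulative:
        y = np.cumsum(y)
    x = np.asarray(series.days, dtype=float)
    res = stats.linregress(x, y)
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return float(res.slope), stderr


def read_feedback_csv(path: str | Path) -> list[FeedbackEvent]:
    """Read events from CSV columns guideline_id,article_id,vote,day."""
    df = pd.read_csv(path, dtype={"guideline_id": str, "article_id": str})
    return [
        FeedbackEvent(
            guideline_id=str(r.guideline_id),
            article_id=str(r.article_id),
            vote=str(r.vote),
            day=int(r.day),
        )
        for r in df.itertuples()
    ]


def write_feedback_csv(events: Iterable[FeedbackEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"guideline_id": e.guideline_id, "article_id": e.article_id,
             "vote": e.vote, "day": e.day}
            for e in events
        ]
    ).to_csv(path, index=False)
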
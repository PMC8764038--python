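"""Symmetric-delete spelling correction with domain-boosted term frequencies.

Chatbot queries are noisy; each token is corrected against a frequency
dictionary before retrieval.  The symmetric-delete scheme precomputes every
deletion variant (up to ``max_distance`` character deletions) of every
dictionary word; at query time only the deletes of the token itself are
generated and looked up, and surviving candidates are verified with the true
Damerau-Levenshtein distance (optimal string alignment: substitutions,
insertions, deletions and adjacent transpositions all cost 1).

Candidates are ranked by (edit distance ascending, frequency descending,
word lexicographic).  Disease-domain words can be boosted by a multiplicative
frequency factor so that, among equally distant candidates, domain vocabulary
wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd


class ParameterError(ValueError):
    """Out-of-range spelling-correction parameter."""


class ValidationError(ValueError):
    """Malformed token or dictionary entry."""


@dataclass
class FrequencyDictionary:
    """Lowercase word -> positive count map."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for word, c in self.counts.items():
            if c <= 0:
                raise ValidationError(f"count for {word!r} must be positive, got {c}")
            if word != word.lower():
                raise ValidationError(f"dictionary word {word!r} must be lowercase")

    def __contains__(self, word: str) -> bool:
        return word in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrequencyDictionary":
        df = pd.read_csv(path, header=None, names=["word", "count"], dtype=str)
        try:
            int(str(df.iloc[0]["count"]))
        except (ValueError, IndexError):
            df = df.iloc[1:]
        return cls(counts={str(w).lower(): int(c)
                           for w, c in zip(df["word"], df["count"])})


@dataclass
class SpellConfig:
    """Edit-distance limit (1 or 2) and domain boosting."""

    max_edit_distance: int = 2
    domain_boost: float = 10.0
    domain_lexicon: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.max_edit_distance not in (1, 2):
            raise ParameterError(
                f"max_edit_distance must be 1 or 2, got {self.max_edit_distance}"
            )
        if self.domain_boost < 1:
            raise ParameterError(
                f"domain_boost must be >= 1, got {self.domain_boost}"
            )
        self.domain_lexicon = frozenset(w.lower() for w in self.domain_lexicon)


def boost_domain(
    dictionary: FrequencyDictionary,
    lexicon: Iterable[str],
    factor: float,
) -> FrequencyDictionary:
    """Multiply (rounding up) the counts of lexicon words present in the dictionary."""
    if factor < 1:
        raise ParameterError(f"boost factor must be >= 1, got {factor}")
    lexicon = {w.lower() for w in lexicon}
    return FrequencyDictionary(counts={
        w: math.ceil(c * factor) if w in lexicon else c
        for w, c in dictionary.counts.items()
    })


def deletion_variants(word: str, max_distance: int) -> set[str]:
    """All strings reachable from ``word`` by <= max_distance character deletions.

    Includes the word itself (distance 0).
    """
    variants = {word}
    frontier = {word}
    for _ in range(max_distance):
        nxt = set()
        for w in frontier:
            for i in range(len(w)):
                nxt.add(w[:i] + w[i + 1:])
        nxt -= variants
        variants |= nxt
        frontier = nxt
    return variants


@dataclass
class DeleteIndex:
    """Precomputed deletion-variant -> originating-words index."""

    max_distance: int
    index: dict[str, set[str]]


def build_index(dictionary: FrequencyDictionary, max_distance: int = 2) -> DeleteIndex:
    """Index every dictionary word under each of its deletion variants."""
    if max_distance not in (1, 2):
        raise ParameterError(f"max_distance must be 1 or 2, got {max_distance}")
    index: dict[str, set[str]] = {}
    for word in dictionary.counts:
        for variant in deletion_variants(word, max_distance):
            index.setdefault(variant, set()).add(word)
    return DeleteIndex(max_distance=max_distance, index=index)


def damerau_levenshtein(a: str, b: str) -> int:
    """Optimal-string-alignment distance: ins/del/sub/adjacent-transposition, cost 1."""
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1,        # deletion
                         cur[j - 1] + 1,     # insertion
                         prev[j - 1] + cost)  # substitution
            if (i > 1 and j > 1 and a[i - 1] == b[j - 2]
                    and a[i - 2] == b[j - 1]):
                cur[j] = min(cur[j], prev2[j - 2] + 1)  # transposition
        prev2, prev = prev, cur
    return prev[lb]


def _effective_count(word: str, dictionary: FrequencyDictionary,
                     cfg: SpellConfig) -> float:
    c = dictionary.counts.get(word, 0)
    if word in cfg.domain_lexicon:
        return c * cfg.domain_boost
    return float(c)


def candidates(token: str, index: DeleteIndex,
               dictionary: FrequencyDictionary,
               max_edit_distance: int) -> dict[str, int]:
    """Dictionary words within true edit distance, via the delete index."""
    found: dict[str, int] = {}
    seen: set[str] = set()
    for variant in deletion_variants(token, max_edit_distance):
        for word in index.index.get(variant, ()):
            if word in seen:
                continue
            seen.add(word)
            d = damerau_levenshtein(token, word)
            if d <= max_edit_distance:
                found[word] = d
    return found


def correct(token: str, index: DeleteIndex,
            dictionary: FrequencyDictionary,
            cfg: SpellConfig | None = None) -> str:
    """Best correction of ``token``; the token itself if in-dictionary or hopeless.

    Ranking: distance ascending, boosted frequency descending, lexicographic.
    """
    cfg = cfg or SpellConfig()
    if not token:
        raise ValidationError("token must be non-empty")
    if token != token.lower():
        raise ValidationError(f"token {token!r} must be lowercase")
    if token in dictionary:
        return token  # distance 0 dominates every alternative
    cand = candidates(token, index, dictionary, cfg.max_edit_distance)
    if not cand:
        return token
    return min(cand, key=lambda w: (cand[w],
                                    -_effective_count(w, dictionary, cfg),
                                    w))


class Corrector:
    """Convenience wrapper binding a dictionary, its delete index, and a config."""

    def __init__(self, dictionary: FrequencyDictionary,
                 cfg: SpellConfig | None = None) -> None:
        self.dictionary = dictionary
        self.cfg = cfg or SpellConfig()
        self.index = build_index(dictionary, self.cfg.max_edit_distance)

    def correct(self, token: str) -> str:
        return correct(token, self.index, self.dictionary, self.cfg)

    def correct_tokens(self, tokens: Iterable[str]) -> list[str]:
        return [self.correct(t) for t in tokens]
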
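"""Word vectors and smooth-inverse-frequency (SIF) document embeddings.

The matching, summarization and FAQ-retrieval stages all represent a piece of
text as a single dense vector: the frequency-down-weighted average of its word
vectors, optionally followed by removal of the corpus's dominant singular
direction ("common component removal").  The weight of a word ``w`` is

    a / (a + p(w))

where ``p(w)`` is the word's relative frequency in a background corpus and
``a`` is a small smoothing constant (default 1e-3).  Frequent function-like
words are damped towards zero weight; words absent from the frequency table
get the maximal weight 1, so rare domain vocabulary is never discarded.

Word vectors are read from the word2vec *text* dialect only: a header line
``<vocab_size> <dimension>`` followed by one ``word v1 ... vd`` row per word.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("infodemic.embeddings")

#: Default SIF smoothing constant.
DEFAULT_SIF_A = 1e-3
#: Default number of common components removed after corpus-level embedding.
DEFAULT_N_COMPONENTS = 1

# Unicode word characters, underscores excluded; hyphens and all punctuation
# split tokens ("COVID-19" -> "covid", "19").
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


class ParseError(ValueError):
    """Malformed word-vector or table file; the message names the line."""


class ParameterError(ValueError):
    """An out-of-range configuration value."""


class InsufficientDataError(ValueError):
    """Too few non-degenerate vectors for the requested operation."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class WordVectorTable:
    """Vocabulary -> dense vector map with a fixed dimension."""

    dimension: int
    entries: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ParameterError(f"dimension must be positive, got {self.dimension}")
        if not self.entries:
            raise ParameterError("word vector table must be non-empty")
        for word, vec in self.entries.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dimension,):
                raise ParameterError(
                    f"vector for {word!r} has shape {vec.shape}, "
                    f"expected ({self.dimension},)"
                )
            self.entries[word] = vec

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __getitem__(self, word: str) -> np.ndarray:
        return self.entries[word]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def vocabulary(self) -> list[str]:
        return list(self.entries)


@dataclass
class TokenFrequencyTable:
    """Background token counts; supplies p(w) = count/total for SIF weights."""

    counts: dict[str, int]
    total: int = 0

    def __post_init__(self) -> None:
        for word, c in self.counts.items():
            if c < 0:
                raise ParameterError(f"negative count for {word!r}")
        computed = int(sum(self.counts.values()))
        if self.total and self.total != computed:
            raise ParameterError(
                f"total {self.total} does not equal sum of counts {computed}"
            )
        self.total = computed
        if self.total <= 0:
            raise ParameterError("frequency table must have positive total count")

    def p(self, word: str) -> float:
        """Relative frequency of ``word``; 0.0 for unseen words."""
        return self.counts.get(word, 0) / self.total

    @classmethod
    def from_csv(cls, path: str | Path) -> "TokenFrequencyTable":
        """Read a two-column (word,count) CSV, with or without a header row."""
        df = pd.read_csv(path, header=None, names=["word", "count"], dtype=str)
        if df.empty:
            raise ParseError(f"{path}: empty frequency table")
        first = str(df.iloc[0]["count"])
        try:
            int(first)
        except ValueError:  # header row
            df = df.iloc[1:]
        if df.empty:
            raise ParseError(f"{path}: frequency table has a header but no rows")
        counts = {str(w): int(c) for w, c in zip(df["word"], df["count"])}
        return cls(counts=counts)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"word": list(self.counts), "count": list(self.counts.values())}
        ).to_csv(path, index=False)


@dataclass
class SIFConfig:
    """Hyperparameters of the SIF embedding.

    a: smoothing constant of the word weight a/(a+p(w)).
    n_common_components: number of top singular directions removed at corpus
        level (0 disables removal).
    """

    a: float = DEFAULT_SIF_A
    n_common_components: int = DEFAULT_N_COMPONENTS

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ParameterError(f"SIF a must be > 0, got {self.a}")
        if self.n_common_components < 0:
            raise ParameterError(
                f"n_common_components must be >= 0, got {self.n_common_components}"
            )


@dataclass
class Document:
    """A guideline or news record: id plus title/body text and optional metadata."""

    id: str
    title: str = ""
    body: str = ""
    date: str | None = None
    source: str | None = None
    language: str | None = None

    def __post_init__(self) -> None:
        if not (self.title or self.body):
            raise ParameterError(f"document {self.id!r}: title or body must be non-empty")


@dataclass
class DocumentVector:
    """Embedding of one text; degenerate means no embeddable token was found."""

    doc_id: str
    vector: np.ndarray
    is_degenerate: bool = False

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.is_degenerate and np.any(self.vector != 0):
            raise ParameterError("degenerate vectors must be all-zero")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_word_vectors(path: str | Path) -> WordVectorTable:
    """Parse a word2vec text-format file into a :class:`WordVectorTable`.

    Duplicate words keep their first occurrence (logged).  Malformed headers
    or rows raise :class:`ParseError` naming the offending line number.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: line 1: empty file")
    header = lines[0].split()
    if len(header) != 2:
        raise ParseError(f"{path}: line 1: expected '<vocab_size> <dimension>' header")
    try:
        vocab_size, dim = int(header[0]), int(header[1])
    except ValueError as exc:
        raise ParseError(f"{path}: line 1: non-integer header field") from exc
    if vocab_size <= 0 or dim <= 0:
        raise ParseError(f"{path}: line 1: header fields must be positive")
    entries: dict[str, np.ndarray] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != dim + 1:
            raise ParseError(
                f"{path}: line {lineno}: expected word + {dim} values, got "
                f"{len(parts) - 1} values"
            )
        word = parts[0]
        try:
            # tolerate U+2212 minus signs from copy-pasted text
            vec = np.array([float(x.replace("−", "-")) for x in parts[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric value") from exc
        if word in entries:
            logger.warning("%s: line %d: duplicate word %r kept first occurrence",
                           path, lineno, word)
            continue
        entries[word] = vec
    if not entries:
        raise ParseError(f"{path}: line 2: no vector rows")
    if len(entries) != vocab_size:
        logger.warning("%s: header declares %d words, parsed %d",
                       path, vocab_size, len(entries))
    return WordVectorTable(dimension=dim, entries=entries)


def write_word_vectors(table: WordVectorTable, path: str | Path) -> None:
    """Write a table in word2vec text format (round-trips with the loader)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {table.dimension}\n")
        for word, vec in table.entries.items():
            fh.write(word + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def read_documents_jsonl(path: str | Path) -> list[Document]:
    """Read documents from JSON-lines with keys id/title/body/date/source."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: line {lineno}: invalid JSON") from exc
            docs.append(Document(
                id=str(rec["id"]),
                title=rec.get("title", "") or "",
                body=rec.get("body", "") or "",
                date=rec.get("date"),
                source=rec.get("source"),
                language=rec.get("language"),
            ))
    return docs


def write_documents_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in docs:
            rec = {"id": d.id, "title": d.title, "body": d.body}
            if d.date is not None:
                rec["date"] = d.date
            if d.source is not None:
                rec["source"] = d.source
            fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# SIF pipeline
# ---------------------------------------------------------------------------


def tokenize(text: str) -> list[str]:
    """Lowercased Unicode word tokens, punctuation and hyphens splitting."""
    return _TOKEN_RE.findall(text.lower())


def sif_weight(word: str, freqs: TokenFrequencyTable, a: float = DEFAULT_SIF_A) -> float:
    """Smooth-inverse-frequency weight a/(a + p(word)), in (0, 1]."""
    if a <= 0:
        raise ParameterError(f"SIF a must be > 0, got {a}")
    return a / (a + freqs.p(word))


def embed_document(
    doc_text: str,
    wv: WordVectorTable,
    freqs: TokenFrequencyTable,
    cfg: SIFConfig | None = None,
    doc_id: str = "",
) -> DocumentVector:
    """SIF embedding: the mean of sif_weight(t)*wv[t] over in-vocabulary tokens.

    Tokens absent from ``wv`` are skipped; a text with no in-vocabulary token
    yields an all-zero vector flagged ``is_degenerate``.
    """
    cfg = cfg or SIFConfig()
    acc = np.zeros(wv.dimension)
    m = 0
    for tok in tokenize(doc_text):
        if tok in wv:
            acc += sif_weight(tok, freqs, cfg.a) * wv[tok]
            m += 1
    if m == 0:
        return DocumentVector(doc_id=doc_id, vector=acc, is_degenerate=True)
    return DocumentVector(doc_id=doc_id, vector=acc / m)


def common_components(vectors: Sequence[DocumentVector], n: int) -> np.ndarray:
    """Top-n right singular vectors of the stacked non-degenerate matrix.

    Returns an (n, dimension) array.  Requires at least two non-degenerate
    vectors when n >= 1.
    """
    if n == 0:
        dim = vectors[0].vector.shape[0] if vectors else 0
        return np.zeros((0, dim))
    mat = np.stack([v.vector for v in vectors if not v.is_degenerate]) \
        if any(not v.is_degenerate for v in vectors) else np.zeros((0, 0))
    if mat.shape[0] < 2:
        raise InsufficientDataError(
            f"component removal needs >= 2 non-degenerate vectors, got {mat.shape[0]}"
        )
    _, _, vt = np.linalg.svd(mat, full_matrices=False)
    return vt[:n]


def _subtract_components(vec: np.ndarray, components: np.ndarray) -> np.ndarray:
    out = vec.copy()
    for u in components:
        out -= np.dot(u, out) * u
    return out


def remove_common_component(
    vectors: Sequence[DocumentVector], n: int = DEFAULT_N_COMPONENTS
) -> list[DocumentVector]:
    """Remove the top-n singular directions from every non-degenerate vector.

    Degenerate vectors pass through unchanged; ``n=0`` is the identity.
    """
    if n == 0:
        return list(vectors)
    comps = common_components(vectors, n)
    out = []
    for v in vectors:
        if v.is_degenerate:
            out.append(v)
        else:
            out.append(DocumentVector(doc_id=v.doc_id,
                                      vector=_subtract_components(v.vector, comps)))
    return out


class SIFEmbedder:
    """Stateful convenience wrapper: word vectors + frequencies + fitted components.

    ``embed`` returns the raw SIF embedding; after :meth:`fit` (called with the
    batch of texts being matched or indexed) it additionally subtracts the
    fitted common components.  Components are never fitted on a single text.
    """

    def __init__(
        self,
        wv: WordVectorTable,
        freqs: TokenFrequencyTable,
        cfg: SIFConfig | None = None,
    ) -> None:
        self.wv = wv
        self.freqs = freqs
        self.cfg = cfg or SIFConfig()
        self.components_: np.ndarray | None = None

    @property
    def dimension(self) -> int:
        return self.wv.dimension

    def embed(self, text: str, doc_id: str = "") -> DocumentVector:
        dv = embed_document(text, self.wv, self.freqs, self.cfg, doc_id=doc_id)
        if self.components_ is not None and not dv.is_degenerate:
            vec = _subtract_components(dv.vector, self.components_)
            if np.allclose(vec, 0):
                return DocumentVector(doc_id=doc_id, vector=np.zeros_like(vec),
                                      is_degenerate=True)
            dv = DocumentVector(doc_id=doc_id, vector=vec)
        return dv

    def fit(self, texts: Iterable[str]) -> "SIFEmbedder":
        """Fit common components on the raw embeddings of ``texts``."""
        if self.cfg.n_common_components == 0:
            self.components_ = None
            return self
        raw = [embed_document(t, self.wv, self.freqs, self.cfg) for t in texts]
        if sum(not v.is_degenerate for v in raw) < 2:
            logger.warning("fewer than 2 non-degenerate texts; skipping "
                           "common-component removal")
            self.components_ = None
            return self
        self.components_ = common_components(raw, self.cfg.n_common_components)
        return self
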
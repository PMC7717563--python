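"""Text vectorization: bag-of-words, tf-idf, and word embeddings.

Three feature families feed the classifiers downstream:

* **binary / count bag-of-words** over a training vocabulary, for the
  naive Bayes sentence classifiers;
* **tf-idf** with the max-normalised term frequency,
  ``tfidf(t, d) = (f_{t,d} / max_{t'} f_{t',d}) * ln(N / df_t)``,
  applied to count vectors (natural logarithm; document frequencies
  are frozen at fit time);
* **word embeddings**, either trained on the corpus itself (count-based:
  positive PMI co-occurrence matrix factorised by truncated SVD) or
  loaded from word2vec text format, mean-pooled into document
  embeddings or stacked into fixed-length word matrices.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "tokenize",
    "Vocabulary",
    "BowVector",
    "build_vocabulary",
    "binarize",
    "count_vector",
    "TfidfWeighter",
    "tfidf_transform",
    "EmbeddingModel",
    "train_embeddings",
    "load_embeddings",
    "save_embeddings",
    "document_embedding",
    "word_matrix",
    "DocMatrix",
]

_TOKEN = re.compile(r"\w+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens; punctuation stripped; deterministic."""
    return [t.lower() for t in _TOKEN.findall(text)]


@dataclass(frozen=True)
class Vocabulary:
    """Ordered term list with term → index lookup (a bijection onto
    ``0..|V|-1``), built from training documents only."""

    terms: tuple[str, ...]
    index: dict[str, int] = field(compare=False)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index


def build_vocabulary(token_lists: Iterable[Sequence[str]]) -> Vocabulary:
    """Insertion-ordered union of all tokens seen during training."""
    index: dict[str, int] = {}
    for tokens in token_lists:
        for token in tokens:
            if token not in index:
                index[token] = len(index)
    return Vocabulary(terms=tuple(index), index=index)


@dataclass(frozen=True)
class BowVector:
    """A dense bag-of-words vector with its mode recorded.

    binary: values in {0, 1}; count: non-negative integers;
    tfidf: non-negative reals.
    """

    mode: Literal["binary", "count", "tfidf"]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if self.mode == "binary" and not np.isin(v, (0, 1)).all():
            raise ValueError("binary vector may only contain 0 and 1")
        if np.any(v < 0):
            raise ValueError(f"{self.mode} vector must be non-negative")


def binarize(tokens: Sequence[str], vocab: Vocabulary) -> BowVector:
    """Term-presence vector; out-of-vocabulary tokens are ignored."""
    values = np.zeros(len(vocab))
    for token in tokens:
        i = vocab.index.get(token)
        if i is not None:
            values[i] = 1.0
    return BowVector("binary", values)


def count_vector(tokens: Sequence[str], vocab: Vocabulary) -> BowVector:
    """Term-frequency vector; out-of-vocabulary tokens are ignored."""
    values = np.zeros(len(vocab))
    for token in tokens:
        i = vocab.index.get(token)
        if i is not None:
            values[i] += 1.0
    return BowVector("count", values)


class TfidfWeighter:
    """Max-normalised tf-idf with document frequencies frozen at fit time.

    ``transform`` maps a count vector to
    ``(f_{t,d} / max_t f_{t,d}) * ln(N / df_t)``; an empty document maps
    to the all-zero vector, and terms unseen at fit time weigh zero.
    """

    def __init__(self):
        self.n_documents: int | None = None
        self.idf: np.ndarray | None = None

    def fit(self, count_vectors: Sequence[BowVector]) -> "TfidfWeighter":
        if not count_vectors:
            raise ValueError("tf-idf requires at least one document")
        counts = np.stack([v.values for v in count_vectors])
        self.n_documents = counts.shape[0]
        df = (counts > 0).sum(axis=0)
        with np.errstate(divide="ignore"):
            idf = np.log(self.n_documents / df)
        idf[df == 0] = 0.0  # term never seen: weight 0
        self.idf = idf
        return self

    def transform(self, vector: BowVector) -> BowVector:
        if self.idf is None:
            raise RuntimeError("TfidfWeighter must be fitted before transform")
        counts = vector.values
        max_f = counts.max() if counts.size else 0.0
        if max_f == 0:
            return BowVector("tfidf", np.zeros_like(counts, dtype=float))
        weighted = (counts / max_f) * self.idf
        return BowVector("tfidf", np.maximum(weighted, 0.0))


def tfidf_transform(count_vectors: Sequence[BowVector]) -> list[BowVector]:
    """Fit-and-transform tf-idf over one corpus of count vectors."""
    weighter = TfidfWeighter().fit(count_vectors)
    return [weighter.transform(v) for v in count_vectors]


@dataclass
class EmbeddingModel:
    """Word vectors of a fixed dimension."""

    dimension: int
    vectors: dict[str, np.ndarray]

    def __post_init__(self):
        for term, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {term!r} has shape {vec.shape}, "
                    f"expected ({self.dimension},)"
                )

    def __contains__(self, term: str) -> bool:
        return term in self.vectors


def train_embeddings(
    token_lists: Sequence[Sequence[str]],
    dimension: int = 100,
    window: int = 5,
    min_count: int = 1,
    seed: int = 0,
) -> EmbeddingModel:
    """Train count-based word embeddings on a (small) corpus.

    Builds a symmetric within-window co-occurrence matrix over all terms
    occurring at least ``min_count`` times, applies positive pointwise
    mutual information, and factorises with truncated SVD; the embedding
    of term *t* is row *t* of ``U * sqrt(S)``.  Deterministic given the
    seed.  If the vocabulary is smaller than the requested dimension the
    extra components are zero-padded so every vector still has shape
    ``(dimension,)``.
    """
    if dimension <= 0:
        raise ValueError("embedding dimension must be positive")
    freqs: dict[str, int] = {}
    for tokens in token_lists:
        for token in tokens:
            freqs[token] = freqs.get(token, 0) + 1
    terms = [t for t in freqs if freqs[t] >= min_count]
    if not terms:
        raise ValueError("corpus has no terms meeting min_count")
    index = {t: i for i, t in enumerate(terms)}
    n = len(terms)

    cooc = np.zeros((n, n))
    for tokens in token_lists:
        ids = [index.get(t, -1) for t in tokens]
        for pos, i in enumerate(ids):
            if i < 0:
                continue
            for off in range(1, window + 1):
                if pos + off >= len(ids):
                    break
                j = ids[pos + off]
                if j >= 0:
                    cooc[i, j] += 1.0
                    cooc[j, i] += 1.0

    total = cooc.sum()
    if total == 0:
        # degenerate corpus (all documents length 1): zero embeddings
        vectors = {t: np.zeros(dimension) for t in terms}
        return EmbeddingModel(dimension, vectors)
    row = cooc.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log((cooc * total) / (row * row.T))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)

    k = min(dimension, n)
    rng = np.random.default_rng(seed)
    # deterministic randomized SVD (scipy/sklearn-style range finder)
    omega = rng.standard_normal((n, min(k + 10, n)))
    q, _ = np.linalg.qr(ppmi @ omega)
    b = q.T @ ppmi
    u_b, s, _ = np.linalg.svd(b, full_matrices=False)
    u = (q @ u_b)[:, :k]
    emb = u * np.sqrt(s[:k])
    if k < dimension:
        emb = np.hstack([emb, np.zeros((n, dimension - k))])
    return EmbeddingModel(dimension, {t: emb[index[t]].copy() for t in terms})


def load_embeddings(path: str | Path) -> EmbeddingModel:
    """Read word2vec text format (``word v1 ... vd`` per line, with an
    optional leading ``count dim`` header line)."""
    vectors: dict[str, np.ndarray] = {}
    dimension: int | None = None
    with open(path, encoding="utf-8") as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty embeddings file")
    start = 0
    head = lines[0].split()
    if len(head) == 2 and all(p.lstrip("-").isdigit() for p in head):
        dimension = int(head[1])
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.split()
        word, values = parts[0], parts[1:]
        if dimension is None:
            dimension = len(values)
        if len(values) != dimension:
            raise ValueError(
                f"line {lineno}: expected {dimension} components, got {len(values)}"
            )
        vectors[word] = np.array([float(v) for v in values])
    if not vectors:
        raise ValueError(f"{path}: no vectors found")
    return EmbeddingModel(dimension, vectors)


def save_embeddings(model: EmbeddingModel, path: str | Path) -> None:
    """Write word2vec text format with a ``count dim`` header."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"{len(model.vectors)} {model.dimension}\n")
        for word, vec in model.vectors.items():
            handle.write(word + " " + " ".join(f"{v:.8g}" for v in vec) + "\n")


def document_embedding(tokens: Sequence[str], model: EmbeddingModel) -> np.ndarray:
    """Mean of the word vectors of in-vocabulary tokens (zero vector if
    the document has none); out-of-vocabulary tokens do not dilute the
    mean."""
    rows = [model.vectors[t] for t in tokens if t in model.vectors]
    if not rows:
        return np.zeros(model.dimension)
    return np.mean(rows, axis=0)


@dataclass
class DocMatrix:
    """Fixed-shape ``max_len x dimension`` word matrix; rows past
    ``n_real_tokens`` are zero padding."""

    rows: np.ndarray
    n_real_tokens: int


def word_matrix(
    tokens: Sequence[str], model: EmbeddingModel, max_len: int = 400
) -> DocMatrix:
    """Stack token vectors into a zero-padded fixed-length matrix,
    truncating documents longer than ``max_len`` words."""
    rows = np.zeros((max_len, model.dimension))
    kept = tokens[:max_len]
    for i, token in enumerate(kept):
        if token in model.vectors:
            rows[i] = model.vectors[token]
    return DocMatrix(rows=rows, n_real_tokens=len(kept))
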
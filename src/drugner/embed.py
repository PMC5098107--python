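"""Word embeddings and the distance operations built on them.

The window and sequence representations both start from continuous
bag-of-words (CBOW) embeddings: every token of the combined train+test
corpus (optionally plus an extra plain-text corpus) gets a ``dim``-length
row vector, trained so a token is predicted from the mean of its context
vectors.  Training uses negative sampling and runs single-threaded from a
fixed seed, so a given corpus + seed always produces the same table.

On top of the table sit the two distances the method uses (Euclidean and
cosine), the group-level distance diagnostics (drug-drug vs drug-nondrug
vs nondrug-nondrug averages) and the weight-decay coefficient

    lambda = (1 / (n * (n - 1))) * sum_{i<j} dist(x_i, x_j)

computed over word vectors.  Note the normalizer counts *ordered* pairs
while the sum runs over unordered ones, so this equals half the mean
pairwise distance; ``mean=True`` selects the true mean instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.base import BaseEstimator

from .corpus import PAD, Corpus


class EmbeddingError(ValueError):
    pass


@dataclass
class WordVectorTable:
    """Token -> row-vector lookup with a zero-vector OOV/padding policy."""

    vectors: Mapping[str, np.ndarray]
    dim: int

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    @property
    def vocab(self) -> set[str]:
        return set(self.vectors)

    def vector(self, token: str) -> np.ndarray:
        """Vector for ``token``; the padding token and OOV map to zeros."""
        v = self.vectors.get(token)
        if v is None:
            return np.zeros(self.dim)
        return v

    def matrix(self, tokens: Sequence[str]) -> np.ndarray:
        return np.vstack([self.vector(t) for t in tokens]) if tokens else np.zeros((0, self.dim))

    def save(self, path: str | Path) -> None:
        """Persist in word2vec text format (header ``vocab_size dim``)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vectors)} {self.dim}\n")
            for token in sorted(self.vectors):
                vals = " ".join(f"{x:.8g}" for x in self.vectors[token])
                fh.write(f"{token} {vals}\n")

    @classmethod
    def load(cls, path: str | Path) -> "WordVectorTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            vectors: dict[str, np.ndarray] = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vectors[parts[0]] = np.asarray([float(x) for x in parts[1:]])
                if vectors[parts[0]].shape != (dim,):
                    raise EmbeddingError(f"bad vector length for {parts[0]!r}")
        if len(vectors) != n:
            raise EmbeddingError("vector count does not match header")
        return cls(vectors=vectors, dim=dim)


class CBOWEmbeddings(BaseEstimator):
    """Seeded CBOW word-embedding trainer with negative sampling.

    Parameters
    ----------
    dim : vector dimension (default 100)
    window : context tokens on each side of the centre token (default 5)
    epochs, negative, alpha, min_alpha : training schedule; the learning
        rate decays linearly from ``alpha`` to ``min_alpha``
    min_count : tokens rarer than this are dropped from the vocabulary
    seed : RNG seed; training is single-threaded and fully deterministic

    Fitted attributes: ``vocab_`` (token -> index), ``syn0_`` (input
    vectors, the embeddings), ``syn1_`` (output vectors).
    """

    def __init__(
        self,
        dim: int = 100,
        window: int = 5,
        epochs: int = 10,
        negative: int = 5,
        alpha: float = 0.1,
        min_alpha: float = 1e-4,
        min_count: int = 1,
        seed: int = 0,
    ):
        self.dim = dim
        self.window = window
        self.epochs = epochs
        self.negative = negative
        self.alpha = alpha
        self.min_alpha = min_alpha
        self.min_count = min_count
        self.seed = seed

    def fit(self, sentences: Sequence[Sequence[str]]) -> "CBOWEmbeddings":
        if self.dim <= 0 or self.window <= 0:
            raise EmbeddingError("dim and window must be positive")
        counts: dict[str, int] = {}
        for sent in sentences:
            for tok in sent:
                counts[tok] = counts.get(tok, 0) + 1
        counts.pop(PAD, None)
        vocab = {t: i for i, t in enumerate(sorted(t for t, c in counts.items() if c >= self.min_count))}
        if not vocab:
            raise EmbeddingError("empty corpus")
        total = sum(counts[t] for t in vocab)
        if total < self.window:
            raise EmbeddingError("corpus smaller than one context window")

        rng = np.random.default_rng(self.seed)
        V = len(vocab)
        syn0 = (rng.random((V, self.dim)) - 0.5) / self.dim
        syn1 = np.zeros((V, self.dim))

        # negative-sampling distribution: unigram^0.75
        freq = np.asarray([counts[t] for t in vocab], dtype=float) ** 0.75
        neg_probs = freq / freq.sum()

        encoded = [
            np.asarray([vocab[t] for t in sent if t in vocab], dtype=np.int64)
            for sent in sentences
        ]
        encoded = [s for s in encoded if len(s) >= 2]
        n_steps = max(1, self.epochs * sum(len(s) for s in encoded))
        step = 0
        for _ in range(self.epochs):
            for sent in encoded:
                n = len(sent)
                for pos in range(n):
                    lr = max(
                        self.min_alpha,
                        self.alpha * (1.0 - step / n_steps),
                    )
                    step += 1
                    lo = max(0, pos - self.window)
                    hi = min(n, pos + self.window + 1)
                    ctx = np.concatenate([sent[lo:pos], sent[pos + 1 : hi]])
                    if len(ctx) == 0:
                        continue
                    h = syn0[ctx].mean(axis=0)
                    targets = np.empty(1 + self.negative, dtype=np.int64)
                    targets[0] = sent[pos]
                    targets[1:] = rng.choice(V, size=self.negative, p=neg_probs)
                    labels = np.zeros(1 + self.negative)
                    labels[0] = 1.0
                    out = syn1[targets]
                    scores = 1.0 / (1.0 + np.exp(-out @ h))
                    g = (scores - labels) * lr
                    dh = g @ out
                    syn1[targets] -= np.outer(g, h)
                    syn0[ctx] -= dh / len(ctx)

        self.vocab_ = vocab
        self.syn0_ = syn0
        self.syn1_ = syn1
        return self

    def to_table(self, center: bool = True, normalize: bool = True) -> WordVectorTable:
        """Export the input vectors as a lookup table.

        By default the vocabulary-mean vector is removed and each vector is
        scaled to unit norm — the usual post-processing that strips the
        common direction raw embeddings share and puts every token on a
        comparable scale (rare tokens otherwise sit near their tiny random
        initialization).
        """
        E = self.syn0_
        if center:
            E = E - E.mean(axis=0)
        if normalize:
            E = E / np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
        return WordVectorTable(
            vectors={t: E[i].copy() for t, i in self.vocab_.items()},
            dim=self.dim,
        )


def train_embeddings(
    corpora: Sequence[Corpus],
    extra_sentences: Sequence[Sequence[str]] = (),
    dim: int = 100,
    window: int = 5,
    seed: int = 0,
    **kwargs,
) -> WordVectorTable:
    """Train CBOW vectors on the combined corpora (+ optional extra text).

    Mirrors the method's setup: train and test sentences are pooled into a
    single embedding corpus so no corpus token is out of vocabulary; an
    additional plain-text source (e.g. encyclopedia text) may be appended
    to enlarge the context statistics.
    """
    sentences: list[list[str]] = []
    for c in corpora:
        sentences.extend(c.token_sentences())
    sentences.extend([list(s) for s in extra_sentences])
    if not sentences:
        raise EmbeddingError("no input sentences")
    est = CBOWEmbeddings(dim=dim, window=window, seed=seed, **kwargs)
    est.fit(sentences)
    return est.to_table()


# ---------------------------------------------------------------------------
# distances


def euclidean_distance(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise EmbeddingError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise EmbeddingError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise EmbeddingError("cosine similarity undefined for the zero vector")
    return float(np.dot(u, v) / (nu * nv))


def lambda_avg_distance(
    X: np.ndarray,
    mean: bool = False,
    max_sample: int = 2000,
    seed: int = 0,
) -> float:
    """Distance-derived weight-decay coefficient over a set of vectors.

    With ``mean=False`` (default) returns
    ``sum_{i<j} dist(x_i, x_j) / (n * (n - 1))`` — the printed formula,
    whose normalizer counts ordered pairs, i.e. half the pairwise mean.
    ``mean=True`` divides by the number of unordered pairs instead.

    For ``n > max_sample`` a uniform subsample (seeded) is used, since the
    all-pairs sum is quadratic in the vocabulary size.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise EmbeddingError("need at least two vectors")
    if n > max_sample:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(n, size=max_sample, replace=False)]
        n = max_sample
    total = float(pdist(X, metric="euclidean").sum())
    if mean:
        return total / (n * (n - 1) / 2)
    return total / (n * (n - 1))


def group_distance_summary(
    table: WordVectorTable, drug_tokens: Iterable[str]
) -> dict[str, dict[str, float]]:
    """Average Euclidean distance and cosine similarity within/between groups.

    Returns ``{"euclidean": {...}, "cosine": {...}}`` with keys
    ``drug-drug``, ``drug-nondrug``, ``nondrug-nondrug``; an average over an
    empty pair set is reported as ``nan``.
    """
    drug = sorted(set(drug_tokens))
    missing = [t for t in drug if t not in table]
    if missing:
        raise EmbeddingError(f"tokens not in vocabulary: {missing[:5]}")
    nondrug = sorted(table.vocab - set(drug))
    D = table.matrix(drug)
    N = table.matrix(nondrug)

    def _cos_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        return 1.0 - cdist(A, B, metric="cosine")

    def _within(M: np.ndarray, metric: str) -> float:
        if M.shape[0] < 2:
            return math.nan
        if metric == "euclidean":
            return float(pdist(M, metric="euclidean").mean())
        iu = np.triu_indices(M.shape[0], k=1)
        return float(_cos_matrix(M, M)[iu].mean())

    def _between(A: np.ndarray, B: np.ndarray, metric: str) -> float:
        if A.shape[0] == 0 or B.shape[0] == 0:
            return math.nan
        if metric == "euclidean":
            return float(cdist(A, B, metric="euclidean").mean())
        return float(_cos_matrix(A, B).mean())

    return {
        metric: {
            "drug-drug": _within(D, metric),
            "drug-nondrug": _between(D, N, metric),
            "nondrug-nondrug": _within(N, metric),
        }
        for metric in ("euclidean", "cosine")
    }
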
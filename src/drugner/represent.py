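"""The three data representations and the multi-token labelling scheme.

Technique 1 slides a 5-token window over the whole corpus treated as one
token stream (windows may cross sentence boundaries).  Technique 2 slides
the window inside each sentence, right-padding with ``*`` so every token
position starts a window.  Both label a window with a class in 1..6:

    class 1      the window does not start a drug name
    class k>=2   the window's first k-1 tokens are exactly one reference
                 drug name (longest reference match wins)

Technique 3 keeps each sentence as a sequence: token i is encoded as the
concatenation ``[xv_i || xd_i]`` of its word vector and a distance block
relative to the previous token, with a binary per-token label (1 = inside
a drug mention).  The distance block is, by default, the elementwise
absolute difference ``|xv_i - xv_{i-1}|`` — a vector whose L2 norm is the
Euclidean distance between the two word vectors; a scalar-replicated
variant is available.  For the first token the block is all zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import (
    PAD,
    AnnotatedSentence,
    Corpus,
    SpanAlignmentError,
    normalize_token,
    resolve_entity_tokens,
    tokenize,
)
from .embed import WordVectorTable, euclidean_distance

logger = logging.getLogger(__name__)

WINDOW = 5  # tokens per window; also the maximum representable name length
N_CLASSES = 6


class RepresentationError(ValueError):
    pass


@dataclass(frozen=True)
class LabelledWindow:
    """A 5-token tuple, its class label and its (sentence, token) origin."""

    tokens: tuple[str, str, str, str, str]
    label: int
    origin: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.tokens) != WINDOW:
            raise RepresentationError(f"window needs {WINDOW} tokens")
        if not 1 <= self.label <= N_CLASSES:
            raise RepresentationError(f"label {self.label} outside 1..{N_CLASSES}")


@dataclass(frozen=True)
class SequenceSample:
    """Per-token encoded inputs (T, 2*dim) and binary labels for one sentence."""

    x: np.ndarray
    y: np.ndarray
    sentence_index: int
    tokens: tuple[str, ...]


class DrugReferenceList:
    """Normalized drug-name token sequences used by the labelling algorithm.

    Built from the annotations of a corpus (``drug`` and ``drug-n`` types
    only); names longer than the window are dropped with a warning since a
    5-token window cannot represent them.
    """

    def __init__(self, sequences: Iterable[Sequence[str]] = ()):
        self.sequences: set[tuple[str, ...]] = set()
        for seq in sequences:
            seq = tuple(seq)
            if not seq:
                raise RepresentationError("empty reference sequence")
            if len(seq) > WINDOW:
                logger.warning("dropping reference longer than %d tokens: %s", WINDOW, seq)
                continue
            self.sequences.add(seq)
        self.max_len = max((len(s) for s in self.sequences), default=0)

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "DrugReferenceList":
        return cls(
            tuple(normalize_token(t) for t in tokenize(name)) for name in names
        )

    @classmethod
    def from_corpus(cls, corpus: Corpus) -> "DrugReferenceList":
        seqs = []
        for sent in corpus:
            for ann in sent.drug_annotations():
                try:
                    rng = resolve_entity_tokens(sent, ann)
                except SpanAlignmentError as exc:
                    logger.warning("skipping unresolvable annotation: %s", exc)
                    continue
                seqs.append(
                    tuple(normalize_token(sent.tokens[i]) for i in rng)
                )
        return cls(seqs)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, seq: Sequence[str]) -> bool:
        return tuple(seq) in self.sequences


def label_window(tokens: Sequence[str], refs: DrugReferenceList) -> int:
    """Class 1..6 for a 5-token window: 1 + longest reference prefix match."""
    if len(tokens) != WINDOW:
        raise RepresentationError(f"window needs {WINDOW} tokens, got {len(tokens)}")
    norm = tuple(normalize_token(t) for t in tokens)
    best = 0
    for k in range(min(refs.max_len, WINDOW), 0, -1):
        if norm[:k] in refs:
            best = k
            break
    return 1 + best


def build_windows_all(corpus: Corpus, refs: DrugReferenceList) -> list[LabelledWindow]:
    """Technique 1: windows over the whole corpus as one token stream.

    A corpus of N tokens yields exactly N-4 windows; windows cross sentence
    boundaries.  ``origin`` is the (sentence, token) position of the
    window's first token.
    """
    stream: list[str] = []
    origins: list[tuple[int, int]] = []
    for si, sent in enumerate(corpus):
        stream.extend(sent.tokens)
        origins.extend((si, ti) for ti in range(len(sent.tokens)))
    n = len(stream)
    if n < WINDOW:
        raise RepresentationError(f"corpus has {n} tokens, need at least {WINDOW}")
    return [
        LabelledWindow(
            tokens=tuple(stream[i : i + WINDOW]),
            label=label_window(stream[i : i + WINDOW], refs),
            origin=origins[i],
        )
        for i in range(n - WINDOW + 1)
    ]


def build_windows_per_sentence(
    corpus: Corpus, refs: DrugReferenceList, pad: str = PAD
) -> list[LabelledWindow]:
    """Technique 2: one window per token position, right-padded with ``pad``.

    A sentence of n tokens yields n windows; no window crosses a sentence
    boundary.
    """
    out: list[LabelledWindow] = []
    for si, sent in enumerate(corpus):
        toks = list(sent.tokens)
        for ti in range(len(toks)):
            chunk = toks[ti : ti + WINDOW]
            chunk += [pad] * (WINDOW - len(chunk))
            out.append(
                LabelledWindow(
                    tokens=tuple(chunk),
                    label=label_window(chunk, refs),
                    origin=(si, ti),
                )
            )
    return out


def encode_windows(
    windows: Sequence[LabelledWindow], table: WordVectorTable
) -> tuple[np.ndarray, np.ndarray]:
    """Stack window encodings into (n, 5*dim) X and (n,) label vector y.

    Each window is the in-order concatenation of its 5 token vectors
    (dim 100 gives the 500-length input); padding and OOV contribute zeros.
    """
    dim = table.dim
    X = np.zeros((len(windows), WINDOW * dim))
    y = np.zeros(len(windows), dtype=np.int64)
    oov: set[str] = set()
    for i, w in enumerate(windows):
        for j, tok in enumerate(w.tokens):
            if tok != PAD and tok not in table:
                oov.add(tok)
            X[i, j * dim : (j + 1) * dim] = table.vector(tok)
        y[i] = w.label
    if oov:
        logger.warning("%d out-of-vocabulary tokens encoded as zeros", len(oov))
    return X, y


def sequence_token_labels(sentence: AnnotatedSentence) -> np.ndarray:
    """Binary label per token: 1 iff the token lies inside a drug mention."""
    y = np.zeros(len(sentence.tokens), dtype=np.int64)
    for ann in sentence.drug_annotations():
        try:
            rng = resolve_entity_tokens(sentence, ann)
        except SpanAlignmentError as exc:
            logger.warning("skipping unresolvable annotation: %s", exc)
            continue
        y[list(rng)] = 1
    return y


def build_sequence_dataset(
    corpus: Corpus,
    table: WordVectorTable,
    distance_block: str = "absdiff",
) -> list[SequenceSample]:
    """Technique 3: per-sentence sequences of [xv_i || xd_i] inputs.

    ``distance_block="absdiff"`` uses the elementwise absolute difference
    to the previous token's vector (its L2 norm equals the Euclidean
    distance); ``"scalar_replicated"`` fills the block with the scalar
    Euclidean distance itself.  The first token's block is all zeros.
    """
    if distance_block not in ("absdiff", "scalar_replicated"):
        raise RepresentationError(f"unknown distance_block {distance_block!r}")
    dim = table.dim
    samples: list[SequenceSample] = []
    for si, sent in enumerate(corpus):
        T = len(sent.tokens)
        if T == 0:
            continue
        xv = table.matrix(sent.tokens)
        xd = np.zeros_like(xv)
        if T > 1:
            if distance_block == "absdiff":
                xd[1:] = np.abs(xv[1:] - xv[:-1])
            else:
                dists = np.linalg.norm(xv[1:] - xv[:-1], axis=1)
                xd[1:] = dists[:, None]
        x = np.hstack([xv, xd])
        samples.append(
            SequenceSample(
                x=x,
                y=sequence_token_labels(sent),
                sentence_index=si,
                tokens=sent.tokens,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# serialization


def write_windows(windows: Sequence[LabelledWindow], path: str | Path) -> None:
    """Tab-separated file: 5 token columns + label (+ origin columns)."""
    lines = [
        "\t".join([*w.tokens, str(w.label), str(w.origin[0]), str(w.origin[1])])
        for w in windows
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_windows(path: str | Path) -> list[LabelledWindow]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.split("\t")
        out.append(
            LabelledWindow(
                tokens=tuple(parts[:WINDOW]),
                label=int(parts[WINDOW]),
                origin=(int(parts[WINDOW + 1]), int(parts[WINDOW + 2])),
            )
        )
    return out


def save_encoded(X: np.ndarray, y: np.ndarray, path: str | Path) -> None:
    """Dense matrix file plus a JSON sidecar recording the shapes."""
    import json

    path = Path(path)
    np.save(path.with_suffix(".npy"), np.hstack([X, y[:, None].astype(float)]))
    path.with_suffix(".json").write_text(
        json.dumps({"n": int(X.shape[0]), "width": int(X.shape[1])}),
        encoding="utf-8",
    )


def load_encoded(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    M = np.load(Path(path).with_suffix(".npy"))
    return M[:, :-1], M[:, -1].astype(np.int64)
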
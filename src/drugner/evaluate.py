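"""Entity decoding and entity-level precision / recall / F scoring.

Window predictions decode by the class semantics: a window at token i
predicted class k >= 2 asserts that tokens i .. i+k-2 form one drug name.
Overlapping assertions within a sentence are resolved by keeping the
higher-confidence one (ties: earlier start, then longer).  Sequence
predictions decode maximal runs of 1-labels into entities.

Scoring compares the extracted set C against the gold set K:

    P = |K n C| / |C|,   R = |K n C| / |K|,   F = 2PR / (P + R)

with exact matching on (sentence, token span, name) by default and a
name-only diagnostic mode.  Empty-set conventions: P := 0 when C is
empty, R := 0 when K is empty; if both are empty P = R = F = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus import (
    PAD,
    Corpus,
    SpanAlignmentError,
    normalize_token,
    resolve_entity_tokens,
)
from .represent import N_CLASSES, LabelledWindow, SequenceSample


class DecodeError(ValueError):
    pass


@dataclass(frozen=True)
class ExtractedEntity:
    """One extracted mention: sentence index, token span and surface name."""

    sentence: int
    start: int
    length: int
    name: str

    def overlaps(self, other: "ExtractedEntity") -> bool:
        return (
            self.sentence == other.sentence
            and self.start <= other.start + other.length - 1
            and other.start <= self.start + self.length - 1
        )


@dataclass
class EvalReport:
    precision: float
    recall: float
    f_score: float
    true_positives: int
    n_extracted: int
    n_gold: int
    matching: str = "exact"

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "true_positives": self.true_positives,
            "n_extracted": self.n_extracted,
            "n_gold": self.n_gold,
            "matching": self.matching,
        }


def gold_entities(corpus: Corpus, max_len: int | None = 5) -> set[ExtractedEntity]:
    """Annotated drug mentions as entities; names longer than the window
    limit are skipped when ``max_len`` is set (they are unrepresentable in
    the window techniques)."""
    out: set[ExtractedEntity] = set()
    for si, sent in enumerate(corpus):
        for ann in sent.drug_annotations():
            try:
                rng = resolve_entity_tokens(sent, ann)
            except SpanAlignmentError:
                continue
            if max_len is not None and len(rng) > max_len:
                continue
            name = " ".join(normalize_token(sent.tokens[i]) for i in rng)
            out.add(ExtractedEntity(si, rng.start, len(rng), name))
    return out


def _resolve_overlaps(
    candidates: list[tuple[float, ExtractedEntity]]
) -> set[ExtractedEntity]:
    kept: list[ExtractedEntity] = []
    # higher confidence first; ties earlier start, then longer span
    for _, ent in sorted(
        candidates, key=lambda ce: (-ce[0], ce[1].sentence, ce[1].start, -ce[1].length)
    ):
        if not any(ent.overlaps(k) for k in kept):
            kept.append(ent)
    return set(kept)


def decode_entities_from_windows(
    windows: Sequence[LabelledWindow],
    classes: Sequence[int],
    confidences: Sequence[float] | None = None,
    sentence_lengths: Mapping[int, int] | None = None,
) -> set[ExtractedEntity]:
    """Decode predicted window classes into an entity set.

    ``classes[i]`` is the predicted class of ``windows[i]``; a class k >= 2
    yields an entity covering the window's first k-1 tokens.  Entities
    containing padding, or running past the end of their sentence (possible
    when windows cross sentence boundaries), are discarded.
    """
    if confidences is None:
        confidences = [1.0] * len(windows)
    if len(classes) != len(windows) or len(confidences) != len(windows):
        raise DecodeError("classes/confidences do not align with windows")
    candidates: list[tuple[float, ExtractedEntity]] = []
    for w, k, conf in zip(windows, classes, confidences):
        k = int(k)
        if not 1 <= k <= N_CLASSES:
            raise DecodeError(f"class {k} outside 1..{N_CLASSES}")
        if k == 1:
            continue
        length = k - 1
        toks = w.tokens[:length]
        if PAD in toks:
            continue
        si, ti = w.origin
        if sentence_lengths is not None and ti + length > sentence_lengths[si]:
            continue  # crosses a sentence boundary
        name = " ".join(normalize_token(t) for t in toks)
        candidates.append((float(conf), ExtractedEntity(si, ti, length, name)))
    return _resolve_overlaps(candidates)


def decode_entities_from_sequence(
    samples: Sequence[SequenceSample],
    labels: Sequence[np.ndarray],
) -> set[ExtractedEntity]:
    """Maximal runs of consecutive 1-labels become single entities."""
    if len(labels) != len(samples):
        raise DecodeError("labels do not align with samples")
    out: set[ExtractedEntity] = set()
    for s, y in zip(samples, labels):
        y = np.asarray(y)
        if len(y) != len(s.tokens):
            raise DecodeError("label vector does not match sentence length")
        start = None
        for i, v in enumerate([*y, 0]):  # sentinel closes a trailing run
            if v == 1 and start is None:
                start = i
            elif v != 1 and start is not None:
                name = " ".join(
                    normalize_token(t) for t in s.tokens[start:i]
                )
                out.add(
                    ExtractedEntity(s.sentence_index, start, i - start, name)
                )
                start = None
    return out


def score(
    gold: set[ExtractedEntity],
    extracted: set[ExtractedEntity],
    matching: str = "exact",
) -> EvalReport:
    """Entity-level precision, recall and F over gold vs extracted sets."""
    if matching == "exact":
        K, C = gold, extracted
    elif matching == "name":
        K = {e.name for e in gold}
        C = {e.name for e in extracted}
    else:
        raise ValueError(f"unknown matching mode {matching!r}")
    tp = len(K & C)
    if not K and not C:
        p = r = f = 1.0
    else:
        p = tp / len(C) if C else 0.0
        r = tp / len(K) if K else 0.0
        f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return EvalReport(
        precision=p,
        recall=r,
        f_score=f,
        true_positives=tp,
        n_extracted=len(C),
        n_gold=len(K),
        matching=matching,
    )
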
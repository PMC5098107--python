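"""Offset-annotated corpus reading, writing and span/token alignment.

A corpus is a list of sentences; each sentence carries zero or more entity
annotations stored standoff-style as *inclusive* 0-based character spans
plus the entity surface name and its type (``drug``, ``drug-n``, ``brand``
or ``group``).  Only ``drug`` and ``drug-n`` are extraction targets; the
other two types are parsed and kept but ignored when building reference
lists and BIO tags.

Serialization dialect (tab-separated standoff, one blank-line-delimited
record per sentence)::

    modification of surface ... clostridium difficile toxin a
    79-107<TAB>clostridium difficile toxin a<TAB>drug

Tokenization is deliberately simple: lowercase + whitespace split, with
punctuation left attached to tokens ("performed.", "stimulants,").  Entity
name matching therefore strips trailing sentence punctuation from a token
before comparison.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

DRUG_TYPES = frozenset({"drug", "drug-n"})
ENTITY_TYPES = frozenset({"drug", "drug-n", "brand", "group"})

#: padding token used by the per-sentence window representation
PAD = "*"

_TOKEN_RE = re.compile(r"\S+")
_TRAILING_PUNCT = ".,;:!?"
_ANN_RE = re.compile(r"^(\d+)-(\d+)\t([^\t]+)\t([a-z-]+)$")


class CorpusFormatError(ValueError):
    """Malformed standoff record (bad span syntax, unknown type, ...)."""


class SpanValidationError(ValueError):
    """An annotation span does not reproduce the annotated name."""


class SpanAlignmentError(ValueError):
    """An annotation span does not align with token boundaries."""


def tokenize(text: str) -> list[str]:
    """Lowercase, whitespace-split tokenization with punctuation retained.

    >>> tokenize("Studies with PLENAXIS were performed.")
    ['studies', 'with', 'plenaxis', 'were', 'performed.']
    """
    return [m.group(0) for m in _TOKEN_RE.finditer(text.lower())]


def token_char_spans(text: str) -> list[tuple[int, int]]:
    """Inclusive character span of each whitespace token of ``text``."""
    return [(m.start(), m.end() - 1) for m in _TOKEN_RE.finditer(text)]


def normalize_token(token: str) -> str:
    """Strip trailing sentence punctuation unless that empties the token."""
    stripped = token.rstrip(_TRAILING_PUNCT)
    return stripped if stripped else token


@dataclass(frozen=True)
class EntityAnnotation:
    """One entity mention: inclusive character span + surface name + type."""

    start: int
    end: int
    name: str
    etype: str

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise CorpusFormatError(f"unknown entity type {self.etype!r}")
        if self.start < 0 or self.start > self.end:
            raise CorpusFormatError(
                f"invalid span {self.start}-{self.end} for {self.name!r}"
            )

    @property
    def is_drug(self) -> bool:
        return self.etype in DRUG_TYPES


@dataclass(frozen=True)
class AnnotatedSentence:
    """A sentence with its tokens, per-token char spans and annotations."""

    raw: str
    tokens: tuple[str, ...]
    token_spans: tuple[tuple[int, int], ...]
    annotations: tuple[EntityAnnotation, ...] = ()

    @classmethod
    def from_raw(
        cls, raw: str, annotations: Iterable[EntityAnnotation] = ()
    ) -> "AnnotatedSentence":
        sent = cls(
            raw=raw,
            tokens=tuple(tokenize(raw)),
            token_spans=tuple(token_char_spans(raw)),
            annotations=tuple(annotations),
        )
        sent.validate()
        return sent

    def validate(self) -> None:
        for ann in self.annotations:
            if ann.end >= len(self.raw):
                raise SpanValidationError(
                    f"span {ann.start}-{ann.end} out of range for sentence "
                    f"of length {len(self.raw)}"
                )
            sliced = self.raw[ann.start : ann.end + 1]
            if sliced.lower() != ann.name.lower():
                raise SpanValidationError(
                    f"span {ann.start}-{ann.end} slices to {sliced!r}, "
                    f"annotation says {ann.name!r}"
                )

    def drug_annotations(self) -> list[EntityAnnotation]:
        return [a for a in self.annotations if a.is_drug]


@dataclass
class Corpus:
    """An ordered collection of annotated sentences with a train/test role."""

    sentences: list[AnnotatedSentence] = field(default_factory=list)
    role: str = "train"

    def __iter__(self) -> Iterator[AnnotatedSentence]:
        return iter(self.sentences)

    def __len__(self) -> int:
        return len(self.sentences)

    def all_tokens(self) -> list[str]:
        out: list[str] = []
        for s in self.sentences:
            out.extend(s.tokens)
        return out

    def token_sentences(self) -> list[list[str]]:
        return [list(s.tokens) for s in self.sentences]


def resolve_entity_tokens(
    sentence: AnnotatedSentence, annotation: EntityAnnotation
) -> range:
    """Map an annotation's character span to a contiguous token index range.

    The first covered token must begin exactly at the span start; the last
    covered token may extend past the span end only by trailing punctuation
    (e.g. annotation "gallocatechins" inside token "gallocatechins,").
    The normalized tokens, space-joined, must equal the normalized name.
    """
    covered = [
        i
        for i, (ts, te) in enumerate(sentence.token_spans)
        if ts <= annotation.end and te >= annotation.start
    ]
    if not covered:
        raise SpanAlignmentError(f"span covers no token: {annotation}")
    first, last = covered[0], covered[-1]
    ts0, _ = sentence.token_spans[first]
    _, te1 = sentence.token_spans[last]
    if ts0 != annotation.start:
        raise SpanAlignmentError(
            f"span {annotation.start}-{annotation.end} starts mid-token "
            f"({sentence.tokens[first]!r})"
        )
    if te1 != annotation.end:
        excess = sentence.raw[annotation.end + 1 : te1 + 1]
        if not excess or any(c not in _TRAILING_PUNCT for c in excess):
            raise SpanAlignmentError(
                f"span {annotation.start}-{annotation.end} ends mid-token "
                f"({sentence.tokens[last]!r})"
            )
    joined = " ".join(
        normalize_token(t) for t in sentence.tokens[first : last + 1]
    )
    expected = " ".join(normalize_token(t) for t in tokenize(annotation.name))
    if joined != expected:
        raise SpanAlignmentError(
            f"resolved tokens {joined!r} != annotation name {expected!r}"
        )
    return range(first, last + 1)


# ---------------------------------------------------------------------------
# standoff serialization


def parse_corpus(path: str | Path, role: str = "train") -> Corpus:
    """Read a tab-separated standoff corpus file.

    Raises :class:`CorpusFormatError` (naming the offending line) on bad
    span syntax and :class:`SpanValidationError` when a span does not slice
    to its stated name.
    """
    text = Path(path).read_text(encoding="utf-8")
    corpus = Corpus(role=role)
    block: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.split("\n"), start=1):
        if line.strip() == "":
            if block:
                corpus.sentences.append(_parse_block(block))
                block = []
        else:
            block.append((lineno, line))
    if block:
        corpus.sentences.append(_parse_block(block))
    return corpus


def _parse_block(block: list[tuple[int, str]]) -> AnnotatedSentence:
    lineno, raw = block[0]
    if "\t" in raw:
        raise CorpusFormatError(f"line {lineno}: sentence text contains a tab")
    annotations = []
    for lineno, line in block[1:]:
        m = _ANN_RE.match(line)
        if m is None:
            raise CorpusFormatError(f"line {lineno}: malformed annotation {line!r}")
        start, end, name, etype = int(m[1]), int(m[2]), m[3], m[4]
        if start > end:
            raise CorpusFormatError(f"line {lineno}: start {start} > end {end}")
        if end >= len(raw):
            raise CorpusFormatError(
                f"line {lineno}: span {start}-{end} out of range "
                f"(sentence length {len(raw)})"
            )
        if etype not in ENTITY_TYPES:
            raise CorpusFormatError(f"line {lineno}: unknown type {etype!r}")
        annotations.append(EntityAnnotation(start, end, name, etype))
    try:
        return AnnotatedSentence.from_raw(raw, annotations)
    except SpanValidationError as exc:
        raise SpanValidationError(f"record at line {lineno}: {exc}") from exc


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the standoff dialect read by :func:`parse_corpus`."""
    lines: list[str] = []
    for sent in corpus:
        lines.append(sent.raw)
        for a in sent.annotations:
            lines.append(f"{a.start}-{a.end}\t{a.name}\t{a.etype}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# CoNLL-style BIO export


def sentence_bio_tags(sentence: AnnotatedSentence) -> list[str]:
    """B-DRUG/I-DRUG/O tags for one sentence (drug and drug-n only)."""
    tags = ["O"] * len(sentence.tokens)
    for ann in sentence.drug_annotations():
        try:
            rng = resolve_entity_tokens(sentence, ann)
        except SpanAlignmentError as exc:
            logger.warning("skipping unresolvable annotation: %s", exc)
            continue
        for j, i in enumerate(rng):
            tags[i] = "B-DRUG" if j == 0 else "I-DRUG"
    return tags


def write_bio(corpus: Corpus, path: str | Path) -> None:
    """One ``token<TAB>tag`` line per token, blank line between sentences."""
    lines: list[str] = []
    for sent in corpus:
        for token, tag in zip(sent.tokens, sentence_bio_tags(sent)):
            lines.append(f"{token}\t{tag}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_bio(path: str | Path) -> list[tuple[list[str], list[str]]]:
    """Read a BIO file back into (tokens, tags) pairs; round-trips write_bio."""
    out: list[tuple[list[str], list[str]]] = []
    tokens: list[str] = []
    tags: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").split("\n"):
        if line.strip() == "":
            if tokens:
                out.append((tokens, tags))
                tokens, tags = [], []
            continue
        tok, tag = line.split("\t")
        tokens.append(tok)
        tags.append(tag)
    if tokens:
        out.append((tokens, tags))
    return out
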
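"""Synthetic annotated-corpus generator.

Emulates the statistical structure that the extraction method exploits in
real pharmacological text, without any linguistic realism:

* background tokens follow a head-dominated (Zipf-like) frequency law, so a
  small number of token types carries most of the corpus mass;
* drug names are 1-5 token strings drawn from a rare token alphabet that is
  disjoint from the background vocabulary (so drug tokens always fall in
  the low-cumulative-frequency part of the ranked distribution);
* drug tokens make up well under 10% of all token occurrences;
* mentions sit inside stereotyped local frames drawn from a small
  medical-context vocabulary (the way real drug mentions share contexts
  such as "administration of X" or "dose of X mg"), which is what makes
  trained embeddings place drug tokens closer to each other than to
  background tokens;
* most sentences carry a mention, as in drug-label text, where nearly
  every sentence names a drug;
* every mention carries an exact inclusive character span.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import AnnotatedSentence, Corpus, EntityAnnotation


class SynthConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the package's study conditions."""

    vocab_size: int = 2000
    n_sentences: int = 1000
    n_test_sentences: int = 250
    sentence_len: tuple[int, int] = (8, 20)
    zipf_exponent: float = 1.1
    drug_lexicon_size: int = 150
    n_drug_names: int = 40
    drug_len_dist: tuple[float, ...] = (0.82, 0.08, 0.05, 0.03, 0.02)
    drug_insertion_rate: float = 0.8
    drug_n_fraction: float = 0.2
    context_vocab_size: int = 12
    context_halo: int = 3
    context_affinity: float = 0.9
    context_background_rate: float = 0.02
    ambiguity_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.drug_lexicon_size >= self.vocab_size:
            raise SynthConfigError("drug lexicon must be smaller than the vocabulary")
        if min(self.vocab_size, self.n_sentences, self.drug_lexicon_size) <= 0:
            raise SynthConfigError("all counts must be positive")
        if not np.isclose(sum(self.drug_len_dist), 1.0):
            raise SynthConfigError("drug_len_dist must sum to 1")
        if len(self.drug_len_dist) > 5:
            raise SynthConfigError("drug names are limited to 5 tokens")
        lo, hi = self.sentence_len
        if lo < 1 or hi < lo:
            raise SynthConfigError("invalid sentence length range")
        if not 0.0 <= self.drug_insertion_rate <= 1.0:
            raise SynthConfigError("drug_insertion_rate must be in [0, 1]")


def _background_vocab(cfg: SynthConfig) -> list[str]:
    n = cfg.vocab_size - cfg.drug_lexicon_size
    return [f"w{i:04d}" for i in range(n)]


def _drug_alphabet(cfg: SynthConfig) -> list[str]:
    return [f"zq{i:03d}x" for i in range(cfg.drug_lexicon_size)]


def _zipf_probs(n: int, s: float) -> np.ndarray:
    p = np.arange(1, n + 1, dtype=float) ** (-s)
    return p / p.sum()


def _draw_name_inventory(cfg: SynthConfig, rng: np.random.Generator) -> list[tuple[str, ...]]:
    """Prefix-free inventory of multi-token drug names over the rare alphabet."""
    alphabet = _drug_alphabet(cfg)
    lengths = 1 + rng.choice(
        len(cfg.drug_len_dist), size=cfg.n_drug_names, p=np.asarray(cfg.drug_len_dist)
    )
    names: list[tuple[str, ...]] = []
    for k in lengths:
        for _ in range(1000):
            cand = tuple(alphabet[i] for i in rng.choice(len(alphabet), size=k, replace=False))
            if not any(
                cand[: len(n)] == n or n[: len(cand)] == cand for n in names
            ):
                names.append(cand)
                break
        else:  # pragma: no cover - only reachable with a degenerate config
            raise SynthConfigError("could not draw a prefix-free name inventory")
    return names


def _context_vocab(cfg: SynthConfig) -> list[str]:
    return [f"cx{i:03d}" for i in range(cfg.context_vocab_size)]


def _make_sentence(
    cfg: SynthConfig,
    rng: np.random.Generator,
    background: list[str],
    bg_probs: np.ndarray,
    names: Sequence[tuple[str, ...]],
    context: Sequence[str],
) -> AnnotatedSentence:
    lo, hi = cfg.sentence_len
    length = int(rng.integers(lo, hi + 1))
    tokens = [background[i] for i in rng.choice(len(background), size=length, p=bg_probs)]
    # context words also occur, sparsely, away from any mention
    for j in range(length):
        if rng.random() < cfg.context_background_rate:
            tokens[j] = context[int(rng.integers(len(context)))]
    annotations: list[EntityAnnotation] = []

    mention: tuple[str, ...] | None = None
    if rng.random() < cfg.drug_insertion_rate:
        mention = names[int(rng.integers(len(names)))]
        pos = int(rng.integers(0, length + 1))
        # stereotyped frame: up to `halo` context tokens on each side
        for d in range(1, cfg.context_halo + 1):
            if pos - d >= 0 and rng.random() < cfg.context_affinity:
                tokens[pos - d] = context[int(rng.integers(len(context)))]
            if pos + d - 1 < length and rng.random() < cfg.context_affinity:
                tokens[pos + d - 1] = context[int(rng.integers(len(context)))]
        tokens[pos:pos] = list(mention)

    if cfg.ambiguity_rate > 0 and rng.random() < cfg.ambiguity_rate:
        # a drug-alphabet token occurring as an unannotated common word
        j = int(rng.integers(len(tokens)))
        if mention is None or tokens[j] not in mention:
            tokens[j] = _drug_alphabet(cfg)[int(rng.integers(cfg.drug_lexicon_size))]

    raw = " ".join(tokens)
    if mention is not None:
        # locate the mention's char span from its token position
        pos = _find_subsequence(tokens, mention)
        start = sum(len(t) + 1 for t in tokens[:pos])
        name = " ".join(mention)
        etype = "drug-n" if rng.random() < cfg.drug_n_fraction else "drug"
        annotations.append(
            EntityAnnotation(start, start + len(name) - 1, name, etype)
        )
    return AnnotatedSentence.from_raw(raw, annotations)


def _find_subsequence(tokens: Sequence[str], sub: Sequence[str]) -> int:
    k = len(sub)
    for i in range(len(tokens) - k + 1):
        if tuple(tokens[i : i + k]) == tuple(sub):
            return i
    raise RuntimeError("inserted mention not found")  # pragma: no cover


def generate_corpus(cfg: SynthConfig | None = None) -> tuple[Corpus, Corpus]:
    """Generate a (train, test) corpus pair sharing one drug-name inventory.

    Deterministic given ``cfg.seed``: the same config yields byte-identical
    corpora when serialized.
    """
    cfg = cfg or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    background = _background_vocab(cfg)
    bg_probs = _zipf_probs(len(background), cfg.zipf_exponent)
    names = _draw_name_inventory(cfg, rng)
    context = _context_vocab(cfg)

    def make(n: int, role: str) -> Corpus:
        return Corpus(
            sentences=[
                _make_sentence(cfg, rng, background, bg_probs, names, context)
                for _ in range(n)
            ],
            role=role,
        )

    return make(cfg.n_sentences, "train"), make(cfg.n_test_sentences, "test")
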
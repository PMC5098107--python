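"""Shared fixtures: a hand-built mini-corpus of pharmacology sentences with
known offsets, and session-scoped synthetic-corpus artifacts reused by the
slower recovery experiments."""

import numpy as np
import pytest
from hypothesis import settings

from drugner import (
    AnnotatedSentence,
    Corpus,
    EntityAnnotation,
    SynthConfig,
    generate_corpus,
    train_embeddings,
)

settings.register_profile("suite", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("suite")


# three DrugBank-style sentences with character-exact drug spans
S1 = (
    "modification of surface histidine residues abolishes the cytotoxic "
    "activity of clostridium difficile toxin a"
)
S2 = (
    "antimicrobial activity of ganoderma lucidum extract alone and in "
    "combination with some antibiotics."
)
S3 = (
    "on the other hand, surprisingly, green tea gallocatechins, "
    "(−)-epigallocatechin-3-o-gallate and theasinensin a, potently "
    "enhanced the promoter activity (182 and 247% activity at 1 microm, "
    "resp.)."
)

MINI_ROWS = [
    (S1, 79, 107, "clostridium difficile toxin a", "drug-n"),
    (S2, 26, 50, "ganoderma lucidum extract", "drug"),
    (S3, 33, 56, "green tea gallocatechins", "drug"),
]


@pytest.fixture
def mini_corpus() -> Corpus:
    sentences = [
        AnnotatedSentence.from_raw(raw, [EntityAnnotation(s, e, name, etype)])
        for raw, s, e, name, etype in MINI_ROWS
    ]
    return Corpus(sentences=sentences, role="train")


@pytest.fixture(scope="session")
def synth_pair():
    return generate_corpus(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def synth_table(synth_pair):
    train, test = synth_pair
    return train_embeddings([train, test], seed=7)
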
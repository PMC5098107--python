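import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drugner.corpus import AnnotatedSentence, Corpus, EntityAnnotation, PAD
from drugner.evaluate import (
    DecodeError,
    ExtractedEntity,
    decode_entities_from_sequence,
    decode_entities_from_windows,
    gold_entities,
    score,
)
from drugner.represent import (
    DrugReferenceList,
    LabelledWindow,
    SequenceSample,
    build_sequence_dataset,
    build_windows_per_sentence,
)


def _window(tokens, origin=(0, 0)):
    return LabelledWindow(tuple(tokens), 1, origin)


def test_window_class_semantics():
    w = _window(("clostridium", "difficile", "toxin", "a", "antimicrobial"), (3, 7))
    (e,) = decode_entities_from_windows([w], [5])
    assert e == ExtractedEntity(3, 7, 4, "clostridium difficile toxin a")


def test_all_class_one_yields_empty_set():
    ws = [_window(("a", "b", "c", "d", "e"), (0, i)) for i in range(4)]
    assert decode_entities_from_windows(ws, [1, 1, 1, 1]) == set()


def test_overlap_resolved_by_confidence():
    w1 = _window(("a", "b", "c", "d", "e"), (0, 0))
    w2 = _window(("b", "c", "d", "e", "f"), (0, 1))
    out = decode_entities_from_windows([w1, w2], [3, 2], [0.9, 0.6])
    assert out == {ExtractedEntity(0, 0, 2, "a b")}
    out2 = decode_entities_from_windows([w1, w2], [3, 2], [0.6, 0.9])
    assert out2 == {ExtractedEntity(0, 1, 1, "b")}


def test_overlap_tie_prefers_earlier_then_longer():
    w1 = _window(("a", "b", "c", "d", "e"), (0, 0))
    w2 = _window(("b", "c", "d", "e", "f"), (0, 1))
    out = decode_entities_from_windows([w1, w2], [3, 2], [0.5, 0.5])
    assert out == {ExtractedEntity(0, 0, 2, "a b")}
    # same start, equal confidence: the longer span wins
    out2 = decode_entities_from_windows([w1, w1], [2, 3], [0.5, 0.5])
    assert out2 == {ExtractedEntity(0, 0, 2, "a b")}


def test_padding_and_boundary_windows_discarded():
    padded = _window(("x", PAD, PAD, PAD, PAD), (0, 4))
    assert decode_entities_from_windows([padded], [3]) == set()
    crossing = _window(("x", "y", "z", "q", "r"), (0, 4))
    assert (
        decode_entities_from_windows([crossing], [3], sentence_lengths={0: 5})
        == set()
    )


def test_invalid_class_rejected():
    w = _window(("a", "b", "c", "d", "e"))
    with pytest.raises(DecodeError):
        decode_entities_from_windows([w], [7])


def _seq_sample(tokens, idx=0):
    return SequenceSample(
        x=np.zeros((len(tokens), 2)),
        y=np.zeros(len(tokens), dtype=int),
        sentence_index=idx,
        tokens=tuple(tokens),
    )


def test_sequence_decode_runs():
    s1 = _seq_sample("drug interaction studies with plenaxis were performed".split(), 0)
    s2 = _seq_sample("cytochrome p-450 is not known in the".split(), 1)
    out = decode_entities_from_sequence(
        [s1, s2],
        [np.array([0, 0, 0, 0, 1, 0, 0]), np.array([1, 1, 0, 0, 0, 0, 0])],
    )
    assert out == {
        ExtractedEntity(0, 4, 1, "plenaxis"),
        ExtractedEntity(1, 0, 2, "cytochrome p-450"),
    }


def test_sequence_decode_trailing_run_and_empty():
    s = _seq_sample(list("abcd"), 0)
    out = decode_entities_from_sequence([s], [np.array([0, 1, 1, 1])])
    assert out == {ExtractedEntity(0, 1, 3, "b c d")}
    assert decode_entities_from_sequence([s], [np.zeros(4, dtype=int)]) == set()


# ---------------------------------------------------------------------------
# scoring


def _ents(n, offset=0):
    return {ExtractedEntity(0, offset + 2 * i, 1, f"d{offset + i}") for i in range(n)}


def test_perfect_match():
    K = _ents(3)
    rep = score(K, set(K))
    assert rep.precision == rep.recall == rep.f_score == 1.0


def test_half_right():
    K = _ents(2)
    C = {next(iter(K)), ExtractedEntity(5, 0, 1, "spurious")}
    rep = score(K, C)
    assert rep.precision == 0.5 and rep.recall == 0.5 and rep.f_score == 0.5


def test_empty_set_conventions():
    K = _ents(2)
    rep = score(K, set())
    assert (rep.precision, rep.recall, rep.f_score) == (0.0, 0.0, 0.0)
    rep2 = score(set(), K)
    assert (rep2.precision, rep2.recall, rep2.f_score) == (0.0, 0.0, 0.0)
    rep3 = score(set(), set())
    assert (rep3.precision, rep3.recall, rep3.f_score) == (1.0, 1.0, 1.0)


def test_name_only_matching_mode():
    K = {ExtractedEntity(0, 0, 1, "dilantin")}
    C = {ExtractedEntity(3, 9, 1, "dilantin")}
    assert score(K, C).f_score == 0.0
    assert score(K, C, matching="name").f_score == 1.0


@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
def test_score_bounds_on_random_confusion_counts(tp, fp, fn):
    K = {ExtractedEntity(0, i, 1, f"k{i}") for i in range(tp + fn)}
    C = {ExtractedEntity(0, i, 1, f"k{i}") for i in range(tp)} | {
        ExtractedEntity(1, i, 1, f"c{i}") for i in range(fp)
    }
    rep = score(K, C)
    assert 0.0 <= rep.precision <= 1.0
    assert 0.0 <= rep.recall <= 1.0
    assert 0.0 <= rep.f_score <= 1.0
    if rep.precision > 0 and rep.recall > 0:
        # harmonic mean lies between min and max of P and R
        assert min(rep.precision, rep.recall) <= rep.f_score <= max(
            rep.precision, rep.recall
        )
        assert rep.f_score == pytest.approx(
            2 * rep.precision * rep.recall / (rep.precision + rep.recall)
        )


# ---------------------------------------------------------------------------
# gold-label round trips


def test_gold_window_round_trip_on_mini_corpus(mini_corpus):
    refs = DrugReferenceList.from_corpus(mini_corpus)
    windows = build_windows_per_sentence(mini_corpus, refs)
    extracted = decode_entities_from_windows(
        windows,
        [w.label for w in windows],
        sentence_lengths={i: len(s.tokens) for i, s in enumerate(mini_corpus)},
    )
    rep = score(gold_entities(mini_corpus), extracted)
    assert rep.precision == rep.recall == rep.f_score == 1.0


def test_gold_sequence_round_trip_on_mini_corpus(mini_corpus):
    from drugner.embed import WordVectorTable

    vocab = {t for s in mini_corpus for t in s.tokens}
    rng = np.random.default_rng(0)
    table = WordVectorTable({t: rng.normal(size=4) for t in vocab}, dim=4)
    samples = build_sequence_dataset(mini_corpus, table)
    extracted = decode_entities_from_sequence(samples, [s.y for s in samples])
    rep = score(gold_entities(mini_corpus, max_len=None), extracted)
    assert rep.precision == rep.recall == rep.f_score == 1.0
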
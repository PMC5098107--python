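import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drugner.corpus import PAD, AnnotatedSentence, Corpus, EntityAnnotation
from drugner.embed import WordVectorTable, euclidean_distance
from drugner.represent import (
    DrugReferenceList,
    LabelledWindow,
    RepresentationError,
    build_sequence_dataset,
    build_windows_all,
    build_windows_per_sentence,
    encode_windows,
    label_window,
    read_windows,
    write_windows,
)

MINI_REFS = DrugReferenceList.from_names(
    [
        "clostridium difficile toxin a",
        "ganoderma lucidum extract",
        "green tea gallocatechins",
    ]
)


def _brute_force_label(tokens, refs):
    """Oracle: try every reference as a prefix, longest match wins."""
    norm = tuple(t.rstrip(".,;:!?") or t for t in tokens)
    best = 0
    for seq in refs.sequences:
        if norm[: len(seq)] == seq:
            best = max(best, len(seq))
    return 1 + best


@pytest.mark.parametrize(
    "tokens, refs, expected",
    [
        # a 4-token name followed by the next sentence's first token
        (("clostridium", "difficile", "toxin", "a", "antimicrobial"), MINI_REFS, 5),
        # suffix of a name does not start a drug
        (("difficile", "toxin", "a", "*", "*"), MINI_REFS, 1),
        (
            ("plenaxis", "were", "performed", "cytochrome", "p-450"),
            DrugReferenceList.from_names(["plenaxis"]),
            2,
        ),
        (
            ("casein", "phosphopeptide-amorphous", "calcium", "phosphate", "complex"),
            DrugReferenceList.from_names(
                ["casein phosphopeptide-amorphous calcium phosphate complex"]
            ),
            6,
        ),
        (("anything", "at", "all", "x", "y"), DrugReferenceList(), 1),
    ],
)
def test_label_window_examples(tokens, refs, expected):
    assert label_window(tokens, refs) == expected


def test_label_window_longest_match_wins():
    refs = DrugReferenceList.from_names(["sodium", "sodium polystyrene sulfonate"])
    assert label_window(("sodium", "polystyrene", "sulfonate", "x", "y"), refs) == 4
    assert label_window(("sodium", "chloride", "x", "y", "z"), refs) == 2


def test_label_window_wrong_arity():
    with pytest.raises(RepresentationError):
        label_window(("a", "b", "c"), DrugReferenceList())


@given(
    st.lists(
        st.tuples(
            st.integers(0, 14),
            st.integers(0, 14),
            st.integers(0, 14),
            st.integers(0, 14),
            st.integers(0, 14),
        ),
        min_size=1,
        max_size=40,
    ),
    st.lists(
        st.lists(st.integers(0, 14), min_size=1, max_size=5),
        max_size=8,
    ),
)
def test_label_window_matches_bruteforce(windows, ref_lists):
    refs = DrugReferenceList([tuple(f"t{i}" for i in seq) for seq in ref_lists])
    for w in windows:
        tokens = tuple(f"t{i}" for i in w)
        assert label_window(tokens, refs) == _brute_force_label(tokens, refs)


def test_reference_list_drops_overlong_names(caplog):
    with caplog.at_level(logging.WARNING):
        refs = DrugReferenceList([("a",), ("b", "c", "d", "e", "f", "g")])
    assert ("a",) in refs
    assert len(refs) == 1


# ---------------------------------------------------------------------------
# window builders


def test_windows_all_counts_and_boundary_crossing(mini_corpus):
    windows = build_windows_all(mini_corpus, MINI_REFS)
    n_tokens = len(mini_corpus.all_tokens())
    assert len(windows) == n_tokens - 4
    assert windows[0].tokens == ("modification", "of", "surface", "histidine", "residues")
    assert windows[1].tokens == ("of", "surface", "histidine", "residues", "abolishes")
    # the window that starts the 4-token name picks up the next sentence's
    # first token and is labelled class 5
    crossing = windows[10]
    assert crossing.tokens == ("clostridium", "difficile", "toxin", "a", "antimicrobial")
    assert crossing.label == 5
    assert windows[11].label == 1


def test_windows_all_requires_five_tokens():
    tiny = Corpus([AnnotatedSentence.from_raw("just three tokens")])
    with pytest.raises(RepresentationError):
        build_windows_all(tiny, DrugReferenceList())


def test_windows_all_exactly_five_tokens():
    c = Corpus([AnnotatedSentence.from_raw("one two three four five")])
    assert len(build_windows_all(c, DrugReferenceList())) == 1


def test_windows_per_sentence_padding_and_counts(mini_corpus):
    windows = build_windows_per_sentence(mini_corpus, MINI_REFS)
    lengths = [len(s.tokens) for s in mini_corpus]
    assert len(windows) == sum(lengths)
    first = windows[: lengths[0]]
    # the sentence-final windows are right-padded and labelled by prefix match
    assert first[10].tokens == ("clostridium", "difficile", "toxin", "a", PAD)
    assert first[10].label == 5
    assert first[11].tokens == ("difficile", "toxin", "a", PAD, PAD)
    assert first[11].label == 1
    assert first[13].tokens == ("a", PAD, PAD, PAD, PAD)
    # no window crosses a sentence boundary
    assert all(w.origin[0] == 0 for w in first)


def test_single_token_sentence_window():
    c = Corpus([AnnotatedSentence.from_raw("alone")])
    (w,) = build_windows_per_sentence(c, DrugReferenceList())
    assert w.tokens == ("alone", PAD, PAD, PAD, PAD)


@given(st.lists(st.integers(1, 9), min_size=1, max_size=6))
def test_window_count_arithmetic(lengths):
    sentences = [
        AnnotatedSentence.from_raw(" ".join(f"w{i}x{j}" for j in range(n)))
        for i, n in enumerate(lengths)
    ]
    c = Corpus(sentences)
    refs = DrugReferenceList()
    assert len(build_windows_per_sentence(c, refs)) == sum(lengths)
    if sum(lengths) >= 5:
        assert len(build_windows_all(c, refs)) == sum(lengths) - 4


# ---------------------------------------------------------------------------
# encodings


def _toy_table():
    rng = np.random.default_rng(2)
    return WordVectorTable(
        {f"tok{i}": rng.normal(size=4) for i in range(10)}, dim=4
    )


def test_encode_concatenates_in_order():
    table = _toy_table()
    w = LabelledWindow(("tok1", "tok3", "tok5", "tok7", "tok9"), 1, (0, 0))
    X, y = encode_windows([w], table)
    assert X.shape == (1, 20)
    for j, tok in enumerate(w.tokens):
        assert np.allclose(X[0, j * 4 : (j + 1) * 4], table.vector(tok))


def test_encode_all_padding_is_zero():
    table = _toy_table()
    w = LabelledWindow((PAD, PAD, PAD, PAD, PAD), 1, (0, 0))
    X, _ = encode_windows([w], table)
    assert not X.any()


def test_sequence_dataset_labels_and_distance_block(mini_corpus, caplog):
    s1 = AnnotatedSentence.from_raw(
        "drug interaction studies with plenaxis were performed",
        [EntityAnnotation(30, 37, "plenaxis", "drug")],
    )
    s2 = AnnotatedSentence.from_raw(
        "cytochrome p-450 is not known in the",
        [EntityAnnotation(0, 15, "cytochrome p-450", "drug")],
    )
    rng = np.random.default_rng(0)
    vocab = {t for s in (s1, s2) for t in s.tokens}
    table = WordVectorTable({t: rng.normal(size=6) for t in vocab}, dim=6)
    samples = build_sequence_dataset(Corpus([s1, s2]), table)
    assert list(samples[0].y) == [0, 0, 0, 0, 1, 0, 0]
    assert list(samples[1].y) == [1, 1, 0, 0, 0, 0, 0]
    for s in samples:
        xv, xd = s.x[:, :6], s.x[:, 6:]
        assert not xd[0].any()
        for i in range(1, len(s.tokens)):
            assert np.linalg.norm(xd[i]) == pytest.approx(
                euclidean_distance(xv[i], xv[i - 1])
            )


def test_sequence_scalar_replicated_block():
    sent = AnnotatedSentence.from_raw("aa bb cc")
    rng = np.random.default_rng(1)
    table = WordVectorTable({t: rng.normal(size=3) for t in ("aa", "bb", "cc")}, dim=3)
    (s,) = build_sequence_dataset(
        Corpus([sent]), table, distance_block="scalar_replicated"
    )
    xv, xd = s.x[:, :3], s.x[:, 3:]
    for i in range(1, 3):
        d = euclidean_distance(xv[i], xv[i - 1])
        assert np.allclose(xd[i], d)


def test_identical_vectors_give_zero_distance_block():
    sent = AnnotatedSentence.from_raw("aa aa aa")
    table = WordVectorTable({"aa": np.array([1.0, 2.0])}, dim=2)
    (s,) = build_sequence_dataset(Corpus([sent]), table)
    assert not s.x[:, 2:].any()


def test_window_tsv_round_trip(tmp_path, mini_corpus):
    windows = build_windows_per_sentence(mini_corpus, MINI_REFS)
    path = tmp_path / "w.tsv"
    write_windows(windows, path)
    assert read_windows(path) == windows
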
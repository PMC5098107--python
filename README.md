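# drugner

Drug-name entity extraction from medical text, for text-mining researchers
and practitioners who need to pull drug mentions — including multi-token
names like *clostridium difficile toxin a* — out of sentences **without any
external dictionary, ontology, or handcrafted features**. Everything the
extractor uses is derived from the corpus itself: word-embedding geometry
and token-frequency structure.

## The method

Two routes from an annotated corpus to extracted entities:

**Window classification.** Sentences are cut into 5-token windows
(*t₁…t₅*), either sliding over the whole corpus as one stream or
per-sentence with `*` padding. Each window gets a class in {1…6}:

```
class 1        t₁ does not start a drug name
class k ≥ 2    (t₁ … t_{k−1}) is exactly one reference drug name
```

so the class directly encodes how many tokens the mention spans. Windows
are encoded by concatenating the five 100-dimensional CBOW word vectors
(500 inputs) and classified by an MLP (two sigmoid hidden layers of 100,
softmax output) trained on the cost

    J(W, b) = (1/m) Σᵢ ½‖h(xᵢ) − yᵢ‖² + (λ/2) Σ W²

where λ ∈ {0, 1, λ*}: λ* is computed from the embedding geometry as

    λ* = (1 / (n(n−1))) Σ_{i<j} dist(xᵢ, xⱼ)

the pairwise Euclidean distance statistic over word vectors. Before
classification, *candidate selection* can drop noise windows: rank the
training vocabulary by frequency, split it into three blocks of
near-equal cumulative frequency, and keep only windows whose first token
falls in the lower two blocks (drug tokens are rare, so none are lost);
or k-means the encoded windows and keep the low-frequency clusters.

**Sequence tagging.** Each sentence is a sequence of per-token inputs
`xᵢ = [xvᵢ ‖ xdᵢ]` — the token's word vector concatenated with a distance
block relative to the previous token (‖xdᵢ‖₂ equals the Euclidean distance
between consecutive word vectors; xd₁ = 0) — tagged 1/0 (drug/non-drug)
by a two-layer LSTM with peephole connections and coupled input/forget
gates. Runs of 1-tags decode into entities.

Both routes are scored entity-level against the gold annotations:

    P = |K ∩ C| / |C|,  R = |K ∩ C| / |K|,  F = 2PR / (P + R)

with exact (sentence, span, name) matching.

A synthetic-corpus generator ships with the package: Zipf-distributed
background text, a rare-token drug lexicon with 1–5-token names, exact
character-span annotations, and stereotyped local contexts around
mentions — so the entire chain is testable without any corpus download.

## Worked example

Generate the default synthetic corpus (1,000 train / 250 test sentences),
train embeddings on the pooled sentences, and run both extraction routes:

```python
from drugner import (
    SynthConfig, generate_corpus, train_embeddings, DrugReferenceList,
    build_windows_per_sentence, build_sequence_dataset, encode_windows,
    WindowMLPClassifier, LSTMTagger, decode_entities_from_windows,
    decode_entities_from_sequence, gold_entities, score,
)

train, test = generate_corpus(SynthConfig(seed=7))
table = train_embeddings([train, test], seed=7)

refs_train = DrugReferenceList.from_corpus(train)
refs_test = DrugReferenceList.from_corpus(test)
w_train = build_windows_per_sentence(train, refs_train)
w_test = build_windows_per_sentence(test, refs_test)
X_train, y_train = encode_windows(w_train, table)
X_test, _ = encode_windows(w_test, table)
clf = WindowMLPClassifier(learning_rate=0.3, seed=7).fit(X_train, y_train)
proba = clf.predict_proba(X_test)
extracted = decode_entities_from_windows(
    w_test, clf.classes_[proba.argmax(axis=1)], proba.max(axis=1),
    sentence_lengths={i: len(s.tokens) for i, s in enumerate(test)},
)
rep = score(gold_entities(test), extracted)
print(f"window MLP   P={rep.precision:.4f} R={rep.recall:.4f} F={rep.f_score:.4f}")

seq_train = build_sequence_dataset(train, table)
seq_test = build_sequence_dataset(test, table)
tagger = LSTMTagger(learning_rate=0.01, seed=7).fit(seq_train)
extracted = decode_entities_from_sequence(
    seq_test, [tagger.predict(s) for s in seq_test]
)
rep = score(gold_entities(test, max_len=None), extracted)
print(f"sequence LSTM P={rep.precision:.4f} R={rep.recall:.4f} F={rep.f_score:.4f}")
```

Output:

```
window MLP   P=0.9641 R=0.9126 F=0.9377
sequence LSTM P=0.9617 R=0.9757 F=0.9687
```

The numbers are held-out entity-level precision/recall/F on the synthetic
test corpus: the window route recovers ~94% of planted mentions exactly
(span and name), and the sequence route — which sees every token rather
than one shot per window — does slightly better, the same ordering the
method shows on real corpora. The `drugner` command exposes each stage
(`synth`, `embed`, `represent`, `select`, `evaluate`, `run`) for shell
pipelines; see `drugner --help`.

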
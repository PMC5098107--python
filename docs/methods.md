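# Methods

This note records the model, the parameter choices, the numerical
decisions, and what the synthetic experiments do and do not demonstrate.

## Problem and representations

The task is recognizing drug name mentions — one to five tokens — in
sentences, with no dictionary, ontology, or handcrafted features. Drug
mentions have two exploitable statistical signatures: their tokens are
rare (they sit in the low-cumulative-frequency part of the ranked
vocabulary), and their trained word vectors are mutually closer than they
are to ordinary words, because drug mentions occur in shared local
contexts.

Three data representations feed two classifier families:

1. **All-sentence windows.** The corpus is one token stream; every
   position starts a 5-token window, so N tokens yield N−4 windows and
   windows cross sentence boundaries. The window length 5 matches the
   longest representable mention.
2. **Per-sentence windows.** Each sentence is a stream of its own; every
   token position starts a window, right-padded with `*`, so a sentence
   of n tokens yields n windows and no window crosses a boundary.
3. **Distance-augmented sequences.** Each sentence is a sequence of
   per-token inputs `[xv_i || xd_i]` (word vector of dimension d, plus a
   d-length distance block relative to the previous token, zero for the
   first token), with binary per-token labels.

Window labels are classes 1–6: class 1 if no reference drug name is a
prefix of the window, class k ≥ 2 if the window's first k−1 tokens are
exactly a reference name. When one reference is a prefix of another
("sodium" / "sodium polystyrene sulfonate"), the longest match wins —
the only rule consistent with the class-escalation scheme. Reference
lists are built from the annotations of the corpus being labelled (train
annotations for train windows, test annotations for test windows); names
longer than 5 tokens cannot be represented in a window and are dropped
with a warning.

The distance block is the elementwise absolute difference
`|xv_i − xv_{i−1}|`, whose L2 norm is exactly the Euclidean distance
between consecutive word vectors; this keeps the stated input width 2d
while staying norm-compatible with the scalar distance. A
`scalar_replicated` variant (the scalar distance copied across the block)
is available for comparison.

## Embeddings

Word vectors are CBOW with negative sampling, trained on the pooled
train+test sentences (optionally plus extra plain text) so that no corpus
token is out of vocabulary; padding `*` and genuinely unseen tokens map
to the zero vector. Defaults: dimension 100, context window 5, 10 epochs,
5 negatives, initial learning rate 0.1 decaying linearly to 1e-4,
single-threaded and seeded, so training is bit-reproducible.

Exported vectors are mean-centred and unit-normalized by default
(`CBOWEmbeddings.to_table(center=..., normalize=...)`). Raw small-corpus
CBOW vectors share a dominant common direction (average cosine between
arbitrary token pairs ≈ 0.8) and rare tokens sit near their tiny random
initialization; removing the vocabulary mean and rescaling puts every
token on a comparable footing. Without this post-processing no
downstream classifier separates anything on desk-scale corpora.

Distance utilities: Euclidean distance, cosine similarity (undefined for
zero vectors — raised as an error), and group-level averages
(drug–drug, drug–nondrug, nondrug–nondrug) used as diagnostics of the
embedding geometry.

The weight-decay coefficient λ is the pairwise-distance statistic
`Σ_{i<j} dist(x_i, x_j) / (n(n−1))`, implemented exactly as that formula
even though its normalizer counts ordered pairs while the sum runs over
unordered ones — so it equals *half* the mean pairwise distance. The
`mean=True` switch selects the true mean for anyone who prefers the
verbal definition over the printed one. For vocabularies above 2,000
tokens a seeded uniform subsample bounds the quadratic all-pairs cost;
at that size the statistic's sampling error is a few percent, which is
irrelevant to its role as a decay coefficient.

## Candidate selection

Ranking the training vocabulary by descending frequency (ties broken
lexicographically) and splitting it into three contiguous blocks of
near-equal *cumulative frequency* puts a handful of very common tokens in
block 1 and the long rare tail in block 3. Boundaries minimize the
maximum deviation of any block's mass from total/3 (dynamic program,
exact; ties resolve to the earliest boundaries). Scenario 2 keeps test
windows whose first token is outside block 1; first tokens unseen in
training count as rarest and are kept, so a drug token can only be lost
if it were among the corpus's most frequent tokens — the opposite of the
drug-token signature. Scenario 3 k-means the encoded windows into y
clusters (seeded, 10 restarts) and drops the y−x clusters with the
highest mean first-token training frequency; which clusters to drop is
not dictated by the class semantics, and dropping the common-word
clusters is the choice consistent with scenario 2's logic.

## Classifiers

**Window MLP.** 500→100→100→K architecture (sigmoid hiddens, softmax
output, K = number of observed classes), minibatch SGD with momentum.
Defaults are the published experiment settings: learning rate 1,
momentum 0.5, 100 epochs, batches of 100. The cost is mean
sum-of-squares on one-hot targets plus the weight-decay term (biases
excluded from the decay sum, the conventional reading of ΣW²); the
per-epoch loss trace is the mean over minibatches.

Two numerical choices are deliberate and load-bearing:

* The output-layer error signal is the conventional softmax backprop
  `h − y`. Propagating the squared error through the softmax Jacobian
  multiplies the signal by output probabilities twice; on imbalanced
  window data (≈ 95% class 1) this stalls permanently at the
  majority-class prior — measured, not conjectured. The monitored loss
  remains the squared-error objective that the decay study is defined
  on, and the classic toolkit lineage this setup descends from
  backpropagates the same shortcut for softmax outputs.
* Hidden sigmoid layers use the 4× Glorot uniform initialization
  recommended for logistic activations; with the plain factor,
  mid-layer activations are nearly constant and gradients vanish.

**Sequence LSTM.** Two stacked recurrent layers, peephole connections,
*coupled* input/forget gates (f = 1 − i), a single sigmoid output unit
per timestep; per-sequence SGD with momentum. Defaults: 2 hidden units
per layer, learning rate 0.001, momentum 0.9, 30 epochs. Each output
timestep's error backpropagates at most `bptt_truncate` steps (default
2) — the "time frame" reading of truncated backprop; the backward pass
is vectorized over origin timesteps. The output gradient uses the
logistic shortcut `p − y` for the same plateau reason as the MLP (the
squared-error factor p(1−p) vanishes exactly where a confidently wrong
output needs the largest correction); the monitored loss is the mean
squared error. Gradients of both networks are verified against finite
differences in the test suite.

## Evaluation

A window predicted class k ≥ 2 asserts an entity over its first k−1
tokens; entities containing padding or running past their sentence are
discarded, and overlapping assertions resolve by confidence (max softmax
probability — the analogue of selecting the lowest-error prediction),
with ties to the earlier start, then the longer span. Sequence
predictions decode maximal runs of 1-tags. Scoring is exact on
(sentence, token span, name), per mention; a name-only mode exists for
diagnostics. F is the harmonic mean 2PR/(P+R) — the printed formula's
denominator ("TruePositive + FalsePositive") is a typo inconsistent with
every reported F value. Conventions: P := 0 when C is empty, R := 0 when
K is empty, and P = R = F = 1 when both are empty.

## Synthetic corpus

The generator emulates the features the method exploits, calibrated to
the real corpora's statistics:

* Zipf-like background (2,000-token vocabulary, exponent 1.1): the top
  quartile of token types carries well over half the mass.
* A 150-token drug alphabet disjoint from the background; a prefix-free
  inventory of 40 drug names with length distribution
  (0.82, 0.08, 0.05, 0.03, 0.02) over 1–5 tokens, matching the ~18%
  multi-token share reported for the real datasets.
* 1,000 train / 250 test sentences of 8–20 tokens; 80% of sentences
  receive one mention (drug-label corpora run at roughly one mention per
  sentence). Drug tokens end up ≈ 7% of all tokens — under the 10%
  observed ceiling — and always inside the lower-2/3 frequency
  partition.
* Mentions sit in stereotyped frames: up to 3 tokens on each side are
  drawn (with probability 0.9) from a 12-token medical-context
  vocabulary that also appears sparsely (2%) elsewhere. This is the
  mechanism that gives drug tokens their shared-context embedding
  signature; without it every token has the same Zipf context
  distribution and the embedding geometry carries no drug signal at all.
* Exact inclusive character spans; 20% of mentions typed `drug-n`, the
  rest `drug`; everything deterministic given the seed.

What the generator does *not* emulate: grammar, morphology, abbreviations
and name variants, ambiguous tokens that are drugs in one context and
common words in another (an `ambiguity_rate` knob exists, default 0),
nested or overlapping mentions, and test-time drug names never seen in
training. Passing recovery tests therefore shows that the chain —
representations, labelling, selection, training, decoding, scoring — is
implemented correctly and can exploit the intended statistical structure;
it does not certify performance on real clinical text.

## Desk-scale experiment settings

The recovery experiments (entity-level F ≥ 0.9 held out, both routes) run
on the default synthetic corpus: ~15k training windows / 1,000 training
sequences — one to two orders of magnitude below the published corpora.
Two training settings are adjusted for that size and documented here as
the package's experiment configuration; class defaults keep the
published values:

* MLP learning rate 0.3 (at 15k windows, rate 1 with momentum 0.5 is
  chaotic — divergent for some seeds, excellent for others; 0.3 is
  stable across seeds).
* LSTM learning rate 0.01 (0.001 underfits within the 30-epoch budget at
  1,000 sequences).

The weight-decay comparison (same seed, λ = distance statistic vs λ = 0;
the decayed run must end with the strictly smaller weight norm) uses a
4,000-window subset and 30 epochs, which is ample for the norm effect.

## Known limitations

* The CBOW trainer is a compact single-threaded implementation — fine at
  desk scale, not built for hundred-million-token corpora.
* Candidate selection assumes the training frequency table is
  representative of test text; genre shift would erode the guarantee
  that drug windows survive scenario 2.
* The window decoder emits at most one entity per starting token and
  cannot represent nested mentions; names longer than 5 tokens are
  invisible to the window route (the sequence route has no such limit).
* Determinism is guaranteed within one platform/BLAS; exact bitwise
  equality across different numpy builds is not promised.
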
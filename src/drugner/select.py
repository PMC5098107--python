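"""Candidate selection: pre-classification filtering of test windows.

Drug tokens are a small, low-frequency part of the vocabulary, so most
windows are noise.  Three selection scenarios reduce that noise before a
window ever reaches the classifier:

* ``all`` — keep everything (the identity);
* ``lower_two_thirds`` — rank the training vocabulary by frequency, split
  it into three contiguous blocks of near-equal *cumulative frequency*
  (not equal token counts), and keep only windows whose first token falls
  in the lower two blocks.  Unseen first tokens are treated as rarest and
  kept;
* ``cluster`` — k-means the encoded windows into ``y`` clusters and keep
  the ``x`` clusters whose members have the lowest mean first-token
  training frequency (drops the common-word clusters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .corpus import Corpus
from .represent import LabelledWindow


class SelectionError(ValueError):
    pass


@dataclass
class FrequencyTable:
    """Token occurrence counts with a deterministic rank order."""

    counts: dict[str, int]

    @classmethod
    def from_corpus(cls, corpus: Corpus) -> "FrequencyTable":
        counts: dict[str, int] = {}
        for tok in corpus.all_tokens():
            counts[tok] = counts.get(tok, 0) + 1
        return cls(counts)

    def ranked(self) -> list[tuple[str, int]]:
        """Tokens by descending frequency; ties broken lexicographically."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, token: str) -> int:
        return self.counts.get(token, 0)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class SelectionResult:
    kept: list[LabelledWindow]
    scenario: str
    diagnostics: dict = field(default_factory=dict)


def frequency_partition(
    freq: FrequencyTable, parts: int = 3
) -> list[list[str]]:
    """Split the ranked vocabulary into contiguous blocks of near-equal mass.

    Boundaries minimize the maximum deviation of any block's frequency sum
    from ``total/parts``; among optimal splits the earliest boundaries win.
    The head block ends up with few, very frequent tokens and the tail
    block with the many rare ones.
    """
    if parts < 2:
        raise SelectionError("parts must be at least 2")
    ranked = freq.ranked()
    n = len(ranked)
    if parts > n:
        raise SelectionError(f"cannot split {n} tokens into {parts} blocks")
    counts = np.asarray([c for _, c in ranked], dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(counts)])  # csum[i] = sum of first i
    target = csum[-1] / parts

    # dp[p][i] = min over splits of tokens i.. into p blocks of the max
    # deviation |block sum - target|; inner minimization vectorized.
    INF = float("inf")
    dp = np.full((parts + 1, n + 1), INF)
    dp[0, n] = 0.0
    for p in range(1, parts + 1):
        # block must leave at least p-1 tokens for the remaining blocks
        for i in range(n - p, -1, -1):
            ends = np.arange(i + 1, n - (p - 1) + 1)
            dev = np.abs(csum[ends] - csum[i] - target)
            cand = np.maximum(dev, dp[p - 1, ends])
            dp[p, i] = cand.min()

    # reconstruct, preferring the earliest boundary achieving the optimum
    blocks: list[list[str]] = []
    i = 0
    for p in range(parts, 0, -1):
        ends = np.arange(i + 1, n - (p - 1) + 1)
        dev = np.abs(csum[ends] - csum[i] - target)
        cand = np.maximum(dev, dp[p - 1, ends])
        j = int(ends[int(np.argmax(cand <= dp[p, i] + 1e-9))])
        blocks.append([t for t, _ in ranked[i:j]])
        i = j
    return blocks


def partition_diagnostics(
    freq: FrequencyTable, blocks: Sequence[Sequence[str]]
) -> list[dict]:
    """Per-block unique-token and frequency sums (selection report rows)."""
    return [
        {
            "block": b + 1,
            "n_tokens": len(block),
            "frequency_sum": int(sum(freq[t] for t in block)),
        }
        for b, block in enumerate(blocks)
    ]


def select_all(windows: Sequence[LabelledWindow]) -> SelectionResult:
    return SelectionResult(kept=list(windows), scenario="all")


def select_lower_two_thirds(
    windows: Sequence[LabelledWindow], freq: FrequencyTable
) -> SelectionResult:
    """Scenario 2: keep windows whose first token sits in the lower 2/3.

    ``freq`` must be built on the *training* corpus.  First tokens absent
    from the table (possible on test data) count as rarest and are kept.
    """
    blocks = frequency_partition(freq, parts=3)
    head = set(blocks[0])
    kept = [w for w in windows if w.tokens[0] not in head]
    return SelectionResult(
        kept=kept,
        scenario="lower_two_thirds",
        diagnostics={
            "partition": partition_diagnostics(freq, blocks),
            "n_in": len(windows),
            "n_kept": len(kept),
        },
    )


def cluster_select(
    windows: Sequence[LabelledWindow],
    X: np.ndarray,
    freq: FrequencyTable,
    y: int,
    x: int,
    seed: int = 0,
) -> SelectionResult:
    """Scenario 3: keep x of y k-means clusters of the encoded windows.

    Clusters are ranked by the mean training frequency of their members'
    first tokens; the ``y - x`` highest-mean (common-word/noise) clusters
    are dropped.  Ties between cluster means break on the cluster id.
    """
    if x >= y:
        raise SelectionError(f"need x < y, got x={x}, y={y}")
    if x < 1:
        raise SelectionError("must keep at least one cluster")
    if len(windows) == 0:
        raise SelectionError("no windows to select from")
    if y > len(windows):
        raise SelectionError(f"more clusters ({y}) than windows ({len(windows)})")
    if X.shape[0] != len(windows):
        raise SelectionError("encoded matrix does not match window list")

    km = KMeans(n_clusters=y, n_init=10, random_state=seed)
    assign = km.fit_predict(X)
    first_freq = np.asarray([freq[w.tokens[0]] for w in windows], dtype=float)
    means = np.asarray(
        [first_freq[assign == c].mean() if np.any(assign == c) else -np.inf for c in range(y)]
    )
    order = sorted(range(y), key=lambda c: (-means[c], c))
    dropped = set(order[: y - x])
    kept = [w for w, c in zip(windows, assign) if c not in dropped]
    return SelectionResult(
        kept=kept,
        scenario="cluster",
        diagnostics={
            "cluster_mean_first_token_freq": {int(c): float(means[c]) for c in range(y)},
            "dropped_clusters": sorted(int(c) for c in dropped),
            "n_in": len(windows),
            "n_kept": len(kept),
        },
    )
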
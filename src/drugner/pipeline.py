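"""End-to-end orchestration: parse -> embed -> represent -> select -> train
-> predict -> decode -> score, with every intermediate persisted alongside
the config snapshot so a run is reproducible from its output directory."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import embed as embed_mod
from .corpus import Corpus, parse_corpus, tokenize
from .evaluate import (
    EvalReport,
    decode_entities_from_sequence,
    decode_entities_from_windows,
    gold_entities,
    score,
)
from .lstm import LSTMTagger
from .mlp import WindowMLPClassifier, regularization_lambda
from .represent import (
    DrugReferenceList,
    build_sequence_dataset,
    build_windows_all,
    build_windows_per_sentence,
    encode_windows,
    write_windows,
)
from .select import (
    FrequencyTable,
    cluster_select,
    select_all,
    select_lower_two_thirds,
)

logger = logging.getLogger(__name__)

SCENARIOS = ("all", "lower_two_thirds", "cluster")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """One experiment cell: representation x selection x classifier."""

    technique: int = 2
    scenario: str = "all"
    classifier: str = "mlp"
    regularization: str = "l0"
    cluster_y: int = 3
    cluster_x: int = 2
    embedding_dim: int = 100
    embedding_window: int = 5
    train_path: str | None = None
    test_path: str | None = None
    extra_corpus_path: str | None = None
    mlp_params: dict = field(default_factory=dict)
    lstm_params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if self.technique not in (1, 2, 3):
            raise ConfigError(f"unknown technique {self.technique}")
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.technique == 3 and self.classifier != "lstm":
            raise ConfigError("technique 3 requires the lstm classifier")
        if self.technique in (1, 2) and self.classifier != "mlp":
            raise ConfigError("techniques 1-2 require the mlp classifier")
        if self.scenario == "cluster" and self.cluster_x >= self.cluster_y:
            raise ConfigError(
                f"cluster scenario needs x < y, got x={self.cluster_x}, y={self.cluster_y}"
            )
        if self.regularization not in ("l0", "l1", "l2"):
            raise ConfigError(f"unknown regularization {self.regularization!r}")


def run_pipeline(
    cfg: RunConfig,
    train: Corpus | None = None,
    test: Corpus | None = None,
) -> EvalReport:
    """Execute the full chain and return the entity-level report.

    Corpora may be passed directly or read from the configured standoff
    paths.  All stages are seeded from ``cfg.seed``; the same config and
    corpora give byte-identical persisted reports.
    """
    cfg.validate()
    t0 = time.perf_counter()
    if train is None:
        if cfg.train_path is None:
            raise ConfigError("no training corpus")
        train = parse_corpus(cfg.train_path, role="train")
    if test is None:
        if cfg.test_path is None:
            raise ConfigError("no test corpus")
        test = parse_corpus(cfg.test_path, role="test")

    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True, indent=2),
            encoding="utf-8",
        )

    extra: list[list[str]] = []
    if cfg.extra_corpus_path:
        for line in Path(cfg.extra_corpus_path).read_text(encoding="utf-8").splitlines():
            toks = tokenize(line)
            if toks:
                extra.append(toks)

    table = embed_mod.train_embeddings(
        [train, test],
        extra_sentences=extra,
        dim=cfg.embedding_dim,
        window=cfg.embedding_window,
        seed=cfg.seed,
    )
    if outdir:
        table.save(outdir / "vectors.txt")
    logger.info("embeddings: %d tokens, dim %d", len(table.vocab), table.dim)

    if cfg.technique == 3:
        report = _run_sequence(cfg, train, test, table, outdir)
    else:
        report = _run_windows(cfg, train, test, table, outdir)

    logger.info("pipeline finished in %.1fs", time.perf_counter() - t0)
    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report.as_dict(), sort_keys=True, indent=2),
            encoding="utf-8",
        )
    return report


def _run_windows(cfg, train, test, table, outdir) -> EvalReport:
    build = build_windows_all if cfg.technique == 1 else build_windows_per_sentence
    refs_train = DrugReferenceList.from_corpus(train)
    refs_test = DrugReferenceList.from_corpus(test)
    train_windows = build(train, refs_train)
    test_windows = build(test, refs_test)
    logger.info(
        "technique %d: %d train / %d test windows",
        cfg.technique, len(train_windows), len(test_windows),
    )
    if outdir:
        write_windows(train_windows, outdir / "train_windows.tsv")
        write_windows(test_windows, outdir / "test_windows.tsv")

    X_train, y_train = encode_windows(train_windows, table)

    freq = FrequencyTable.from_corpus(train)
    if cfg.scenario == "all":
        sel = select_all(test_windows)
    elif cfg.scenario == "lower_two_thirds":
        sel = select_lower_two_thirds(test_windows, freq)
    else:
        X_all, _ = encode_windows(test_windows, table)
        sel = cluster_select(
            test_windows, X_all, freq, y=cfg.cluster_y, x=cfg.cluster_x, seed=cfg.seed
        )
    logger.info("selection %s kept %d/%d test windows",
                sel.scenario, len(sel.kept), len(test_windows))
    if outdir:
        (outdir / "selection.json").write_text(
            json.dumps({"scenario": sel.scenario, "diagnostics": sel.diagnostics},
                       sort_keys=True, indent=2, default=str),
            encoding="utf-8",
        )

    lam = regularization_lambda(cfg.regularization, table, seed=cfg.seed)
    clf = WindowMLPClassifier(alpha=lam, seed=cfg.seed, **cfg.mlp_params)
    clf.fit(X_train, y_train)

    X_test, _ = encode_windows(sel.kept, table)
    proba = clf.predict_proba(X_test)
    classes = clf.classes_[np.argmax(proba, axis=1)]
    conf = proba.max(axis=1)

    sentence_lengths = {i: len(s.tokens) for i, s in enumerate(test)}
    extracted = decode_entities_from_windows(
        sel.kept, classes, conf, sentence_lengths=sentence_lengths
    )
    return score(gold_entities(test, max_len=5), extracted)


def _run_sequence(cfg, train, test, table, outdir) -> EvalReport:
    train_seq = build_sequence_dataset(train, table)
    test_seq = build_sequence_dataset(test, table)
    tagger = LSTMTagger(seed=cfg.seed, **cfg.lstm_params)
    tagger.fit(train_seq)
    predicted = [tagger.predict(s) for s in test_seq]
    extracted = decode_entities_from_sequence(test_seq, predicted)
    return score(gold_entities(test, max_len=None), extracted)
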
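"""Reproducible benchmark protocol comparing the four sequence labellers.

One benchmark *condition* generates a synthetic corpus, splits it
7:1.5:1.5, trains the CNN encoder with the smoothed-Viterbi, bi-LSTM and
CRF labellers, and evaluates test accuracy and recall balance.  The
independent classifier's predictions come from the Viterbi bundle
re-smoothed at c=0, which provably degenerates to per-sentence argmax
(the classifier parameters are identical to an independently trained
classifier with the same seed).  Aggregation over several seeds yields
the mean ordering the decoder comparison is about.

Dimensions are deliberately modest (embedding 32, 16 feature maps per
kernel, decoder state 32, 400 notes) so a full five-seed comparison runs
in minutes on one CPU; the comparison is about the ordering of the
decoders, not absolute accuracies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .encoders import EncoderConfig
from .evaluation import accuracy, balance_score, confusion, sweep_c
from .simulate import default_config, generate_corpus
from .corpus import split_corpus
from .training import TrainConfig, predict, train

__all__ = ["ConditionResult", "BenchmarkResult", "run_condition", "run_benchmark"]

DECODERS = ("independent", "viterbi", "bilstm", "crf")


@dataclass
class ConditionResult:
    """Metrics for one corpus/seed condition."""

    test_accuracy: dict[str, float]
    balance: dict[str, float]
    sweep_grid: list[float]
    sweep_dev_accuracy: list[float]
    best_c: float
    classifier_dev_accuracy: float
    n_test_sentences: int


@dataclass
class BenchmarkResult:
    conditions: list[ConditionResult]

    def mean_accuracy(self, decoder: str) -> float:
        return float(np.mean([c.test_accuracy[decoder] for c in self.conditions]))

    def mean_balance(self, decoder: str) -> float:
        return float(np.mean([c.balance[decoder] for c in self.conditions]))

    def paired_gap_sem(self, hi: str, lo: str) -> tuple[float, float]:
        """Mean and standard error of per-seed accuracy differences hi - lo."""
        diffs = np.array(
            [c.test_accuracy[hi] - c.test_accuracy[lo] for c in self.conditions]
        )
        return float(diffs.mean()), float(diffs.std(ddof=1) / np.sqrt(len(diffs)))

    @property
    def mean_sweep_curve(self) -> tuple[list[float], list[float]]:
        grid = self.conditions[0].sweep_grid
        curve = np.mean([c.sweep_dev_accuracy for c in self.conditions], axis=0)
        return grid, [float(x) for x in curve]

    @property
    def n_test_sentences(self) -> int:
        return sum(c.n_test_sentences for c in self.conditions)


def run_condition(
    corpus_seed: int,
    train_seed: int,
    n_notes: int = 400,
    overlap: float = 0.7,
    self_transition: float = 0.8,
    max_epochs: int = 100,
    patience: int = 10,
    run_sweep: bool = True,
) -> ConditionResult:
    """Train and evaluate all decoder families on one synthetic corpus."""
    config = default_config(
        overlap=overlap, n_notes=n_notes, seed=corpus_seed,
        self_transition=self_transition,
    )
    corpus = generate_corpus(config)
    tr, dv, te = split_corpus(corpus, (7, 1.5, 1.5), seed=train_seed)
    encoder_config = EncoderConfig(kind="cnn", embedding_dim=32, cnn_feature_maps=16)
    train_config = TrainConfig(
        max_epochs=max_epochs, patience=patience, seed=train_seed,
        decoder_state_size=32,
    )

    acc: dict[str, float] = {}
    bal: dict[str, float] = {}

    viterbi_bundle = train(tr, dv, encoder_config, "viterbi", train_config)
    pred_v = predict(viterbi_bundle, te)
    acc["viterbi"] = accuracy(pred_v, te)
    bal["viterbi"] = balance_score(confusion(pred_v, te))
    pred_i = predict(viterbi_bundle.with_smoothing(0.0), te)
    acc["independent"] = accuracy(pred_i, te)
    bal["independent"] = balance_score(confusion(pred_i, te))

    for kind in ("bilstm", "crf"):
        bundle = train(tr, dv, encoder_config, kind, train_config)
        pred = predict(bundle, te)
        acc[kind] = accuracy(pred, te)
        bal[kind] = balance_score(confusion(pred, te))

    if run_sweep:
        sweep = sweep_c(viterbi_bundle, dv)
        grid, curve, best = sweep.grid, sweep.dev_accuracy, sweep.best_c
    else:
        grid, curve, best = [], [], float("nan")
    return ConditionResult(
        test_accuracy=acc,
        balance=bal,
        sweep_grid=grid,
        sweep_dev_accuracy=curve,
        best_c=best,
        classifier_dev_accuracy=accuracy(
            predict(viterbi_bundle.with_smoothing(0.0), dv), dv
        ),
        n_test_sentences=te.n_sentences,
    )


def run_benchmark(
    seeds: list[int],
    corpus_seed_offset: int = 100,
    **condition_kwargs,
) -> BenchmarkResult:
    """Run one condition per seed; corpus seed is ``offset + seed``."""
    conditions = [
        run_condition(corpus_seed=corpus_seed_offset + s, train_seed=s, **condition_kwargs)
        for s in seeds
    ]
    return BenchmarkResult(conditions=conditions)
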
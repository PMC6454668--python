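"""Evaluation metrics and the smoothing-factor sweep.

Accuracy pools all sentences over all notes.  The confusion matrix
follows the reference-in-rows convention: cell (i, j) counts gold-label-i
sentences predicted as j, and ``row_percent`` expresses each row as
percentages (per-class recall on the diagonal).  The balance score is
the standard deviation of per-class recall over classes with nonzero
support — lower means performance is spread more evenly across event
categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus
from .training import ModelBundle, predict

__all__ = [
    "ConfusionMatrix",
    "SweepResult",
    "accuracy",
    "confusion",
    "balance_score",
    "sweep_c",
    "format_confusion",
]


def _check_structure(predicted: Corpus, gold: Corpus) -> None:
    if len(predicted) != len(gold):
        raise ValueError("corpora have different numbers of notes")
    for i, (p, g) in enumerate(zip(predicted.notes, gold.notes)):
        if len(p) != len(g):
            raise ValueError(f"note {i} has mismatched sentence counts")
        if p.labels is None or g.labels is None:
            raise ValueError("both corpora must be labelled")


def accuracy(predicted: Corpus, gold: Corpus) -> float:
    """Fraction of sentences whose predicted label equals the gold label."""
    _check_structure(predicted, gold)
    correct = total = 0
    for p, g in zip(predicted.notes, gold.notes):
        correct += sum(int(a == b) for a, b in zip(p.labels, g.labels))
        total += len(p)
    return correct / total


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K); rows = reference, columns = prediction
    row_percent: np.ndarray  # NaN rows mark zero-support classes
    support: np.ndarray  # (K,) gold sentences per class
    label_names: tuple[str, ...]

    @property
    def per_class_recall(self) -> np.ndarray:
        """Diagonal of row_percent / 100 (NaN where unsupported)."""
        return np.diagonal(self.row_percent) / 100.0


def confusion(predicted: Corpus, gold: Corpus) -> ConfusionMatrix:
    _check_structure(predicted, gold)
    k = len(gold.label_set)
    counts = np.zeros((k, k), dtype=np.int64)
    for p, g in zip(predicted.notes, gold.notes):
        for a, b in zip(g.labels, p.labels):
            counts[a, b] += 1
    support = counts.sum(axis=1)
    row_percent = np.full((k, k), np.nan)
    nz = support > 0
    row_percent[nz] = 100.0 * counts[nz] / support[nz, None]
    return ConfusionMatrix(
        counts=counts,
        row_percent=row_percent,
        support=support,
        label_names=gold.label_set.names,
    )


def balance_score(cm: ConfusionMatrix) -> float:
    """Standard deviation of per-class recall (%) over supported classes."""
    recalls = np.diagonal(cm.row_percent)[cm.support > 0]
    if len(recalls) < 2:
        raise ValueError("balance score needs at least two supported classes")
    return float(np.std(recalls))


@dataclass
class SweepResult:
    grid: list[float]
    dev_accuracy: list[float]
    best_c: float


def sweep_c(
    bundle: ModelBundle,
    dev_corpus: Corpus,
    grid: list[float] | None = None,
) -> SweepResult:
    """Evaluate dev accuracy of a smoothed-Viterbi bundle across ``c`` values.

    Only the stored transition model is re-smoothed per grid point; no
    model parameter changes.  Ties in accuracy resolve to the smaller c.
    """
    if bundle.decoder_kind != "viterbi":
        raise ValueError("sweep_c requires a smoothed-Viterbi bundle")
    if grid is None:
        grid = [round(0.1 * i, 10) for i in range(11)]
    if not grid:
        raise ValueError("sweep grid must be nonempty")
    if any(not 0.0 <= c <= 1.0 for c in grid):
        raise ValueError("sweep grid values must lie in [0, 1]")
    accs = []
    for c in grid:
        accs.append(accuracy(predict(bundle.with_smoothing(c), dev_corpus), dev_corpus))
    best = max(range(len(grid)), key=lambda i: (accs[i], -grid[i]))
    return SweepResult(grid=list(grid), dev_accuracy=accs, best_c=float(grid[best]))


def format_confusion(cm: ConfusionMatrix, percent: bool = True) -> str:
    """Render the confusion matrix as an aligned text table."""
    width = max(len(n) for n in cm.label_names)
    head = " " * (width + 2) + "  ".join(f"{n[:8]:>8}" for n in cm.label_names)
    lines = [head]
    for i, name in enumerate(cm.label_names):
        if percent:
            if cm.support[i] == 0:
                cells = "  ".join(f"{'n/a':>8}" for _ in cm.label_names)
            else:
                cells = "  ".join(f"{x:8.1f}" for x in cm.row_percent[i])
        else:
            cells = "  ".join(f"{x:8d}" for x in cm.counts[i])
        lines.append(f"{name:<{width}}  {cells}")
    return "\n".join(lines)
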
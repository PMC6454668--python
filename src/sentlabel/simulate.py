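"""Synthetic annotated-corpus generation.

Real annotated clinical notes are scarce and rarely shareable, so this
module simulates corpora with the statistical structure the labelling
task assumes: each note's label sequence follows a first-order Markov
chain with high self-transition mass (medical events span several
consecutive short sentences), label frequencies are heavily imbalanced
(one dominant "Description of symptoms"-like category, several rare
ones), and each label emits tokens from a mixture of a label-private
vocabulary and a shared vocabulary.  The mixture weight ``overlap`` is
the lexical-separability dial: at 0 every label has a disjoint
vocabulary and per-sentence classification is easy; at 1 all labels
share one token distribution and only the label transitions carry
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .corpus import AnnotatedNote, Corpus, LabelSet, default_label_set

__all__ = [
    "GeneratorConfig",
    "CorpusStats",
    "default_config",
    "generate_corpus",
    "corpus_stats",
    "save_config",
    "load_config",
]

_SIMPLEX_TOL = 1e-9

#: Qualitative stationary weights mirroring the observed label imbalance:
#: a dominant symptom-description category, a large general-status
#: category, and several rare examination categories.
_DEFAULT_WEIGHTS = np.array(
    [0.40, 0.06, 0.02, 0.10, 0.21, 0.05, 0.04, 0.01, 0.01, 0.02, 0.08]
)


@dataclass
class GeneratorConfig:
    """Full statistical description of the synthetic corpus process."""

    label_set: LabelSet
    tokens: list[str]
    initial_probs: np.ndarray
    transition_probs: np.ndarray
    emission_probs: np.ndarray  # (K, |tokens|)
    note_length_range: tuple[int, int] = (4, 12)
    sentence_length_range: tuple[int, int] = (2, 6)
    n_notes: int = 500
    seed: int = 0

    def validate(self) -> None:
        k = len(self.label_set)
        ip = np.asarray(self.initial_probs, dtype=np.float64)
        tp = np.asarray(self.transition_probs, dtype=np.float64)
        ep = np.asarray(self.emission_probs, dtype=np.float64)
        if ip.shape != (k,):
            raise ValueError("initial_probs must have one entry per label")
        if abs(ip.sum() - 1.0) > _SIMPLEX_TOL or (ip < 0).any():
            raise ValueError("initial_probs must be a probability simplex vector")
        if tp.shape != (k, k):
            raise ValueError("transition_probs must be K x K")
        if np.abs(tp.sum(axis=1) - 1.0).max() > _SIMPLEX_TOL or (tp < 0).any():
            raise ValueError("every transition row must be a probability simplex")
        if ep.shape != (k, len(self.tokens)):
            raise ValueError("emission_probs must be K x |tokens|")
        if np.abs(ep.sum(axis=1) - 1.0).max() > _SIMPLEX_TOL or (ep < 0).any():
            raise ValueError("every emission row must be a probability simplex")
        for lo, hi in (self.note_length_range, self.sentence_length_range):
            if not (1 <= lo <= hi):
                raise ValueError("length ranges require 1 <= min <= max")
        if self.n_notes < 1:
            raise ValueError("n_notes must be >= 1")


def _zipf(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def default_config(
    overlap: float = 0.7,
    n_notes: int = 500,
    seed: int = 0,
    self_transition: float = 0.8,
    n_private: int = 30,
    n_shared: int = 60,
) -> GeneratorConfig:
    """Default 11-label configuration with imbalanced, blocky labels.

    ``overlap`` mixes each label's private token distribution (weight
    ``1 - overlap``) with one shared distribution (weight ``overlap``).
    Every label keeps self-transition probability ``self_transition``;
    the remaining mass goes to other labels proportionally to their
    stationary weights.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must lie in [0, 1], got {overlap}")
    label_set = default_label_set()
    k = len(label_set)
    w = _DEFAULT_WEIGHTS / _DEFAULT_WEIGHTS.sum()

    trans = np.zeros((k, k))
    for i in range(k):
        others = w.copy()
        others[i] = 0.0
        trans[i] = (1.0 - self_transition) * others / others.sum()
        trans[i, i] = self_transition
    trans /= trans.sum(axis=1, keepdims=True)

    tokens = [f"ev{l:02d}_w{i:03d}" for l in range(k) for i in range(n_private)]
    tokens += [f"shared_w{i:03d}" for i in range(n_shared)]
    n_tokens = len(tokens)
    shared_dist = np.zeros(n_tokens)
    shared_dist[k * n_private :] = _zipf(n_shared)
    emission = np.zeros((k, n_tokens))
    for l in range(k):
        private = np.zeros(n_tokens)
        private[l * n_private : (l + 1) * n_private] = _zipf(n_private)
        emission[l] = (1.0 - overlap) * private + overlap * shared_dist
    emission /= emission.sum(axis=1, keepdims=True)

    config = GeneratorConfig(
        label_set=label_set,
        tokens=tokens,
        initial_probs=w,
        transition_probs=trans,
        emission_probs=emission,
        n_notes=n_notes,
        seed=seed,
    )
    config.validate()
    return config


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Sample a labelled corpus from the configured Markov process.

    Fully determined by ``config.seed``: note lengths are uniform over
    ``note_length_range``, the first label follows ``initial_probs``,
    subsequent labels follow the previous label's transition row,
    sentence lengths are uniform over ``sentence_length_range`` and
    tokens are i.i.d. from the label's emission distribution.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = len(config.label_set)
    ip = np.asarray(config.initial_probs, dtype=np.float64)
    tp = np.asarray(config.transition_probs, dtype=np.float64)
    ep = np.asarray(config.emission_probs, dtype=np.float64)
    notes: list[AnnotatedNote] = []
    for _ in range(config.n_notes):
        n_sent = int(rng.integers(config.note_length_range[0],
                                  config.note_length_range[1] + 1))
        labels: list[int] = []
        for t in range(n_sent):
            probs = ip if t == 0 else tp[labels[-1]]
            labels.append(int(rng.choice(k, p=probs)))
        sentences: list[list[str]] = []
        for lab in labels:
            n_tok = int(rng.integers(config.sentence_length_range[0],
                                     config.sentence_length_range[1] + 1))
            idx = rng.choice(len(config.tokens), size=n_tok, p=ep[lab])
            sentences.append([config.tokens[i] for i in idx])
        notes.append(AnnotatedNote(sentences=sentences, labels=labels))
    return Corpus(notes=notes, label_set=config.label_set)


@dataclass
class CorpusStats:
    """Exact per-label counts and empirical chain frequencies."""

    label_counts: np.ndarray
    initial_counts: np.ndarray
    transition_counts: np.ndarray
    initial_freqs: np.ndarray
    transition_freqs: np.ndarray  # zero rows stay all-zero
    mean_note_length: float


def corpus_stats(corpus: Corpus) -> CorpusStats:
    if not corpus.is_labelled:
        raise ValueError("corpus statistics require a fully labelled corpus")
    k = len(corpus.label_set)
    label_counts = np.zeros(k, dtype=np.int64)
    initial = np.zeros(k, dtype=np.int64)
    trans = np.zeros((k, k), dtype=np.int64)
    for note in corpus.notes:
        initial[note.labels[0]] += 1
        for lab in note.labels:
            label_counts[lab] += 1
        for a, b in zip(note.labels[:-1], note.labels[1:]):
            trans[a, b] += 1
    row_sums = trans.sum(axis=1, keepdims=True)
    tfreq = np.divide(trans, row_sums, out=np.zeros((k, k)), where=row_sums > 0)
    n_init = initial.sum()
    ifreq = initial / n_init if n_init else initial.astype(np.float64)
    return CorpusStats(
        label_counts=label_counts,
        initial_counts=initial,
        transition_counts=trans,
        initial_freqs=ifreq,
        transition_freqs=tfreq,
        mean_note_length=float(np.mean([len(n) for n in corpus.notes])),
    )


def save_config(config: GeneratorConfig, path: str | Path) -> None:
    """Serialize a generator configuration as YAML."""
    payload = {
        "labels": list(config.label_set.names),
        "tokens": list(config.tokens),
        "initial_probs": np.asarray(config.initial_probs).tolist(),
        "transition_probs": np.asarray(config.transition_probs).tolist(),
        "emission_probs": np.asarray(config.emission_probs).tolist(),
        "note_length_range": list(config.note_length_range),
        "sentence_length_range": list(config.sentence_length_range),
        "n_notes": config.n_notes,
        "seed": config.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh)


def load_config(path: str | Path) -> GeneratorConfig:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    config = GeneratorConfig(
        label_set=LabelSet(tuple(payload["labels"])),
        tokens=list(payload["tokens"]),
        initial_probs=np.asarray(payload["initial_probs"]),
        transition_probs=np.asarray(payload["transition_probs"]),
        emission_probs=np.asarray(payload["emission_probs"]),
        note_length_range=tuple(payload["note_length_range"]),
        sentence_length_range=tuple(payload["sentence_length_range"]),
        n_notes=int(payload["n_notes"]),
        seed=int(payload["seed"]),
    )
    config.validate()
    return config
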
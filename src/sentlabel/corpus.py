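"""Data model and file I/O for labelled clinical-note corpora.

A clinical note is modelled as an ordered sequence of *short sentences*
(comma/period-delimited spans, arriving pre-tokenized), each carrying at
most one event label.  The default label set contains ten high-level
medical event categories plus the catch-all ``Others``.

File dialect
------------
One short sentence per line, ``LABEL<TAB>space-separated tokens``; a blank
line terminates a note; the placeholder label ``-`` marks unlabelled
sentences (prediction inputs).  UTF-8 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LabelSet",
    "AnnotatedNote",
    "Corpus",
    "Vocabulary",
    "DEFAULT_LABELS",
    "default_label_set",
    "read_corpus",
    "write_corpus",
    "split_corpus",
    "build_vocabulary",
    "load_embeddings",
    "CorpusFormatError",
    "UnknownLabelError",
]

#: The ten medical event categories plus "Others".
DEFAULT_LABELS: tuple[str, ...] = (
    "Description of symptoms",
    "History of treatment",
    "History of diagnosis",
    "Admission status",
    "General status",
    "Imaging examination",
    "Laboratory examination",
    "Electrocardiogram examination",
    "Endoscopy",
    "Pathological examination",
    "Others",
)

#: Placeholder label column for unlabelled sentences.
UNLABELLED = "-"

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
PAD_INDEX = 0
UNK_INDEX = 1


class CorpusFormatError(ValueError):
    """Raised for malformed corpus or embedding files."""


class UnknownLabelError(ValueError):
    """Raised when a file contains a label outside the label set."""


@dataclass(frozen=True)
class LabelSet:
    """Ordered, unique label names with a name-to-index map."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("label names must be unique")
        if not self.names:
            raise ValueError("label set must be nonempty")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(self.names)})

    @property
    def index(self) -> dict[str, int]:
        return dict(self._index)

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, i: int) -> str:
        return self.names[i]

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise UnknownLabelError(f"unknown label: {name!r}") from None


def default_label_set() -> LabelSet:
    """The 11-category event tag system (10 medical events + Others)."""
    return LabelSet(DEFAULT_LABELS)


@dataclass
class AnnotatedNote:
    """One clinical note: sentences (token lists) plus optional labels.

    ``labels`` is either ``None`` (prediction input) or a list of label
    indices of the same length as ``sentences``.
    """

    sentences: list[list[str]]
    labels: list[int] | None = None

    def __post_init__(self) -> None:
        for sent in self.sentences:
            if len(sent) < 1:
                raise ValueError("every sentence must contain at least one token")
            for tok in sent:
                if any(ch.isspace() for ch in tok):
                    raise ValueError(f"token contains whitespace: {tok!r}")
        if self.labels is not None and len(self.labels) != len(self.sentences):
            raise ValueError("labels and sentences must have the same length")

    def __len__(self) -> int:
        return len(self.sentences)

    @property
    def is_labelled(self) -> bool:
        return self.labels is not None


@dataclass
class Corpus:
    """A list of notes sharing one label set."""

    notes: list[AnnotatedNote]
    label_set: LabelSet

    def __post_init__(self) -> None:
        k = len(self.label_set)
        for note in self.notes:
            if note.labels is not None:
                for lab in note.labels:
                    if not 0 <= lab < k:
                        raise ValueError(f"label index {lab} outside 0..{k - 1}")

    def __len__(self) -> int:
        return len(self.notes)

    @property
    def n_sentences(self) -> int:
        return sum(len(n) for n in self.notes)

    @property
    def is_labelled(self) -> bool:
        return all(n.is_labelled for n in self.notes)


def read_corpus(path: str | Path, label_set: LabelSet) -> Corpus:
    """Read a corpus file (sentence-per-line, tab-separated dialect).

    Unlabelled sentences use the placeholder label ``-``; a note must be
    either fully labelled or fully unlabelled.
    """
    notes: list[AnnotatedNote] = []
    sentences: list[list[str]] = []
    labels: list[int | None] = []

    def flush(lineno: int) -> None:
        if not sentences:
            return
        labelled = [l for l in labels if l is not None]
        if labelled and len(labelled) != len(labels):
            raise CorpusFormatError(
                f"line {lineno}: note mixes labelled and unlabelled sentences"
            )
        notes.append(
            AnnotatedNote(
                sentences=list(sentences),
                labels=list(labelled) if labelled else None,
            )
        )
        sentences.clear()
        labels.clear()

    with open(path, encoding="utf-8") as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush(lineno)
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CorpusFormatError(
                    f"line {lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            label_str, token_str = parts
            tokens = token_str.split()
            if not tokens:
                raise CorpusFormatError(f"line {lineno}: sentence has no tokens")
            if label_str == UNLABELLED:
                labels.append(None)
            else:
                labels.append(label_set.index_of(label_str))
            sentences.append(tokens)
        flush(lineno + 1)
    return Corpus(notes=notes, label_set=label_set)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the sentence-per-line dialect (round-trip safe)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, note in enumerate(corpus.notes):
            if i:
                fh.write("\n")
            for j, sent in enumerate(note.sentences):
                if note.labels is None:
                    label_str = UNLABELLED
                else:
                    label_str = corpus.label_set[note.labels[j]]
                fh.write(f"{label_str}\t{' '.join(sent)}\n")


def split_corpus(
    corpus: Corpus,
    ratios: Sequence[float] = (7.0, 1.5, 1.5),
    seed: int = 0,
) -> tuple[Corpus, Corpus, Corpus]:
    """Shuffle notes with ``seed`` and partition into train/dev/test.

    Sizes are ``floor(n*r1/S)`` and ``floor(n*r2/S)``; the test set takes
    the remainder.  Deterministic for a fixed seed.
    """
    r = [float(x) for x in ratios]
    if len(r) != 3 or any(x < 0 for x in r) or sum(r) <= 0:
        raise ValueError("ratios must be three nonnegative numbers with positive sum")
    if len(corpus) == 0:
        raise ValueError("cannot split an empty corpus")
    n = len(corpus)
    total = sum(r)
    n_train = int(np.floor(n * r[0] / total))
    n_dev = int(np.floor(n * r[1] / total))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    picks = [corpus.notes[i] for i in order]
    mk = lambda notes: Corpus(notes=notes, label_set=corpus.label_set)
    return (
        mk(picks[:n_train]),
        mk(picks[n_train : n_train + n_dev]),
        mk(picks[n_train + n_dev :]),
    )


@dataclass
class Vocabulary:
    """Token-to-index map with reserved PAD (0) and UNK (1) entries.

    Non-reserved indices are assigned by descending corpus frequency,
    ties broken lexicographically.
    """

    token_to_index: dict[str, int]
    min_count: int = 1

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def encode_token(self, token: str) -> int:
        return self.token_to_index.get(token, UNK_INDEX)

    def encode_sentence(self, tokens: Iterable[str]) -> list[int]:
        return [self.encode_token(t) for t in tokens]

    @property
    def tokens(self) -> list[str]:
        out = [""] * len(self.token_to_index)
        for tok, i in self.token_to_index.items():
            out[i] = tok
        return out


def build_vocabulary(corpus: Corpus, min_count: int = 1) -> Vocabulary:
    """Build a vocabulary of tokens with frequency >= ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if len(corpus) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    freq: dict[str, int] = {}
    for note in corpus.notes:
        for sent in note.sentences:
            for tok in sent:
                freq[tok] = freq.get(tok, 0) + 1
    kept = sorted(
        (t for t, c in freq.items() if c >= min_count),
        key=lambda t: (-freq[t], t),
    )
    mapping = {PAD_TOKEN: PAD_INDEX, UNK_TOKEN: UNK_INDEX}
    for i, tok in enumerate(kept, start=2):
        mapping[tok] = i
    return Vocabulary(token_to_index=mapping, min_count=min_count)


def load_embeddings(
    path: str | Path,
    vocabulary: Vocabulary,
    dim: int,
    seed: int = 0,
) -> np.ndarray:
    """Load word2vec-style plain-text embeddings into a |V| x dim matrix.

    Rows for tokens present in the file are copied verbatim.  Tokens
    missing from the file (including UNK) are drawn from a seeded uniform
    distribution on [-0.25, 0.25]; the PAD row is all zeros.
    """
    rng = np.random.default_rng(seed)
    matrix = rng.uniform(-0.25, 0.25, size=(len(vocabulary), dim))
    matrix[PAD_INDEX] = 0.0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise CorpusFormatError("embedding file must start with 'count dim' header")
        file_dim = int(header[1])
        if file_dim != dim:
            raise CorpusFormatError(
                f"embedding dimension mismatch: file has {file_dim}, requested {dim}"
            )
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < dim + 1:
                raise CorpusFormatError(
                    f"line {lineno}: expected token plus {dim} values"
                )
            token = parts[0]
            if token in vocabulary:
                matrix[vocabulary.token_to_index[token]] = np.asarray(
                    parts[1 : dim + 1], dtype=np.float64
                )
    matrix[PAD_INDEX] = 0.0
    return matrix
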
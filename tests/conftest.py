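import numpy as np
import pytest

from sentlabel.corpus import AnnotatedNote, Corpus, LabelSet, default_label_set


@pytest.fixture
def ab_labels() -> LabelSet:
    return LabelSet(("A", "B"))


@pytest.fixture
def labels11() -> LabelSet:
    return default_label_set()


@pytest.fixture
def tiny_corpus(ab_labels) -> Corpus:
    """Two hand-written notes over a two-label set."""
    notes = [
        AnnotatedNote(
            sentences=[["fever", "two", "days"], ["no", "rash"], ["ct", "scan"]],
            labels=[0, 0, 1],
        ),
        AnnotatedNote(
            sentences=[["xray", "normal"], ["cough"]],
            labels=[1, 0],
        ),
    ]
    return Corpus(notes=notes, label_set=ab_labels)


def make_random_corpus(label_set, n_notes, seed, max_len=5, vocab=("fever", "cough", "xray", "ct", "normal", "rash")):
    """Random labelled corpus for property tests (not the generator module)."""
    rng = np.random.default_rng(seed)
    notes = []
    for _ in range(n_notes):
        n_sent = int(rng.integers(1, max_len + 1))
        sentences = [
            [vocab[i] for i in rng.integers(0, len(vocab), size=rng.integers(1, 5))]
            for _ in range(n_sent)
        ]
        labels = [int(x) for x in rng.integers(0, len(label_set), size=n_sent)]
        notes.append(AnnotatedNote(sentences=sentences, labels=labels))
    return Corpus(notes=notes, label_set=label_set)
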
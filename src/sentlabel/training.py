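"""End-to-end training of encoder + sequence-labeller combinations.

Any sentence encoder (CNN or bi-LSTM) can be paired with one of four
labelling strategies:

* ``independent`` — per-sentence softmax classifier (cross-entropy);
* ``bilstm`` — bi-LSTM decoder over the note (per-sentence cross-entropy);
* ``crf`` — linear-chain CRF (sequence negative log-likelihood);
* ``viterbi`` — smoothed Viterbi: the independent classifier is trained
  with the same optimization path (and therefore identical parameters for
  the same seed), then the label-transition matrix is estimated from the
  training labels and exponent-smoothed; no decoder parameters are
  trained.

Optimization uses Adam (learning rate 0.001 by default) with early
stopping on development-set accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concatenate
from .corpus import AnnotatedNote, Corpus, LabelSet, Vocabulary, build_vocabulary
from .decoders import (
    CRF,
    BiLSTMDecoder,
    SoftmaxHead,
    TransitionModel,
    classify_independent,
    bilstm_decode,
    crf_decode,
    crf_nll,
    estimate_transitions,
    smooth_transitions,
    viterbi_decode,
)
from .encoders import EncoderConfig, build_encoder
from .layers import Adam, cross_entropy

__all__ = ["TrainConfig", "ModelBundle", "train", "predict"]

DECODER_KINDS = ("independent", "viterbi", "bilstm", "crf")


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    optimizer: str = "adam"
    dropout_rate: float = 0.5
    batch_size: int = 16  # notes per batch
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0
    smoothing_c: float = 0.3
    decoder_state_size: int = 128
    transition_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1 or self.max_epochs < 1:
            raise ValueError("patience and max_epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class ModelBundle:
    """Self-contained trained model: everything prediction needs."""

    vocabulary: Vocabulary
    label_set: LabelSet
    encoder_config: EncoderConfig
    encoder_state: list[np.ndarray]
    decoder_kind: str
    decoder_state: list[np.ndarray]
    decoder_state_size: int
    transition_model: TransitionModel | None
    smoothing_c: float
    metadata: dict

    # -- runtime reconstruction -------------------------------------------

    def _runtime(self):
        rng = np.random.default_rng(0)
        encoder = build_encoder(self.encoder_config, len(self.vocabulary), rng)
        for p, arr in zip(encoder.parameters(), self.encoder_state):
            p.data = np.array(arr, dtype=np.float64)
        k = len(self.label_set)
        dim = self.encoder_config.output_dim
        if self.decoder_kind in ("independent", "viterbi"):
            dec = SoftmaxHead(dim, k, rng)
        elif self.decoder_kind == "bilstm":
            dec = BiLSTMDecoder(dim, k, rng, state_size=self.decoder_state_size)
        elif self.decoder_kind == "crf":
            dec = _CRFLabeller(dim, k, rng)
        else:
            raise ValueError(f"unknown decoder kind {self.decoder_kind!r}")
        for p, arr in zip(dec.parameters(), self.decoder_state):
            p.data = np.array(arr, dtype=np.float64)
        return encoder, dec

    def with_smoothing(self, c: float) -> "ModelBundle":
        """Re-smooth the stored transition model; no parameters change."""
        if self.transition_model is None:
            raise ValueError("bundle has no transition model")
        import dataclasses

        return dataclasses.replace(
            self,
            smoothing_c=float(c),
            transition_model=smooth_transitions(self.transition_model, c),
        )

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        tm = self.transition_model
        payload = {
            "vocabulary": self.vocabulary.token_to_index,
            "min_count": self.vocabulary.min_count,
            "labels": list(self.label_set.names),
            "encoder_config": {
                "kind": self.encoder_config.kind,
                "embedding_dim": self.encoder_config.embedding_dim,
                "cnn_kernel_sizes": list(self.encoder_config.cnn_kernel_sizes),
                "cnn_feature_maps": self.encoder_config.cnn_feature_maps,
                "lstm_state_size": self.encoder_config.lstm_state_size,
                "lstm_layers": self.encoder_config.lstm_layers,
                "dropout_rate": self.encoder_config.dropout_rate,
            },
            "encoder_state": [a.tolist() for a in self.encoder_state],
            "decoder_kind": self.decoder_kind,
            "decoder_state": [a.tolist() for a in self.decoder_state],
            "decoder_state_size": self.decoder_state_size,
            "smoothing_c": self.smoothing_c,
            "transition_model": None
            if tm is None
            else {
                "counts": tm.counts.tolist(),
                "initial_counts": tm.initial_counts.tolist(),
                "pseudocount": tm.pseudocount,
            },
            "metadata": self.metadata,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        ec = payload["encoder_config"]
        ec["cnn_kernel_sizes"] = tuple(ec["cnn_kernel_sizes"])
        tm_payload = payload["transition_model"]
        tm = None
        if tm_payload is not None:
            counts = np.asarray(tm_payload["counts"], dtype=np.int64)
            initial = np.asarray(tm_payload["initial_counts"], dtype=np.int64)
            eps = float(tm_payload["pseudocount"])
            raw = counts + eps
            init = initial + eps
            tm = TransitionModel(
                counts=counts,
                initial_counts=initial,
                pseudocount=eps,
                raw_probs=raw / raw.sum(axis=1, keepdims=True),
                raw_initial=init / init.sum(),
            )
            tm = smooth_transitions(tm, float(payload["smoothing_c"]))
        return cls(
            vocabulary=Vocabulary(
                token_to_index=dict(payload["vocabulary"]),
                min_count=int(payload["min_count"]),
            ),
            label_set=LabelSet(tuple(payload["labels"])),
            encoder_config=EncoderConfig(**ec),
            encoder_state=[np.asarray(a) for a in payload["encoder_state"]],
            decoder_kind=payload["decoder_kind"],
            decoder_state=[np.asarray(a) for a in payload["decoder_state"]],
            decoder_state_size=int(payload["decoder_state_size"]),
            transition_model=tm,
            smoothing_c=float(payload["smoothing_c"]),
            metadata=dict(payload["metadata"]),
        )


class _CRFLabeller:
    """Emission projection + CRF parameters, bundled for convenience."""

    def __init__(self, in_dim: int, n_labels: int, rng: np.random.Generator):
        self.head = SoftmaxHead(in_dim, n_labels, rng)
        self.crf = CRF(n_labels, rng)

    def parameters(self) -> list[Tensor]:
        return self.head.parameters() + self.crf.parameters()


def _note_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _encode_notes(encoder, vocabulary, notes, train, rng):
    """Flatten a batch of notes into one encoded sentence batch.

    Returns the (N, D) encoding tensor plus per-note sentence offsets.
    """
    flat: list[list[int]] = []
    offsets = [0]
    for note in notes:
        for sent in note.sentences:
            flat.append(vocabulary.encode_sentence(sent))
        offsets.append(len(flat))
    enc = encoder.encode_batch(flat, train=train, rng=rng)
    return enc, offsets


def _batch_loss(kind, encoder, dec, vocabulary, notes, rng):
    enc, offsets = _encode_notes(encoder, vocabulary, notes, train=True, rng=rng)
    gold = np.concatenate([np.asarray(n.labels, dtype=np.intp) for n in notes])
    if kind in ("independent", "viterbi"):
        return cross_entropy(dec.logits(enc), gold)
    if kind == "bilstm":
        lengths = np.array([len(n) for n in notes], dtype=np.intp)
        t_max = int(lengths.max())
        dim = enc.shape[1]
        padded_rows = concatenate([enc, Tensor(np.zeros((1, dim)))], axis=0)
        idx = np.full((len(notes), t_max), enc.shape[0], dtype=np.intp)
        for b in range(len(notes)):
            idx[b, : lengths[b]] = np.arange(offsets[b], offsets[b + 1])
        logits = dec.logits(padded_rows[(idx,)], lengths)  # (B, T, K)
        b_idx = np.repeat(np.arange(len(notes)), lengths)
        t_idx = np.concatenate([np.arange(l) for l in lengths])
        return cross_entropy(logits[(b_idx, t_idx)], gold)
    if kind == "crf":
        scores = dec.head.logits(enc)
        total = None
        for b, note in enumerate(notes):
            nll = crf_nll(scores[(slice(offsets[b], offsets[b + 1]),)], note.labels, dec.crf)
            total = nll if total is None else total + nll
        return total * (1.0 / len(gold))
    raise ValueError(f"unknown decoder kind {kind!r}")


def _decode_note(kind, encoder, dec, vocabulary, note, transitions):
    enc = encoder.encode_batch(
        [vocabulary.encode_sentence(s) for s in note.sentences]
    )
    if kind == "independent":
        probs = classify_independent(enc, dec)
        return [int(i) for i in probs.argmax(axis=1)]
    if kind == "viterbi":
        probs = classify_independent(enc, dec)
        return viterbi_decode(probs, transitions).labels
    if kind == "bilstm":
        probs = bilstm_decode(enc.data, dec)
        return [int(i) for i in probs.argmax(axis=1)]
    if kind == "crf":
        scores = dec.head.logits(enc)
        return crf_decode(scores, dec.crf).labels
    raise ValueError(f"unknown decoder kind {kind!r}")


def _corpus_accuracy(kind, encoder, dec, vocabulary, corpus, transitions) -> float:
    correct = total = 0
    for note in corpus.notes:
        pred = _decode_note(kind, encoder, dec, vocabulary, note, transitions)
        correct += sum(int(p == g) for p, g in zip(pred, note.labels))
        total += len(note)
    return correct / total


def train(
    train_corpus: Corpus,
    dev_corpus: Corpus,
    encoder_config: EncoderConfig | None = None,
    decoder_kind: str = "viterbi",
    config: TrainConfig | None = None,
    min_count: int = 1,
    embeddings: np.ndarray | None = None,
) -> ModelBundle:
    """Fit an encoder + labeller combination with early stopping.

    For ``decoder_kind="viterbi"`` the classifier is optimized exactly as
    for ``"independent"`` (identical parameter trajectory and epoch
    selection for the same seed); the smoothed transition model is
    attached afterwards from the training labels alone.
    """
    if decoder_kind not in DECODER_KINDS:
        raise ValueError(f"decoder_kind must be one of {DECODER_KINDS}")
    for c in (train_corpus, dev_corpus):
        if len(c) == 0:
            raise ValueError("train and dev corpora must be nonempty")
        if not c.is_labelled:
            raise ValueError("train and dev corpora must be labelled")
    if train_corpus.label_set.names != dev_corpus.label_set.names:
        raise ValueError("train and dev corpora use different label sets")
    encoder_config = encoder_config or EncoderConfig()
    config = config or TrainConfig()
    encoder_config.dropout_rate = config.dropout_rate

    rng = np.random.default_rng(config.seed)
    vocabulary = build_vocabulary(train_corpus, min_count=min_count)
    k = len(train_corpus.label_set)
    encoder = build_encoder(encoder_config, len(vocabulary), rng, embeddings)
    dim = encoder_config.output_dim

    # the viterbi labeller trains the plain classifier: same init, same
    # optimization, same model selection
    train_kind = "independent" if decoder_kind == "viterbi" else decoder_kind
    if train_kind == "independent":
        dec = SoftmaxHead(dim, k, rng)
    elif train_kind == "bilstm":
        dec = BiLSTMDecoder(dim, k, rng, state_size=config.decoder_state_size)
    else:
        dec = _CRFLabeller(dim, k, rng)

    params = encoder.parameters() + dec.parameters()
    optimizer = Adam(params, lr=config.learning_rate)

    best_acc = -1.0
    best_state = None
    best_epoch = 0
    epochs_run = 0
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        epochs_run = epoch
        for batch_ids in _note_batches(len(train_corpus), config.batch_size, rng):
            notes = [train_corpus.notes[i] for i in batch_ids]
            optimizer.zero_grad()
            loss = _batch_loss(train_kind, encoder, dec, vocabulary, notes, rng)
            loss.backward()
            optimizer.step()
        acc = _corpus_accuracy(train_kind, encoder, dec, vocabulary, dev_corpus, None)
        if acc > best_acc:
            best_acc = acc
            best_state = [p.data.copy() for p in params]
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    for p, arr in zip(params, best_state):
        p.data = arr

    transitions = None
    metadata = {
        "epochs_run": epochs_run,
        "best_epoch": best_epoch,
        "best_dev_accuracy": best_acc,
    }
    if decoder_kind == "viterbi":
        transitions = smooth_transitions(
            estimate_transitions(train_corpus, config.transition_pseudocount),
            config.smoothing_c,
        )
        metadata["dev_accuracy_viterbi"] = _corpus_accuracy(
            "viterbi", encoder, dec, vocabulary, dev_corpus, transitions
        )
    return ModelBundle(
        vocabulary=vocabulary,
        label_set=train_corpus.label_set,
        encoder_config=encoder_config,
        encoder_state=[p.data.copy() for p in encoder.parameters()],
        decoder_kind=decoder_kind,
        decoder_state=[p.data.copy() for p in dec.parameters()],
        decoder_state_size=config.decoder_state_size,
        transition_model=transitions,
        smoothing_c=config.smoothing_c,
        metadata=metadata,
    )


def predict(bundle: ModelBundle, corpus: Corpus) -> Corpus:
    """Label every sentence of ``corpus`` with the bundled model.

    Deterministic (evaluation mode); note and sentence order preserved.
    """
    encoder, dec = bundle._runtime()
    out_notes = []
    for note in corpus.notes:
        labels = _decode_note(
            bundle.decoder_kind, encoder, dec, bundle.vocabulary, note,
            bundle.transition_model,
        )
        out_notes.append(AnnotatedNote(sentences=[list(s) for s in note.sentences],
                                       labels=labels))
    return Corpus(notes=out_notes, label_set=bundle.label_set)
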
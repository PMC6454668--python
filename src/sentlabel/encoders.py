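"""Sentence feature extractors: text-CNN and stacked bi-LSTM.

Both map a short sentence (a sequence of vocabulary indices) to a
fixed-length vector over a trainable embedding table:

* CNN: 1-D convolutions with kernel sizes 3/4/5 (100 feature maps each by
  default), ReLU, max-over-time pooling, concatenation -> 300 dims.
* bi-LSTM: a stack of bidirectional LSTM layers (state size 128, 2 layers
  by default); the encoding concatenates the final forward and final
  backward states of the top layer -> 256 dims.

Encoders are context-free per sentence: the vector for sentence *i*
depends only on sentence *i*.  Sentences shorter than the largest CNN
kernel are right-padded with the PAD embedding up to that kernel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concatenate, dropout
from .corpus import AnnotatedNote, Vocabulary, PAD_INDEX
from .layers import BiLSTM, Linear, gather_time

__all__ = [
    "EncoderConfig",
    "CNNEncoder",
    "BiLSTMEncoder",
    "build_encoder",
    "encode_cnn",
    "encode_bilstm",
    "encode_note",
]

NEG_INF = -1e30


@dataclass
class EncoderConfig:
    kind: str = "cnn"  # "cnn" | "bilstm"
    embedding_dim: int = 100
    cnn_kernel_sizes: tuple[int, ...] = (3, 4, 5)
    cnn_feature_maps: int = 100
    lstm_state_size: int = 128
    lstm_layers: int = 2
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("cnn", "bilstm"):
            raise ValueError(f"unknown encoder kind: {self.kind!r}")
        if self.kind == "bilstm" and self.lstm_layers not in (1, 2, 3):
            raise ValueError("lstm_layers must be 1, 2 or 3")

    @property
    def output_dim(self) -> int:
        if self.kind == "cnn":
            return len(self.cnn_kernel_sizes) * self.cnn_feature_maps
        return 2 * self.lstm_state_size


def _pad_batch(sentences: list[list[int]], min_len: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Stack index sequences into a PAD-padded (B, L) matrix plus lengths."""
    if not sentences:
        raise ValueError("empty batch of sentences")
    lengths = np.array([len(s) for s in sentences], dtype=np.intp)
    if (lengths < 1).any():
        raise ValueError("empty sentence cannot be encoded")
    L = max(int(lengths.max()), min_len)
    ids = np.full((len(sentences), L), PAD_INDEX, dtype=np.intp)
    for b, s in enumerate(sentences):
        ids[b, : len(s)] = s
    return ids, lengths


class CNNEncoder:
    """Text-CNN feature extractor (ReLU + max-over-time pooling)."""

    def __init__(
        self,
        config: EncoderConfig,
        vocab_size: int,
        rng: np.random.Generator,
        embeddings: np.ndarray | None = None,
    ):
        self.config = config
        D, F = config.embedding_dim, config.cnn_feature_maps
        if embeddings is None:
            embeddings = rng.uniform(-0.25, 0.25, size=(vocab_size, D))
            embeddings[PAD_INDEX] = 0.0
        self.embedding = Tensor(np.asarray(embeddings, dtype=np.float64), requires_grad=True)
        self.convs = [Linear(k * D, F, rng) for k in config.cnn_kernel_sizes]

    @property
    def output_dim(self) -> int:
        return self.config.output_dim

    def encode_batch(
        self,
        sentences: list[list[int]],
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        kmax = max(self.config.cnn_kernel_sizes)
        ids, lengths = _pad_batch(sentences, min_len=kmax)
        L = ids.shape[1]
        emb = self.embedding[ids]  # (B, L, D)
        pooled: list[Tensor] = []
        for k, conv in zip(self.config.cnn_kernel_sizes, self.convs):
            n_windows = L - k + 1
            windows = concatenate(
                [emb[(slice(None), slice(i, i + n_windows))] for i in range(k)], axis=2
            )  # (B, n_windows, k*D)
            act = conv(windows).relu()
            # windows starting past a sentence's own padded extent are masked
            # out so the encoding is independent of batch-mate lengths
            valid = np.maximum(lengths, kmax) - k + 1
            mask = np.where(np.arange(n_windows)[None, :] < valid[:, None], 0.0, NEG_INF)
            pooled.append((act + Tensor(mask[:, :, None])).max(axis=1))
        out = concatenate(pooled, axis=1)
        if train and self.config.dropout_rate > 0:
            out = dropout(out, self.config.dropout_rate, rng)
        return out

    def parameters(self) -> list[Tensor]:
        params = [self.embedding]
        for conv in self.convs:
            params.extend(conv.parameters())
        return params


class BiLSTMEncoder:
    """Stacked bi-LSTM extractor; final fwd/bwd top-layer states concatenated."""

    def __init__(
        self,
        config: EncoderConfig,
        vocab_size: int,
        rng: np.random.Generator,
        embeddings: np.ndarray | None = None,
    ):
        self.config = config
        D, H = config.embedding_dim, config.lstm_state_size
        if embeddings is None:
            embeddings = rng.uniform(-0.25, 0.25, size=(vocab_size, D))
            embeddings[PAD_INDEX] = 0.0
        self.embedding = Tensor(np.asarray(embeddings, dtype=np.float64), requires_grad=True)
        self.stack = [
            BiLSTM(D if i == 0 else 2 * H, H, rng) for i in range(config.lstm_layers)
        ]

    @property
    def output_dim(self) -> int:
        return self.config.output_dim

    def encode_batch(
        self,
        sentences: list[list[int]],
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        ids, lengths = _pad_batch(sentences)
        H = self.config.lstm_state_size
        x = self.embedding[ids]
        for i, layer in enumerate(self.stack):
            if i and train and self.config.dropout_rate > 0:
                x = dropout(x, self.config.dropout_rate, rng)
            x = layer(x, lengths)  # (B, L, 2H)
        fwd = x[(slice(None), slice(None), slice(0, H))]
        final_fwd = gather_time(fwd, lengths - 1)
        final_bwd = x[(slice(None), 0, slice(H, 2 * H))]
        out = concatenate([final_fwd, final_bwd], axis=1)
        if train and self.config.dropout_rate > 0:
            out = dropout(out, self.config.dropout_rate, rng)
        return out

    def parameters(self) -> list[Tensor]:
        params = [self.embedding]
        for layer in self.stack:
            params.extend(layer.parameters())
        return params


def build_encoder(
    config: EncoderConfig,
    vocab_size: int,
    rng: np.random.Generator,
    embeddings: np.ndarray | None = None,
):
    cls = CNNEncoder if config.kind == "cnn" else BiLSTMEncoder
    return cls(config, vocab_size, rng, embeddings)


def encode_cnn(sentence: list[int], encoder: CNNEncoder) -> np.ndarray:
    """Encode one sentence (evaluation mode) with a CNN extractor."""
    if len(sentence) < 1:
        raise ValueError("empty sentence cannot be encoded")
    return encoder.encode_batch([list(sentence)]).data[0]


def encode_bilstm(sentence: list[int], encoder: BiLSTMEncoder) -> np.ndarray:
    """Encode one sentence (evaluation mode) with a bi-LSTM extractor."""
    if len(sentence) < 1:
        raise ValueError("empty sentence cannot be encoded")
    return encoder.encode_batch([list(sentence)]).data[0]


def encode_note(note: AnnotatedNote, encoder, vocabulary: Vocabulary) -> list[np.ndarray]:
    """Encode every sentence of a note, preserving order (evaluation mode)."""
    if len(note) < 1:
        raise ValueError("note has no sentences")
    batch = [vocabulary.encode_sentence(s) for s in note.sentences]
    enc = encoder.encode_batch(batch)
    return [enc.data[i] for i in range(len(batch))]
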
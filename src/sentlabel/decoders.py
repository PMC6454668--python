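"""Sequence labellers over sentence encodings.

Four decoding strategies assign one event label per short sentence:

* independent classification — affine + softmax per sentence;
* bi-LSTM decoder — a 1-layer bidirectional LSTM over the note's
  sentence encodings, then per-position softmax;
* linear-chain CRF — jointly normalized path scores with learned
  transition/start/stop parameters, trained by maximum likelihood;
* smoothed Viterbi — the empirical label-transition matrix of the
  training corpus, exponent-smoothed by a factor ``c`` and combined with
  the independent classifier's probabilities in a Viterbi decode.  No
  decoder parameters are trained.

The smoothing rescales each transition row as

    T_hat[i, j] = T[i, j]**c / sum_k T[i, k]**c

so ``c = 0`` yields uniform transitions (pure classification) and
``c = 1`` recovers the raw empirical transitions.  The classifier's
probabilities and the corpus transition statistics come from different
estimators; the exponent damps the transition matrix so it guides rather
than dominates the decode.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .autodiff import Tensor, logsumexp
from .corpus import Corpus
from .layers import BiLSTM, Linear, softmax

__all__ = [
    "DecodePath",
    "TransitionModel",
    "SoftmaxHead",
    "BiLSTMDecoder",
    "CRF",
    "classify_independent",
    "estimate_transitions",
    "smooth_transitions",
    "viterbi_decode",
    "bilstm_decode",
    "crf_log_partition",
    "crf_nll",
    "crf_decode",
]

LOG_FLOOR = -1e9


def _safe_log(p: np.ndarray) -> np.ndarray:
    """Elementwise log with zero probabilities floored at LOG_FLOOR."""
    out = np.full_like(p, LOG_FLOOR, dtype=np.float64)
    np.log(p, out=out, where=p > 0)
    return np.maximum(out, LOG_FLOOR)


@dataclass
class DecodePath:
    labels: list[int]
    score: float


@dataclass
class TransitionModel:
    """Empirical next-label statistics with pseudocount and smoothing state.

    ``raw_probs[i, j] = (counts[i, j] + eps) / sum_k (counts[i, k] + eps)``;
    ``smoothed_probs`` applies the exponent ``c`` row-wise (and likewise to
    the initial distribution).  Transitions never cross note boundaries.
    """

    counts: np.ndarray
    initial_counts: np.ndarray
    pseudocount: float
    raw_probs: np.ndarray
    raw_initial: np.ndarray
    smoothing_factor: float | None = None
    smoothed_probs: np.ndarray | None = None
    smoothed_initial: np.ndarray | None = None

    @property
    def n_labels(self) -> int:
        return self.counts.shape[0]

    def to_text(self, path: str | Path, label_names: list[str] | None = None) -> None:
        """Write the raw probability matrix as an inspectable text table."""
        k = self.n_labels
        names = label_names or [str(i) for i in range(k)]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(names) + "\n")
            for i in range(k):
                fh.write("\t".join(f"{x:.10g}" for x in self.raw_probs[i]) + "\n")


def classify_independent(encodings, head: "SoftmaxHead") -> np.ndarray:
    """Per-sentence label distributions: affine map + softmax, independently.

    ``encodings`` is a (T, D) array (or Tensor); the result is a (T, K)
    row-stochastic array.
    """
    if isinstance(encodings, Tensor):
        encodings = encodings.data
    encodings = np.asarray(encodings, dtype=np.float64)
    if encodings.ndim != 2 or encodings.shape[0] == 0:
        raise ValueError("expected a nonempty (T, D) array of encodings")
    logits = head.logits(Tensor(encodings))
    return softmax(logits, axis=-1).data


class SoftmaxHead:
    """Fully connected softmax layer mapping encodings to K label scores."""

    def __init__(self, in_dim: int, n_labels: int, rng: np.random.Generator):
        self.linear = Linear(in_dim, n_labels, rng)
        self.n_labels = n_labels

    def logits(self, encodings: Tensor) -> Tensor:
        if encodings.shape[-1] != self.linear.W.shape[0]:
            raise ValueError(
                f"encoding dim {encodings.shape[-1]} does not match head "
                f"input dim {self.linear.W.shape[0]}"
            )
        return self.linear(encodings)

    def parameters(self) -> list[Tensor]:
        return self.linear.parameters()


def estimate_transitions(corpus: Corpus, pseudocount: float = 1.0) -> TransitionModel:
    """Count label bigrams within notes and first-sentence labels.

    ``pseudocount`` (default 1) is added to every cell before row
    normalization so unseen transitions keep strictly positive mass.
    """
    if not corpus.is_labelled:
        raise ValueError("transition estimation requires a fully labelled corpus")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    k = len(corpus.label_set)
    counts = np.zeros((k, k), dtype=np.int64)
    initial = np.zeros(k, dtype=np.int64)
    for note in corpus.notes:
        labels = note.labels
        initial[labels[0]] += 1
        for a, b in zip(labels[:-1], labels[1:]):
            counts[a, b] += 1
    raw = counts + pseudocount
    row_sums = raw.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        raise ValueError(
            "zero pseudocount with an unobserved label row cannot be normalized"
        )
    init = initial + pseudocount
    if init.sum() == 0:
        raise ValueError("zero pseudocount with no initial observations")
    return TransitionModel(
        counts=counts,
        initial_counts=initial,
        pseudocount=float(pseudocount),
        raw_probs=raw / row_sums,
        raw_initial=init / init.sum(),
    )


def smooth_transitions(model: TransitionModel, c: float) -> TransitionModel:
    """Exponent-smooth every transition row (and the initial distribution)."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"smoothing factor must lie in [0, 1], got {c}")
    if c == 0.0 and (model.raw_probs <= 0).any():
        raise ValueError("c=0 requires strictly positive raw probabilities")
    powered = model.raw_probs**c
    smoothed = powered / powered.sum(axis=1, keepdims=True)
    pinit = model.raw_initial**c
    return replace(
        model,
        smoothing_factor=float(c),
        smoothed_probs=smoothed,
        smoothed_initial=pinit / pinit.sum(),
    )


def viterbi_decode(
    emissions: np.ndarray,
    transitions: TransitionModel,
    use_initial: bool = True,
) -> DecodePath:
    """Maximum-score label path under smoothed transitions (log domain).

    Score of a path y is ``log p_init(y1) + log e_1(y1) +
    sum_t [log T_hat(y_{t-1}, y_t) + log e_t(y_t)]``.  Zero probabilities
    are floored at exp(LOG_FLOOR); ties break toward the lower label index.
    """
    emissions = np.asarray(emissions, dtype=np.float64)
    if emissions.ndim != 2 or emissions.shape[0] == 0:
        raise ValueError("expected a nonempty (T, K) emission array")
    if transitions.smoothed_probs is None:
        raise ValueError("transition model must be smoothed before decoding")
    log_e = _safe_log(emissions)
    log_t = _safe_log(transitions.smoothed_probs)
    T, K = emissions.shape
    delta = log_e[0].copy()
    if use_initial:
        delta += _safe_log(transitions.smoothed_initial)
    back = np.zeros((T, K), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + log_t  # (prev, next)
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + log_e[t]
    path = [int(delta.argmax())]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return DecodePath(labels=path, score=float(delta.max()))


class BiLSTMDecoder:
    """1-layer bi-LSTM over a note's sentence encodings + softmax head."""

    def __init__(self, in_dim: int, n_labels: int, rng: np.random.Generator,
                 state_size: int = 128):
        self.bilstm = BiLSTM(in_dim, state_size, rng)
        self.head = Linear(2 * state_size, n_labels, rng)
        self.n_labels = n_labels
        self.state_size = state_size

    def logits(self, encodings: Tensor, lengths: np.ndarray) -> Tensor:
        """(B, T, D) padded batch of notes -> (B, T, K) label scores."""
        return self.head(self.bilstm(encodings, lengths))

    def parameters(self) -> list[Tensor]:
        return self.bilstm.parameters() + self.head.parameters()


def bilstm_decode(encodings, decoder: BiLSTMDecoder) -> np.ndarray:
    """Per-position label distributions for one note's encoding sequence."""
    if isinstance(encodings, Tensor):
        encodings = encodings.data
    encodings = np.asarray(encodings, dtype=np.float64)
    if encodings.ndim != 2 or encodings.shape[0] == 0:
        raise ValueError("expected a nonempty (T, D) array of encodings")
    if encodings.shape[1] != decoder.bilstm.fwd.W_ih.shape[0]:
        raise ValueError("encoding dim does not match decoder input dim")
    T = encodings.shape[0]
    logits = decoder.logits(Tensor(encodings[None, :, :]), np.array([T]))
    return softmax(logits, axis=-1).data[0]


class CRF:
    """Linear-chain CRF parameters: transition, start and stop scores."""

    def __init__(self, n_labels: int, rng: np.random.Generator):
        scale = 0.1
        self.transitions = Tensor(rng.uniform(-scale, scale, (n_labels, n_labels)),
                                  requires_grad=True)
        self.start = Tensor(rng.uniform(-scale, scale, n_labels), requires_grad=True)
        self.stop = Tensor(rng.uniform(-scale, scale, n_labels), requires_grad=True)
        self.n_labels = n_labels

    def parameters(self) -> list[Tensor]:
        return [self.transitions, self.start, self.stop]


def crf_log_partition(emission_scores, crf: CRF) -> Tensor:
    """log-sum-exp over all K^T path scores, by the forward recursion."""
    e = emission_scores if isinstance(emission_scores, Tensor) else Tensor(emission_scores)
    if not np.isfinite(e.data).all():
        raise ValueError("emission scores must be finite")
    T, K = e.shape
    if T < 1:
        raise ValueError("need at least one position")
    alpha = crf.start + e[(0,)]
    for t in range(1, T):
        cand = alpha.reshape(K, 1) + crf.transitions + e[(t,)].reshape(1, K)
        alpha = logsumexp(cand, axis=0)
    return logsumexp(alpha + crf.stop, axis=0)


def crf_path_score(emission_scores, labels, crf: CRF) -> Tensor:
    """Score of one label path under the CRF (differentiable)."""
    e = emission_scores if isinstance(emission_scores, Tensor) else Tensor(emission_scores)
    labels = np.asarray(labels, dtype=np.intp)
    T = e.shape[0]
    score = crf.start[(labels[0],)] + e[(0, labels[0])]
    for t in range(1, T):
        score = score + crf.transitions[(labels[t - 1], labels[t])] + e[(t, labels[t])]
    return score + crf.stop[(labels[-1],)]


def crf_nll(emission_scores, labels, crf: CRF) -> Tensor:
    """Negative log-likelihood: log-partition minus the gold path score."""
    labels = np.asarray(labels, dtype=np.intp)
    e = emission_scores if isinstance(emission_scores, Tensor) else Tensor(emission_scores)
    if len(labels) != e.shape[0]:
        raise ValueError("labels and emission scores must have equal length")
    return crf_log_partition(e, crf) - crf_path_score(e, labels, crf)


def crf_decode(emission_scores, crf: CRF) -> DecodePath:
    """Max-score Viterbi decode; ties toward the lower label index."""
    e = emission_scores.data if isinstance(emission_scores, Tensor) else np.asarray(
        emission_scores, dtype=np.float64
    )
    if not np.isfinite(e).all():
        raise ValueError("emission scores must be finite")
    T, K = e.shape
    trans = crf.transitions.data
    delta = crf.start.data + e[0]
    back = np.zeros((T, K), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + trans
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + e[t]
    delta = delta + crf.stop.data
    path = [int(delta.argmax())]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return DecodePath(labels=path, score=float(delta.max()))
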
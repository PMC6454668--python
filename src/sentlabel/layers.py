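"""Neural building blocks: linear maps, LSTMs, Adam, cross-entropy.

All parameters are float64 :class:`~sentlabel.autodiff.Tensor` objects
with ``requires_grad=True``; initialization is fully determined by the
``numpy`` generator passed in.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, logsumexp

__all__ = [
    "Linear",
    "LSTM",
    "BiLSTM",
    "Adam",
    "softmax",
    "cross_entropy",
    "reverse_time",
    "gather_time",
]


class Linear:
    """Affine map ``x @ W + b``; Glorot-uniform initialized."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = Tensor(rng.uniform(-bound, bound, size=(in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


def gather_time(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select ``x[b, idx[b], :]`` for each batch row (B,L,D) -> (B,D)."""
    b = np.arange(x.shape[0])
    return x[(b, np.asarray(idx, dtype=np.intp))]


def reverse_time(x: Tensor, lengths: np.ndarray) -> Tensor:
    """Reverse each row's first ``lengths[b]`` timesteps; padding stays put."""
    B, L = x.shape[0], x.shape[1]
    t = np.arange(L)[None, :]
    lens = np.asarray(lengths, dtype=np.intp)[:, None]
    idx = np.where(t < lens, lens - 1 - t, t)
    b = np.arange(B)[:, None]
    return x[(b, idx)]


class LSTM:
    """Unidirectional LSTM over (B, L, D) input; returns (B, L, H) states.

    Gate order inside the fused weight matrices is input, forget, cell,
    output; forget-gate bias starts at 1.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(hidden)
        self.W_ih = Tensor(rng.uniform(-scale, scale, size=(in_dim, 4 * hidden)), requires_grad=True)
        self.W_hh = Tensor(rng.uniform(-scale, scale, size=(hidden, 4 * hidden)), requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outputs: list[Tensor] = []
        for t in range(L):
            xt = x[(slice(None), t)]
            gates = xt @ self.W_ih + h @ self.W_hh + self.b
            i = gates[(slice(None), slice(0, H))].sigmoid()
            f = gates[(slice(None), slice(H, 2 * H))].sigmoid()
            g = gates[(slice(None), slice(2 * H, 3 * H))].tanh()
            o = gates[(slice(None), slice(3 * H, 4 * H))].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs.append(h.reshape(B, 1, H))
        return concatenate(outputs, axis=1)

    def parameters(self) -> list[Tensor]:
        return [self.W_ih, self.W_hh, self.b]


class BiLSTM:
    """Bidirectional LSTM; output concatenates forward and backward states.

    The backward pass runs the reversed sequence (per-row true lengths)
    through its own LSTM and un-reverses the result, so position ``t``
    of the output holds the backward state computed from tokens t..end.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(in_dim, hidden, rng)
        self.bwd = LSTM(in_dim, hidden, rng)
        self.hidden = hidden

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        out_f = self.fwd(x)
        out_b = reverse_time(self.bwd(reverse_time(x, lengths)), lengths)
        return concatenate([out_f, out_b], axis=2)

    def parameters(self) -> list[Tensor]:
        return self.fwd.parameters() + self.bwd.parameters()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return (x - logsumexp(x, axis=axis, keepdims=True)).exp()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of ``labels`` under softmax(logits)."""
    labels = np.asarray(labels, dtype=np.intp)
    lse = logsumexp(logits, axis=-1)
    gold = logits[(np.arange(len(labels)), labels)]
    return (lse - gold).mean()


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
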
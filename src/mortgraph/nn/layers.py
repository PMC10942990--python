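"""Neural layers used by the mortality forecasters.

Layers hold their parameters as :class:`~mortgraph.nn.autodiff.Tensor`
leaves and expose ``parameters()`` for the optimizer. Initialization draws
from a caller-supplied ``numpy.random.Generator`` so that model construction
is fully reproducible: building the same architecture from the same seed
yields bit-identical parameters.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module", "Linear", "LayerNorm", "MultiHeadAttention", "FeedForward",
    "EncoderLayer", "GCNLayer", "RNNCore", "LSTMCore", "Conv1dCore",
    "positional_encoding", "attention", "Adam",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: recursive parameter collection over attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Normalisation over the last axis with learnable gain and shift."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self.shift = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gain + self.shift


def attention(q: Tensor, k: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention.

    ``q``, ``k`` must share their last dimension d_k; returns the weighted
    values and the attention weights (rows sum to 1).
    """
    d_k = q.shape[-1]
    if k.shape[-1] != d_k:
        raise ValueError(f"query/key dimension mismatch: {d_k} vs {k.shape[-1]}")
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (
        1.0 / np.sqrt(d_k)
    )
    weights = scores.softmax(axis=-1)
    return weights @ v, weights


class MultiHeadAttention(Module):
    """h parallel attention heads on learned projections, re-projected.

    d_k = d_v = d_model / h; the per-head projections are stored as one
    (d_model, d_model) matrix each and reshaped into heads.
    """

    def __init__(self, d_model: int, h: int, rng: np.random.Generator):
        if d_model % h != 0:
            raise ValueError(f"d_model={d_model} not divisible by h={h}")
        self.d_model, self.h, self.d_k = d_model, h, d_model // h
        self.w_q = Tensor(_glorot(rng, d_model, d_model), requires_grad=True)
        self.w_k = Tensor(_glorot(rng, d_model, d_model), requires_grad=True)
        self.w_v = Tensor(_glorot(rng, d_model, d_model), requires_grad=True)
        self.w_o = Tensor(_glorot(rng, d_model, d_model), requires_grad=True)

    def _split(self, x: Tensor, batch: int, seq: int) -> Tensor:
        # (B, T, d_model) -> (B, h, T, d_k)
        return x.reshape(batch, seq, self.h, self.d_k).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, return_weights: bool = False):
        batch, seq, _ = x.shape
        q = self._split(x @ self.w_q, batch, seq)
        k = self._split(x @ self.w_k, batch, seq)
        v = self._split(x @ self.w_v, batch, seq)
        ctx, weights = attention(q, k, v)
        merged = ctx.transpose(0, 2, 1, 3).reshape(batch, seq, self.d_model)
        out = merged @ self.w_o
        if return_weights:
            return out, weights
        return out


class FeedForward(Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.lin1 = Linear(d_model, d_ff, rng)
        self.lin2 = Linear(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when p == 0 or no generator is supplied."""
    if p <= 0.0 or rng is None:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class EncoderLayer(Module):
    """Post-norm transformer encoder block: MHA + FFN with residuals.

    Dropout (when requested during training) acts on the two residual
    branches before each add-and-norm.
    """

    def __init__(self, d_model: int, h: int, d_ff: int, rng: np.random.Generator):
        self.mha = MultiHeadAttention(d_model, h, rng)
        self.norm1 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, d_ff, rng)
        self.norm2 = LayerNorm(d_model)

    def __call__(self, x: Tensor, drop_p: float = 0.0,
                 drop_rng: np.random.Generator | None = None) -> Tensor:
        x = self.norm1(x + dropout(self.mha(x), drop_p, drop_rng))
        return self.norm2(x + dropout(self.ffn(x), drop_p, drop_rng))


class GCNLayer(Module):
    """One graph-convolution layer: sigma(P X W + b).

    ``P`` is the symmetric-normalised propagation matrix (constant or a
    differentiable tensor when the adaptive graph parameters are trained);
    the layer is applied independently at each time step.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 activation: str = "relu"):
        self.weight = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)
        if activation not in ("relu", "identity", "tanh"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation

    def __call__(self, p, x: Tensor) -> Tensor:
        p = p if isinstance(p, Tensor) else Tensor(p)
        if p.shape[-1] != x.shape[-2]:
            raise ValueError(
                f"propagation matrix {p.shape} does not match features {x.shape}"
            )
        h = p @ x @ self.weight + self.bias
        if self.activation == "relu":
            return h.relu()
        if self.activation == "tanh":
            return h.tanh()
        return h


class RNNCore(Module):
    """Plain tanh recurrence over (B, T, d_in); returns last hidden state."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.w_x = Tensor(_glorot(rng, d_in, d_hidden), requires_grad=True)
        self.w_h = Tensor(_glorot(rng, d_hidden, d_hidden), requires_grad=True)
        self.bias = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.d_hidden = d_hidden

    def __call__(self, x: Tensor) -> Tensor:
        batch, seq, _ = x.shape
        h = Tensor(np.zeros((batch, self.d_hidden)))
        for step in range(seq):
            h = (x[:, step, :] @ self.w_x + h @ self.w_h + self.bias).tanh()
        return h


class LSTMCore(Module):
    """Single-layer LSTM over (B, T, d_in); returns last hidden state.

    Gate order in the stacked weight matrices is input, forget, cell, output.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.w_x = Tensor(_glorot(rng, d_in, 4 * d_hidden), requires_grad=True)
        self.w_h = Tensor(_glorot(rng, d_hidden, 4 * d_hidden), requires_grad=True)
        bias = np.zeros(4 * d_hidden)
        bias[d_hidden:2 * d_hidden] = 1.0  # forget-gate bias init
        self.bias = Tensor(bias, requires_grad=True)
        self.d_hidden = d_hidden

    def __call__(self, x: Tensor) -> Tensor:
        batch, seq, _ = x.shape
        n = self.d_hidden
        h = Tensor(np.zeros((batch, n)))
        c = Tensor(np.zeros((batch, n)))
        for step in range(seq):
            z = x[:, step, :] @ self.w_x + h @ self.w_h + self.bias
            i = z[:, 0 * n:1 * n].sigmoid()
            f = z[:, 1 * n:2 * n].sigmoid()
            g = z[:, 2 * n:3 * n].tanh()
            o = z[:, 3 * n:4 * n].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class Conv1dCore(Module):
    """Two causal 1-D convolutions over time, ReLU between; last position out."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator,
                 kernel: int = 3):
        self.kernel = kernel
        self.w1 = [Tensor(_glorot(rng, d_in * kernel, d_hidden, (d_in, d_hidden)),
                          requires_grad=True) for _ in range(kernel)]
        self.b1 = Tensor(np.zeros(d_hidden), requires_grad=True)
        self.w2 = [Tensor(_glorot(rng, d_hidden * kernel, d_hidden,
                                  (d_hidden, d_hidden)), requires_grad=True)
                   for _ in range(kernel)]
        self.b2 = Tensor(np.zeros(d_hidden), requires_grad=True)

    def _conv(self, x: Tensor, weights, bias) -> Tensor:
        batch, seq, _ = x.shape
        outs = []
        for t in range(seq):
            acc = None
            for k, w in enumerate(weights):
                src = t - (len(weights) - 1) + k  # causal: looks back in time
                if src < 0:
                    continue
                term = x[:, src, :] @ w
                acc = term if acc is None else acc + term
            outs.append((acc + bias).reshape(batch, 1, -1))
        return concat(outs, axis=1)

    def __call__(self, x: Tensor) -> Tensor:
        h = self._conv(x, self.w1, self.b1).relu()
        h = self._conv(h, self.w2, self.b2).relu()
        return h[:, -1, :]


def positional_encoding(seq_len: int, d_model: int) -> np.ndarray:
    """Sinusoidal positional-encoding table of shape (seq_len, d_model)."""
    pos = np.arange(seq_len)[:, None].astype(np.float64)
    i = np.arange(d_model)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, (2.0 * np.floor(i / 2.0)) / d_model)
    table = np.zeros((seq_len, d_model))
    table[:, 0::2] = np.sin(angle[:, 0::2])
    table[:, 1::2] = np.cos(angle[:, 1::2])
    return table


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
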
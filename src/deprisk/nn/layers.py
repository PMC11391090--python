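"""Neural building blocks: linear maps, layer norm, multi-head self-attention,
transformer encoder layers, LSTM/GRU recurrences, additive attention pooling,
and a 1-D text CNN — all on the package's autodiff tensors.

Conventions (shared with the straight-line oracle used in the tests):

* post-norm transformer blocks: ``x = LN(x + SelfAttn(x)); x = LN(x + FFN(x))``
* attention scores scaled by ``1/sqrt(d_head)``; padded keys receive an
  additive ``-1e9`` before the softmax
* layer norm uses the biased variance and ``eps = 1e-5``
* LSTM gate order ``i, f, g, o``; GRU gate order ``r, z, n`` with the
  candidate ``n = tanh(x W_xn + r * (h W_hn) + b_n)``
* sinusoidal positional encodings: ``pe[p, 2i] = sin(p / 10000^(2i/d))``,
  ``pe[p, 2i+1] = cos(p / 10000^(2i/d))`` (so position 0 is 0,1,0,1,...)
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, concatenate, layer_norm, softmax, stack

NEG_INF = -1e9
LN_EPS = 1e-5


class Module:
    """Bare-bones parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        out = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


def positional_encoding(length: int, d_model: int) -> np.ndarray:
    """Fixed sinusoidal position table of shape (length, d_model)."""
    pos = np.arange(length, dtype=np.float64)[:, None]
    i = np.arange(d_model, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, (2.0 * (i // 2)) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when p == 0 or rng is None (eval mode)."""
    if p <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = glorot(rng, n_in, n_out)
        self.b = zeros((n_out,))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = zeros((dim,))
        self.dim = dim

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, LN_EPS)


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        """x: (B, T, d); key_mask: (B, T) with 1 for real positions."""
        B, T, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B, T, d) -> (B, h, T, dh)
            return t.reshape(B, T, h, dh).transpose((0, 2, 1, 3))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(dh))
        bias = (1.0 - np.asarray(key_mask, dtype=np.float64)) * NEG_INF
        scores = scores + Tensor(bias[:, None, None, :])
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(B, T, d)
        return self.wo(ctx)


class TransformerLayer(Module):
    def __init__(self, d_model: int, n_heads: int, ffn_mult: int, rng):
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_model * ffn_mult, rng)
        self.ff2 = Linear(d_model * ffn_mult, d_model, rng)
        self.ln2 = LayerNorm(d_model)

    def __call__(self, x: Tensor, key_mask: np.ndarray,
                 drop: float = 0.0, rng=None) -> Tensor:
        x = self.ln1(x + dropout(self.attn(x, key_mask), drop, rng))
        ff = self.ff2(self.ff1(x).relu())
        return self.ln2(x + dropout(ff, drop, rng))


class TransformerEncoder(Module):
    """Stack of post-norm transformer layers with sinusoidal positions."""

    def __init__(self, d_model: int, n_heads: int, n_layers: int, ffn_mult: int,
                 rng, use_positions: bool = True):
        self.d_model = d_model
        self.use_positions = use_positions
        self.layers = [TransformerLayer(d_model, n_heads, ffn_mult, rng)
                       for _ in range(n_layers)]

    def __call__(self, x: Tensor, key_mask: np.ndarray,
                 drop: float = 0.0, rng=None) -> Tensor:
        if self.use_positions:
            x = x + Tensor(positional_encoding(x.shape[1], self.d_model))
        for layer in self.layers:
            x = layer(x, key_mask, drop, rng)
        return x


class LSTM(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx = glorot(rng, n_in, 4 * hidden)
        self.wh = glorot(rng, hidden, 4 * hidden)
        self.b = zeros((4 * hidden,))

    def step(self, xt: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        g = xt @ self.wx + h @ self.wh + self.b
        H = self.hidden
        i = g[:, 0 * H:1 * H].sigmoid()
        f = g[:, 1 * H:2 * H].sigmoid()
        n = g[:, 2 * H:3 * H].tanh()
        o = g[:, 3 * H:4 * H].sigmoid()
        c_new = f * c + i * n
        h_new = o * c_new.tanh()
        return h_new, c_new

    def __call__(self, x: Tensor, mask: np.ndarray, reverse: bool = False) -> Tensor:
        """x: (B, T, n_in); mask: (B, T). Returns hidden states (B, T, hidden).

        Masked steps carry the previous state through unchanged, so trailing
        padding never alters the states of real positions.
        """
        B, T, _ = x.shape
        h = Tensor(np.zeros((B, self.hidden)))
        c = Tensor(np.zeros((B, self.hidden)))
        order = range(T - 1, -1, -1) if reverse else range(T)
        outs: list[Tensor | None] = [None] * T
        for t in order:
            m = Tensor(mask[:, t:t + 1].astype(np.float64))
            h_new, c_new = self.step(x[:, t, :], h, c)
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
            outs[t] = h
        return stack(outs, axis=1)


class GRU(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx = glorot(rng, n_in, 3 * hidden)
        self.wh = glorot(rng, hidden, 3 * hidden)
        self.b = zeros((3 * hidden,))

    def __call__(self, x: Tensor, mask: np.ndarray, reverse: bool = False) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        order = range(T - 1, -1, -1) if reverse else range(T)
        outs: list[Tensor | None] = [None] * T
        for t in order:
            m = Tensor(mask[:, t:t + 1].astype(np.float64))
            gx = x[:, t, :] @ self.wx + self.b
            gh = h @ self.wh
            r = (gx[:, 0 * H:1 * H] + gh[:, 0 * H:1 * H]).sigmoid()
            z = (gx[:, 1 * H:2 * H] + gh[:, 1 * H:2 * H]).sigmoid()
            n = (gx[:, 2 * H:3 * H] + r * gh[:, 2 * H:3 * H]).tanh()
            h_new = (1.0 - z) * n + z * h
            h = m * h_new + (1.0 - m) * h
            outs[t] = h
        return stack(outs, axis=1)


class AdditiveAttention(Module):
    """Bahdanau-style pooling: alpha_i = softmax(v' tanh(W h_i)), sum alpha h."""

    def __init__(self, d_in: int, attn_size: int, rng: np.random.Generator):
        self.W = glorot(rng, d_in, attn_size)
        self.v = glorot(rng, attn_size, 1)

    def weights(self, hs: Tensor, mask: np.ndarray) -> Tensor:
        scores = ((hs @ self.W).tanh() @ self.v).reshape(hs.shape[0], hs.shape[1])
        bias = (1.0 - np.asarray(mask, dtype=np.float64)) * NEG_INF
        return softmax(scores + Tensor(bias), axis=-1)

    def __call__(self, hs: Tensor, mask: np.ndarray) -> Tensor:
        alpha = self.weights(hs, mask)
        return (alpha.reshape(hs.shape[0], hs.shape[1], 1) * hs).sum(axis=1)


class TextCNN(Module):
    """Parallel 1-D convolutions with max-over-time pooling.

    Each kernel size k is a linear map over the k*d window; output is the
    concatenation over kernel sizes (width = sum of filter counts).
    """

    def __init__(self, d_in: int, kernel_sizes: tuple[int, ...], filters: int, rng):
        self.kernel_sizes = tuple(kernel_sizes)
        self.filters = filters
        self.convs = [Linear(k * d_in, filters, rng) for k in self.kernel_sizes]

    @property
    def out_dim(self) -> int:
        return self.filters * len(self.kernel_sizes)

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        """x: (B, L, d) padded; lengths: (B,) valid token counts (>= 1)."""
        B, L, d = x.shape
        pooled = []
        for k, conv in zip(self.kernel_sizes, self.convs):
            if L < k:  # pad so at least one window exists
                pad = Tensor(np.zeros((B, k - L, d)))
                xk, Lk = concatenate([x, pad], axis=1), k
            else:
                xk, Lk = x, L
            windows = concatenate([xk[:, i:Lk - k + 1 + i, :] for i in range(k)],
                                  axis=-1)  # (B, Lk-k+1, k*d)
            feat = conv(windows).relu()
            n_win = Lk - k + 1
            # windows starting past the last valid start are masked out
            starts = np.arange(n_win)[None, :]
            valid_start = np.maximum(np.asarray(lengths)[:, None] - k, 0)
            win_mask = starts <= valid_start
            feat = feat + Tensor(((~win_mask)[:, :, None]) * NEG_INF)
            pooled.append(feat.max(axis=1))
        return concatenate(pooled, axis=-1)
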
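"""Neural-network building blocks on the autodiff core.

All layers are deterministic given the NumPy Generator used at construction;
there is no dropout or other train-time stochasticity, so "eval mode" is
simply running the forward pass.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module", "Linear", "Embedding", "Conv1dSame", "LayerNorm",
    "MultiHeadSelfAttention", "TransformerBlock", "GATLayer",
    "sinusoidal_positions", "bce_with_logits",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape or (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Parameter container; submodules registered via attributes."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        for p, a in zip(self.parameters(), arrays, strict=True):
            p.data = np.asarray(a, dtype=np.float64).reshape(p.shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        self.table = Tensor(rng.normal(0.0, 0.1, size=(vocab_size, dim)),
                            requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.table[np.asarray(ids, dtype=np.intp)]


class Conv1dSame(Module):
    """1D convolution over (batch, length, channels) with zero 'same' padding.

    Implemented as a sum of shifted slices times per-offset weight matrices,
    which keeps the autodiff graph to plain matmuls.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        self.W = Tensor(_glorot(rng, kernel * c_in, c_out, (kernel, c_in, c_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        half = self.kernel // 2
        pad = Tensor(np.zeros((B, half, x.shape[2])))
        xp = concat([pad, x, pad], axis=1)
        out = None
        for k in range(self.kernel):
            term = xp[:, k:k + L, :] @ self.W[k]
            out = term if out is None else out + term
        return out + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("dim must divide evenly across heads")
        self.heads = heads
        self.dh = dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        """key_mask: (B, L) with 1 at real tokens, 0 at padding."""
        B, L, D = x.shape

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, L, self.heads, self.dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (self.dh ** -0.5)
        bias = np.where(key_mask[:, None, None, :] > 0, 0.0, -1e9)
        attn = (scores + Tensor(bias)).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(out)


class TransformerBlock(Module):
    def __init__(self, dim: int, heads: int, ff_mult: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ln1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_mult * dim, rng)
        self.ff2 = Linear(ff_mult * dim, dim, rng)
        self.ln2 = LayerNorm(dim)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.attn(x, key_mask))
        return self.ln2(x + self.ff2(self.ff1(x).relu()))


class GATLayer(Module):
    """Multi-head graph attention over dense-padded batched graphs.

    Inputs: node features (B, N, f), adjacency mask (B, N, N) that already
    includes self-loops and is 0 at padded rows/columns and non-edges.
    Head outputs are concatenated.
    """

    def __init__(self, f_in: int, f_out_per_head: int, heads: int,
                 rng: np.random.Generator):
        self.heads = heads
        self.W = [Tensor(_glorot(rng, f_in, f_out_per_head), requires_grad=True)
                  for _ in range(heads)]
        self.a_src = [Tensor(_glorot(rng, f_out_per_head, 1), requires_grad=True)
                      for _ in range(heads)]
        self.a_dst = [Tensor(_glorot(rng, f_out_per_head, 1), requires_grad=True)
                      for _ in range(heads)]

    def __call__(self, x: Tensor, adj: np.ndarray) -> Tensor:
        bias = np.where(adj > 0, 0.0, -1e9)
        outs = []
        for h in range(self.heads):
            wh = x @ self.W[h]                                # (B, N, d)
            src = wh @ self.a_src[h]                          # (B, N, 1)
            dst = (wh @ self.a_dst[h]).swapaxes(-1, -2)       # (B, 1, N)
            e = (src + dst).leaky_relu(0.2) + Tensor(bias)    # (B, N, N)
            attn = e.softmax(axis=-1)
            outs.append(attn @ wh)
        return concat(outs, axis=-1)


def sinusoidal_positions(max_len: int, dim: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.zeros((max_len, dim))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


def bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable mean binary cross-entropy from logits."""
    z = logits.reshape(-1).clip(-30.0, 30.0)
    yt = Tensor(np.asarray(y, dtype=np.float64).reshape(-1))
    # log(1 + e^z) - y z, written with softplus(z) = relu(z) + log1p(e^-|z|)
    abs_z = z.relu() + (z * -1.0).relu()
    softplus = z.relu() + ((abs_z * -1.0).exp() + 1.0).log()
    return (softplus - yt * z).mean()
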
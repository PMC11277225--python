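"""The three molecular encoders: sequence CNN, sequence Transformer, graph GAT.

Each encoder maps a molecule to a fixed-length feature vector and carries a
small supervised auxiliary head (a single logit) used only to give the
encoder a training signal; the head is discarded once features are extracted.
Padding positions and padded graph nodes are masked out everywhere, so
extending the padding of an input never changes an encoder's output.
"""

from __future__ import annotations

import numpy as np

from ..nn import (Adam, Conv1dSame, Embedding, GATLayer, Linear, Module,
                  Tensor, TransformerBlock, bce_with_logits,
                  sinusoidal_positions)
from .features import ATOM_FEATURE_DIM

__all__ = ["CNNEncoder", "TransformerEncoder", "GATEncoder", "train_encoder"]

_NEG_INF = -1e9


class CNNEncoder(Module):
    """Embedding -> stacked masked 1D convolutions -> masked global max-pool."""

    def __init__(self, vocab_size: int, embed_dim: int = 64,
                 channels: int = 64, kernels: tuple = (3, 5, 7),
                 out_dim: int = 64, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.embed = Embedding(vocab_size, embed_dim, rng)
        self.convs = [Conv1dSame(embed_dim if i == 0 else channels,
                                 channels, k, rng)
                      for i, k in enumerate(kernels)]
        self.proj = Linear(channels, out_dim, rng)
        self.head = Linear(out_dim, 1, rng)
        self.out_dim = out_dim

    def encode(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        m = Tensor(mask[:, :, None].astype(np.float64))
        x = self.embed(ids) * m
        for conv in self.convs:
            x = conv(x).relu() * m
        # masked global max-pool: padded positions pushed to -1e9
        pooled = (x + (m - 1.0) * (-_NEG_INF)).max(axis=1)
        return self.proj(pooled)

    def logits(self, ids, mask) -> Tensor:
        return self.head(self.encode(ids, mask))


class TransformerEncoder(Module):
    """Position-encoded self-attention blocks with masked mean pooling."""

    def __init__(self, vocab_size: int, max_len: int, dim: int = 64,
                 heads: int = 4, blocks: int = 2, out_dim: int = 64,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.embed = Embedding(vocab_size, dim, rng)
        self.pos = sinusoidal_positions(max_len, dim)
        self.blocks = [TransformerBlock(dim, heads, 4, rng)
                       for _ in range(blocks)]
        self.proj = Linear(dim, out_dim, rng)
        self.head = Linear(out_dim, 1, rng)
        self.out_dim = out_dim

    def encode(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        L = ids.shape[1]
        m = Tensor(mask[:, :, None].astype(np.float64))
        x = (self.embed(ids) + Tensor(self.pos[:L])) * m
        for blk in self.blocks:
            x = blk(x, mask)
        # mean over unmasked positions only
        denom = mask.sum(axis=1, keepdims=True).astype(np.float64)
        pooled = (x * m).sum(axis=1) * Tensor(1.0 / np.maximum(denom, 1.0))
        return self.proj(pooled)

    def logits(self, ids, mask) -> Tensor:
        return self.head(self.encode(ids, mask))


class GATEncoder(Module):
    """Two multi-head graph-attention layers with masked mean pooling."""

    def __init__(self, f_in: int = ATOM_FEATURE_DIM, hidden: int = 32,
                 heads: int = 4, out_dim: int = 64,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        if out_dim % heads:
            raise ValueError("out_dim must be divisible by the head count")
        self.gat1 = GATLayer(f_in, hidden, heads, rng)
        self.gat2 = GATLayer(hidden * heads, out_dim // heads, heads, rng)
        self.proj = Linear(out_dim, out_dim, rng)
        self.head = Linear(out_dim, 1, rng)
        self.out_dim = out_dim

    def encode(self, feats: np.ndarray, adj: np.ndarray,
               node_mask: np.ndarray) -> Tensor:
        m = Tensor(node_mask[:, :, None].astype(np.float64))
        x = self.gat1(Tensor(feats), adj).relu() * m
        x = self.gat2(x, adj).relu() * m
        denom = node_mask.sum(axis=1, keepdims=True).astype(np.float64)
        pooled = x.sum(axis=1) * Tensor(1.0 / np.maximum(denom, 1.0))
        return self.proj(pooled)

    def logits(self, feats, adj, node_mask) -> Tensor:
        return self.head(self.encode(feats, adj, node_mask))


def train_encoder(encoder: Module, batches_fn, val_fn, *, epochs: int,
                  lr: float, patience: int, shuffle_rng: np.random.Generator,
                  ) -> list[float]:
    """Supervised training loop with early stopping on validation loss.

    ``batches_fn(rng)`` yields (args, y) minibatches where ``args`` are the
    positional inputs of ``encoder.logits``; ``val_fn()`` returns the full
    validation (args, y).  The encoder is restored to its best-validation
    state before returning the per-epoch validation losses.
    """
    opt = Adam(encoder.parameters(), lr=lr)
    best_val, best_state, since_best = np.inf, None, 0
    history = []
    for _ in range(epochs):
        for args, y in batches_fn(shuffle_rng):
            opt.zero_grad()
            loss = bce_with_logits(encoder.logits(*args), y)
            loss.backward()
            opt.step()
        vargs, vy = val_fn()
        val_loss = float(bce_with_logits(encoder.logits(*vargs), vy).data)
        history.append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = [a.copy() for a in encoder.state_arrays()]
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best_state is not None:
        encoder.load_state_arrays(best_state)
    return history
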
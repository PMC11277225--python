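"""Variational autoencoder that fuses the concatenated encoder features.

A Gaussian-latent VAE: the encoder maps the fused feature vector to a mean
and log-variance, the reparameterization trick draws a differentiable latent
sample, and the decoder reconstructs the input.  Training minimizes squared
reconstruction error (summed over feature dimensions, averaged over the
batch) plus a weighted KL divergence to the standard normal prior.  At
inference the latent is the mean (sampling disabled), so downstream
predictions are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Adam, Linear, Module, Tensor

__all__ = ["LatentCode", "VAE", "kl_divergence_terms"]


@dataclass(frozen=True)
class LatentCode:
    """Latent mean / log-variance / sample triple for a batch."""

    mu: np.ndarray
    logvar: np.ndarray
    z: np.ndarray
    latent_dim: int

    def __post_init__(self):
        if not (self.mu.shape == self.logvar.shape == self.z.shape):
            raise ValueError("mu, logvar and z must share a shape")


def kl_divergence_terms(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Per-sample KL(q(z|x) || N(0, I)) = -1/2 sum(1 + logvar - mu^2 - e^logvar).

    Non-negative for every (mu, logvar), zero exactly when mu = 0, logvar = 0.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=np.float64))
    return -0.5 * np.sum(1.0 + logvar - mu ** 2 - np.exp(logvar), axis=1)


class VAE(Module):
    """MLP encoder/decoder VAE over fixed-length fused feature vectors."""

    def __init__(self, input_dim: int, latent_dim: int = 32,
                 hidden_dim: int = 128, kl_weight: float = 1.0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.input_dim = input_dim
        self.latent_dim = latent_dim
        self.kl_weight = kl_weight
        self.enc = Linear(input_dim, hidden_dim, rng)
        self.enc_mu = Linear(hidden_dim, latent_dim, rng)
        self.enc_logvar = Linear(hidden_dim, latent_dim, rng)
        self.dec1 = Linear(latent_dim, hidden_dim, rng)
        self.dec2 = Linear(hidden_dim, input_dim, rng)

    def _encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.enc(x).relu()
        return self.enc_mu(h), self.enc_logvar(h).clip(-10.0, 10.0)

    def _decode(self, z: Tensor) -> Tensor:
        return self.dec2(self.dec1(z).relu())

    def forward(self, x, sample: bool = False,
                rng: np.random.Generator | None = None,
                ) -> tuple[LatentCode, np.ndarray, dict]:
        """One pass; returns (latent code, reconstruction, loss terms).

        With ``sample`` off, z equals mu exactly.  Loss terms are scalars:
        ``recon`` (mean squared error), ``kl`` (batch-mean KL), ``total``.
        """
        xt = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))
        code, recon, loss = self._forward_graph(xt, sample=sample, rng=rng)
        latent = LatentCode(mu=code[0].data.copy(), logvar=code[1].data.copy(),
                            z=code[2].data.copy(), latent_dim=self.latent_dim)
        terms = {k: float(v.data) for k, v in loss.items()}
        return latent, recon.data.copy(), terms

    def _forward_graph(self, xt: Tensor, sample: bool,
                       rng: np.random.Generator | None):
        mu, logvar = self._encode(xt)
        if sample:
            if rng is None:
                raise ValueError("sampling requires a random generator")
            eps = Tensor(rng.standard_normal(mu.shape))
            z = mu + (logvar * 0.5).exp() * eps
        else:
            z = mu
        recon = self._decode(z)
        diff = recon - xt
        # squared error summed over feature dims (Gaussian log-likelihood
        # scaling), averaged over the batch: keeps reconstruction and the
        # dimension-summed KL on comparable scales so the posterior does not
        # collapse to the prior
        recon_loss = (diff * diff).sum(axis=-1).mean()
        kl = ((mu * mu + logvar.exp() - logvar - 1.0) * 0.5).sum(axis=-1).mean()
        total = recon_loss + kl * self.kl_weight
        return (mu, logvar, z), recon, {"recon": recon_loss, "kl": kl,
                                        "total": total}

    def loss_trace(self, x: np.ndarray, epochs: int, lr: float = 1e-3,
                   sample: bool = False, seed: int = 0) -> list[float]:
        """Full-batch training on a fixed batch, returning per-epoch total loss."""
        rng = np.random.default_rng(seed)
        opt = Adam(self.parameters(), lr=lr)
        xt = Tensor(np.atleast_2d(np.asarray(x, dtype=np.float64)))
        trace = []
        for _ in range(epochs):
            opt.zero_grad()
            _, _, loss = self._forward_graph(xt, sample=sample, rng=rng)
            trace.append(float(loss["total"].data))
            loss["total"].backward()
            opt.step()
        return trace

    def fit(self, X: np.ndarray, X_val: np.ndarray | None = None, *,
            epochs: int = 100, batch_size: int = 64, lr: float = 1e-3,
            patience: int = 10, sample: bool = True, seed: int = 0,
            ) -> list[float]:
        """Minibatch training with early stopping on validation total loss."""
        rng = np.random.default_rng(seed)
        opt = Adam(self.parameters(), lr=lr)
        X = np.asarray(X, dtype=np.float64)
        best_val, best_state, since_best = np.inf, None, 0
        history = []
        for _ in range(epochs):
            order = rng.permutation(X.shape[0])
            for start in range(0, X.shape[0], batch_size):
                xb = Tensor(X[order[start:start + batch_size]])
                opt.zero_grad()
                _, _, loss = self._forward_graph(xb, sample=sample, rng=rng)
                loss["total"].backward()
                opt.step()
            xv = X if X_val is None else np.asarray(X_val, dtype=np.float64)
            _, _, vloss = self._forward_graph(Tensor(xv), sample=False, rng=rng)
            val = float(vloss["total"].data)
            history.append(val)
            if val < best_val - 1e-6:
                best_val, since_best = val, 0
                best_state = [a.copy() for a in self.state_arrays()]
            else:
                since_best += 1
                if since_best >= patience:
                    break
        if best_state is not None:
            self.load_state_arrays(best_state)
        return history

    def latent_mean(self, X: np.ndarray) -> np.ndarray:
        mu, _ = self._encode(Tensor(np.atleast_2d(np.asarray(X, dtype=np.float64))))
        return mu.data.copy()
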
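"""The staged hybrid toxicity classifier.

Stage 1 trains the CNN, Transformer and GAT encoders with small supervised
auxiliary heads on the training part (early stopping on the validation
part).  Stage 2 freezes the encoders, concatenates their features in the
fixed order [CNN | Transformer | GAT], standardizes them, and trains the VAE
on the result.  Stage 3 fits a gradient-boosted decision-tree classifier on
the latent means of the training molecules.  All randomness flows from one
seed, and inference uses z = mu, so predictions are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted
import xgboost as xgb

from ..standardize import MoleculeRecord, Rejection, standardize_record
from .encoders import CNNEncoder, GATEncoder, TransformerEncoder, train_encoder
from .features import (build_vocab, pad_graph_batch, smiles_to_graph,
                       tokenize_smiles)
from .vae import VAE, LatentCode

__all__ = ["HybridConfig", "FusedFeatures", "fuse",
           "HybridToxicityClassifier", "train_hybrid", "predict_hybrid"]


@dataclass(frozen=True)
class HybridConfig:
    """All sizes, rates and seeds of the hybrid pipeline; every field is
    serialized into the run manifest."""

    max_len: int = 120
    embed_dim: int = 64
    cnn_channels: int = 64
    cnn_kernels: tuple = (3, 5, 7)
    d1: int = 64               # CNN feature width
    tfm_heads: int = 4
    tfm_blocks: int = 2
    d2: int = 64               # Transformer feature width
    gat_hidden: int = 32
    gat_heads: int = 4
    d3: int = 64               # GAT feature width
    latent_dim: int = 32
    kl_weight: float = 1.0
    encoder_epochs: int = 100
    vae_epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 10
    seed: int = 42
    xgb_n_estimators: int = 200
    xgb_max_depth: int = 4
    xgb_learning_rate: float = 0.1

    def __post_init__(self):
        for name in ("max_len", "embed_dim", "d1", "d2", "d3", "latent_dim",
                     "encoder_epochs", "vae_epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FusedFeatures:
    """Order-stable concatenation [CNN | Transformer | GAT] of encoder outputs."""

    vector: np.ndarray
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.vector.shape[-1] != sum(self.dims):
            raise ValueError("fused length must equal d1 + d2 + d3")


def fuse(c: np.ndarray, t: np.ndarray, g: np.ndarray) -> FusedFeatures:
    """Concatenate per-molecule encoder outputs in the order [CNN|Tfm|GAT]."""
    c, t, g = (np.atleast_2d(np.asarray(v, dtype=np.float64)) for v in (c, t, g))
    if not (c.shape[0] == t.shape[0] == g.shape[0]):
        raise ValueError("encoder outputs must align on the batch axis")
    return FusedFeatures(vector=np.concatenate([c, t, g], axis=1),
                         dims=(c.shape[1], t.shape[1], g.shape[1]))


class HybridToxicityClassifier(BaseEstimator, ClassifierMixin):
    """CNN + Transformer + GAT encoders fused through a VAE into a
    gradient-boosted tree classifier.

    ``fit`` takes SMILES strings (standardized) and binary labels plus an
    explicit validation part used for early stopping only.

    Attributes
    ----------
    vocab_ : token-to-id map built from the training SMILES.
    cnn_, transformer_, gat_ : the trained encoders.
    vae_ : the trained feature-fusion VAE.
    booster_ : the fitted XGBoost head.
    history_ : per-stage validation loss traces.
    """

    def __init__(self, config: HybridConfig | None = None):
        self.config = config

    # ------------------------------------------------------------ featurize
    def _token_arrays(self, smiles_list):
        cfg = self.config_
        seqs = [tokenize_smiles(s, self.vocab_, cfg.max_len)
                for s in smiles_list]
        ids = np.stack([s.token_ids for s in seqs])
        mask = np.stack([s.mask for s in seqs]).astype(np.float64)
        return ids, mask

    def _graph_arrays(self, smiles_list):
        graphs = [smiles_to_graph(s) for s in smiles_list]
        return pad_graph_batch(graphs)

    def _encode_all(self, smiles_list) -> np.ndarray:
        ids, mask = self._token_arrays(smiles_list)
        feats, adj, nmask = self._graph_arrays(smiles_list)
        out = []
        bs = self.config_.batch_size
        for start in range(0, len(smiles_list), bs):
            sl = slice(start, start + bs)
            c = self.cnn_.encode(ids[sl], mask[sl]).data
            t = self.transformer_.encode(ids[sl], mask[sl]).data
            g = self.gat_.encode(feats[sl], adj[sl], nmask[sl]).data
            out.append(fuse(c, t, g).vector)
        return np.concatenate(out, axis=0)

    def _normalize(self, F: np.ndarray) -> np.ndarray:
        return (F - self.feat_mean_) / self.feat_std_

    # ----------------------------------------------------------------- fit
    def fit(self, X, y, X_val=None, y_val=None):
        smiles = list(X)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        if X_val is None:
            raise ValueError("fit requires a validation part (X_val, y_val) "
                             "for early stopping")
        smiles_val = list(X_val)
        y_val = np.asarray(y_val).astype(int)
        cfg = self.config or HybridConfig()
        self.config_ = cfg
        root = np.random.default_rng(cfg.seed)
        init_rng = np.random.default_rng(root.integers(2 ** 31))
        shuffle_rng = np.random.default_rng(root.integers(2 ** 31))

        self.vocab_ = build_vocab(smiles)
        ids, mask = self._token_arrays(smiles)
        ids_v, mask_v = self._token_arrays(smiles_val)
        feats, adj, nmask = self._graph_arrays(smiles)
        feats_v, adj_v, nmask_v = self._graph_arrays(smiles_val)

        self.cnn_ = CNNEncoder(len(self.vocab_), cfg.embed_dim,
                               cfg.cnn_channels, cfg.cnn_kernels, cfg.d1,
                               init_rng)
        self.transformer_ = TransformerEncoder(len(self.vocab_), cfg.max_len,
                                               cfg.embed_dim, cfg.tfm_heads,
                                               cfg.tfm_blocks, cfg.d2,
                                               init_rng)
        self.gat_ = GATEncoder(hidden=cfg.gat_hidden, heads=cfg.gat_heads,
                               out_dim=cfg.d3, rng=init_rng)

        n = len(smiles)

        def seq_batches(arrays):
            def gen(rng):
                order = rng.permutation(n)
                for s in range(0, n, cfg.batch_size):
                    b = order[s:s + cfg.batch_size]
                    yield tuple(a[b] for a in arrays), y[b]
            return gen

        self.history_ = {}
        self.history_["cnn"] = train_encoder(
            self.cnn_, seq_batches((ids, mask)),
            lambda: ((ids_v, mask_v), y_val),
            epochs=cfg.encoder_epochs, lr=cfg.learning_rate,
            patience=cfg.patience, shuffle_rng=shuffle_rng)
        self.history_["transformer"] = train_encoder(
            self.transformer_, seq_batches((ids, mask)),
            lambda: ((ids_v, mask_v), y_val),
            epochs=cfg.encoder_epochs, lr=cfg.learning_rate,
            patience=cfg.patience, shuffle_rng=shuffle_rng)
        self.history_["gat"] = train_encoder(
            self.gat_, seq_batches((feats, adj, nmask)),
            lambda: ((feats_v, adj_v, nmask_v), y_val),
            epochs=cfg.encoder_epochs, lr=cfg.learning_rate,
            patience=cfg.patience, shuffle_rng=shuffle_rng)

        # stage 2: frozen-feature VAE
        F = self._encode_all_raw(ids, mask, feats, adj, nmask)
        F_val = self._encode_all_raw(ids_v, mask_v, feats_v, adj_v, nmask_v)
        self.feat_mean_ = F.mean(axis=0)
        self.feat_std_ = np.maximum(F.std(axis=0), 1e-8)
        Fn, Fn_val = self._normalize(F), self._normalize(F_val)
        self.vae_ = VAE(input_dim=Fn.shape[1], latent_dim=cfg.latent_dim,
                        kl_weight=cfg.kl_weight, rng=init_rng)
        self.history_["vae"] = self.vae_.fit(
            Fn, Fn_val, epochs=cfg.vae_epochs, batch_size=cfg.batch_size,
            lr=cfg.learning_rate, patience=cfg.patience, sample=True,
            seed=int(root.integers(2 ** 31)))

        # stage 3: boosted trees on latent means (deterministic)
        Z = self.vae_.latent_mean(Fn)
        params = {"objective": "binary:logistic", "max_depth": cfg.xgb_max_depth,
                  "eta": cfg.xgb_learning_rate, "seed": cfg.seed,
                  "nthread": 1, "tree_method": "hist"}
        self.booster_ = xgb.train(params, xgb.DMatrix(Z, label=y),
                                  num_boost_round=cfg.xgb_n_estimators)
        self.classes_ = np.array([0, 1])
        return self

    def _encode_all_raw(self, ids, mask, feats, adj, nmask) -> np.ndarray:
        out = []
        bs = self.config_.batch_size
        for s in range(0, ids.shape[0], bs):
            sl = slice(s, s + bs)
            c = self.cnn_.encode(ids[sl], mask[sl]).data
            t = self.transformer_.encode(ids[sl], mask[sl]).data
            g = self.gat_.encode(feats[sl], adj[sl], nmask[sl]).data
            out.append(fuse(c, t, g).vector)
        return np.concatenate(out, axis=0)

    # ------------------------------------------------------------- predict
    def latent_codes(self, X) -> LatentCode:
        """Latent (mu, logvar, z=mu) for molecules, inference mode."""
        check_is_fitted(self, "booster_")
        Fn = self._normalize(self._encode_all(list(X)))
        latent, _, _ = self.vae_.forward(Fn, sample=False)
        return latent

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "booster_")
        Fn = self._normalize(self._encode_all(list(X)))
        Z = self.vae_.latent_mean(Fn)
        p1 = self.booster_.predict(xgb.DMatrix(Z))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # ---------------------------------------------------------- persistence
    def save(self, directory: str | Path) -> None:
        check_is_fitted(self, "booster_")
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {"config": asdict(self.config_), "vocab": self.vocab_}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        arrays = {}
        for name, mod in (("cnn", self.cnn_), ("transformer", self.transformer_),
                          ("gat", self.gat_), ("vae", self.vae_)):
            for i, a in enumerate(mod.state_arrays()):
                arrays[f"{name}_{i}"] = a
        arrays["feat_mean"] = self.feat_mean_
        arrays["feat_std"] = self.feat_std_
        np.savez(d / "weights.npz", **arrays)
        self.booster_.save_model(d / "booster.json")  # Booster JSON

    @classmethod
    def load(cls, directory: str | Path) -> "HybridToxicityClassifier":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        cfg = HybridConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in manifest["config"].items()})
        self = cls(config=cfg)
        self.config_ = cfg
        self.vocab_ = manifest["vocab"]
        rng = np.random.default_rng(0)
        self.cnn_ = CNNEncoder(len(self.vocab_), cfg.embed_dim,
                               cfg.cnn_channels, cfg.cnn_kernels, cfg.d1, rng)
        self.transformer_ = TransformerEncoder(len(self.vocab_), cfg.max_len,
                                               cfg.embed_dim, cfg.tfm_heads,
                                               cfg.tfm_blocks, cfg.d2, rng)
        self.gat_ = GATEncoder(hidden=cfg.gat_hidden, heads=cfg.gat_heads,
                               out_dim=cfg.d3, rng=rng)
        with np.load(d / "weights.npz") as z:
            for name, mod in (("cnn", self.cnn_),
                              ("transformer", self.transformer_),
                              ("gat", self.gat_)):
                mod.load_state_arrays(
                    [z[f"{name}_{i}"] for i in range(len(mod.parameters()))])
            self.feat_mean_ = z["feat_mean"]
            self.feat_std_ = z["feat_std"]
            dim = self.feat_mean_.shape[0]
            self.vae_ = VAE(input_dim=dim, latent_dim=cfg.latent_dim,
                            kl_weight=cfg.kl_weight, rng=rng)
            self.vae_.load_state_arrays(
                [z[f"vae_{i}"] for i in range(len(self.vae_.parameters()))])
        self.booster_ = xgb.Booster()
        self.booster_.load_model(d / "booster.json")
        self.classes_ = np.array([0, 1])
        return self


def train_hybrid(records, split, config: HybridConfig | None = None,
                 ) -> HybridToxicityClassifier:
    """Train the hybrid pipeline from a labeled record list and a split."""
    del records  # membership is carried by the split itself
    clf = HybridToxicityClassifier(config=config)
    clf.fit([r.smiles for r in split.train],
            [r.label for r in split.train],
            X_val=[r.smiles for r in split.validation],
            y_val=[r.label for r in split.validation])
    return clf


def predict_hybrid(pipeline: HybridToxicityClassifier, records):
    """Per-molecule probability scores and labels with per-record rejection.

    Returns (scores, labels, rejections): unparseable inputs appear in
    ``rejections`` and carry NaN score / -1 label, never failing the batch.
    """
    records = list(records)
    smiles, keep, rejections = [], [], []
    for i, rec in enumerate(records):
        raw = rec.smiles if isinstance(rec, MoleculeRecord) else str(rec)
        result = standardize_record(raw)
        if isinstance(result, Rejection):
            rejections.append((i, result))
        else:
            smiles.append(result)
            keep.append(i)
    scores = np.full(len(records), np.nan)
    labels = np.full(len(scores), -1, dtype=int)
    if smiles:
        p = pipeline.predict_proba(smiles)[:, 1]
        scores[keep] = p
        labels[keep] = (p >= 0.5).astype(int)
    return scores, labels, rejections
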
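"""Tokenizer, molecular graphs, encoder invariances, the VAE, and the staged
hybrid classifier."""

import numpy as np
import pytest

from reprotox import SynthSpec, gen_toy_molecules, split_dataset
from reprotox.hybrid import (CNNEncoder, GATEncoder, HybridConfig,
                             HybridToxicityClassifier, TransformerEncoder,
                             VAE, build_vocab, detokenize, fuse,
                             kl_divergence_terms, pad_graph_batch,
                             predict_hybrid, smiles_to_graph, smiles_tokens,
                             tokenize_smiles, train_hybrid)


class TestTokenizer:
    @pytest.mark.parametrize("smiles,expected", [
        ("CCO", ["C", "C", "O"]),
        ("ClCCl", ["Cl", "C", "Cl"]),
        ("c1ccccc1", ["c", "1", "c", "c", "c", "c", "c", "1"]),
        ("O=[N+]([O-])C", ["O", "=", "[N+]", "(", "[O-]", ")", "C"]),
        ("C%12CC%12", ["C", "%12", "C", "C", "%12"]),
    ])
    def test_atom_aware_tokenization(self, smiles, expected):
        assert smiles_tokens(smiles) == expected

    def test_round_trip_through_vocab(self):
        corpus = ["CCO", "ClCCl", "c1ccccc1O"]
        vocab = build_vocab(corpus)
        for s in corpus:
            assert detokenize(tokenize_smiles(s, vocab, max_len=20)) == s

    def test_unknown_token_maps_to_unk(self):
        vocab = build_vocab(["CCO"])
        seq = tokenize_smiles("CBr", vocab, max_len=8)
        assert seq.token_ids[1] == 1  # <unk>

    def test_truncation_flagged(self):
        vocab = build_vocab(["CCCCCCCC"])
        seq = tokenize_smiles("CCCCCCCC", vocab, max_len=4)
        assert seq.truncated and seq.n_real == 4

    def test_empty_smiles_raises(self):
        with pytest.raises(ValueError):
            smiles_tokens("")


class TestGraphs:
    def test_ethanol_counts(self):
        g = smiles_to_graph("CCO")
        assert g.n_atoms == 3 and g.edges.shape[0] == 4

    def test_methane_single_node_no_edges(self):
        g = smiles_to_graph("C")
        assert g.n_atoms == 1 and g.edges.shape[0] == 0

    def test_benzene_aromatic_ring(self):
        g = smiles_to_graph("c1ccccc1")
        assert g.n_atoms == 6 and g.edges.shape[0] == 12
        aromatic_col = g.atom_features[:, 17]
        assert aromatic_col.sum() == 6
        assert g.bond_features[:, 1].sum() == 12  # all bonds aromatic

    def test_edges_symmetric(self):
        g = smiles_to_graph("CC(=O)OC")
        pairs = {tuple(e) for e in g.edges}
        assert all((j, i) in pairs for (i, j) in pairs)

    def test_padded_batch_masks(self):
        feats, adj, mask = pad_graph_batch([smiles_to_graph("C"),
                                            smiles_to_graph("CCO")])
        assert feats.shape == (2, 3, feats.shape[2])
        assert mask.tolist() == [[1, 0, 0], [1, 1, 1]]
        assert adj[0, 1:, :].sum() == 0  # padded nodes have no edges


def _seq_arrays(smiles, vocab, max_len):
    seqs = [tokenize_smiles(s, vocab, max_len) for s in smiles]
    ids = np.stack([s.token_ids for s in seqs])
    mask = np.stack([s.mask for s in seqs]).astype(np.float64)
    return ids, mask


class TestEncoderInvariances:
    SMILES = ["CCO", "c1ccccc1O", "O=[N+]([O-])c1ccccc1"]

    def test_cnn_padding_extension_invariance(self):
        vocab = build_vocab(self.SMILES)
        enc = CNNEncoder(len(vocab), 16, 16, (3, 5), 8,
                         np.random.default_rng(0))
        short = enc.encode(*_seq_arrays(self.SMILES, vocab, 20)).data
        long = enc.encode(*_seq_arrays(self.SMILES, vocab, 48)).data
        assert np.abs(short - long).max() < 1e-5

    def test_transformer_padding_extension_invariance(self):
        vocab = build_vocab(self.SMILES)
        enc = TransformerEncoder(len(vocab), 64, 16, 2, 1, 8,
                                 np.random.default_rng(0))
        short = enc.encode(*_seq_arrays(self.SMILES, vocab, 20)).data
        long = enc.encode(*_seq_arrays(self.SMILES, vocab, 48)).data
        assert np.abs(short - long).max() < 1e-5

    def test_encoders_deterministic_in_eval(self):
        vocab = build_vocab(self.SMILES)
        enc = CNNEncoder(len(vocab), 16, 16, (3,), 8,
                         np.random.default_rng(0))
        args = _seq_arrays(self.SMILES, vocab, 20)
        assert np.array_equal(enc.encode(*args).data, enc.encode(*args).data)

    def test_gat_atom_permutation_invariance(self):
        g = smiles_to_graph("CC(=O)OC")  # 5 heavy atoms
        enc = GATEncoder(hidden=8, heads=2, out_dim=8,
                         rng=np.random.default_rng(1))
        feats, adj, mask = pad_graph_batch([g])
        base = enc.encode(feats, adj, mask).data
        rng = np.random.default_rng(2)
        for _ in range(3):
            perm = rng.permutation(g.n_atoms)
            pf = feats[:, perm, :]
            pa = adj[:, perm][:, :, perm]
            out = enc.encode(pf, pa, mask).data
            assert np.abs(out - base).max() < 1e-5

    def test_gat_single_node_graph(self):
        feats, adj, mask = pad_graph_batch([smiles_to_graph("C")])
        enc = GATEncoder(hidden=8, heads=2, out_dim=8,
                         rng=np.random.default_rng(1))
        out = enc.encode(feats, adj, mask)
        assert out.shape == (1, 8)
        assert np.all(np.isfinite(out.data))


class TestFuse:
    def test_order_and_length_contract(self):
        c, t, g = np.ones((2, 4)), np.full((2, 4), 2.0), np.full((2, 4), 3.0)
        fused = fuse(c, t, g)
        assert fused.vector.shape == (2, 12)
        assert np.all(fused.vector[:, :4] == 1.0)
        assert np.all(fused.vector[:, 8:] == 3.0)

    def test_zero_in_zero_out(self):
        fused = fuse(np.zeros((1, 3)), np.zeros((1, 3)), np.zeros((1, 3)))
        assert not fused.vector.any()

    def test_misaligned_batches_raise(self):
        with pytest.raises(ValueError):
            fuse(np.zeros((2, 3)), np.zeros((1, 3)), np.zeros((2, 3)))


class TestVAE:
    def test_kl_closed_form_values(self):
        assert kl_divergence_terms(np.zeros(4), np.zeros(4))[0] == pytest.approx(0.0)
        assert kl_divergence_terms(np.array([1.0, 0.0]),
                                   np.zeros(2))[0] == pytest.approx(0.5)

    def test_kl_non_negative_with_equality_only_at_prior(self, rng):
        mu = rng.normal(size=(10_000, 4)) * 2
        logvar = rng.normal(size=(10_000, 4)) * 2
        kl = kl_divergence_terms(mu, logvar)
        assert np.all(kl >= 0)
        assert np.all(kl[np.abs(mu).sum(1) + np.abs(logvar).sum(1) > 1e-8] > 0)

    def test_inference_latent_equals_mean(self, rng):
        vae = VAE(input_dim=8, latent_dim=3, rng=np.random.default_rng(0))
        x = rng.normal(size=(5, 8))
        code, _, _ = vae.forward(x, sample=False)
        assert np.array_equal(code.z, code.mu)

    def test_sampling_uses_reparameterization(self, rng):
        vae = VAE(input_dim=8, latent_dim=3, rng=np.random.default_rng(0))
        x = rng.normal(size=(5, 8))
        code, _, _ = vae.forward(x, sample=True, rng=np.random.default_rng(1))
        assert not np.array_equal(code.z, code.mu)

    def test_loss_decreases_on_fixed_batch(self, rng):
        vae = VAE(input_dim=12, latent_dim=4, rng=np.random.default_rng(3))
        x = rng.normal(size=(64, 12))
        trace = vae.loss_trace(x, epochs=20)
        assert all(b < a for a, b in zip(trace, trace[1:]))

    def test_identity_capacity_reaches_near_zero_reconstruction(self, rng):
        # latent as wide as the input and no KL pressure: the VAE can act as
        # an autoencoder and overfit a tiny batch almost exactly
        x = rng.normal(size=(32, 6))
        vae = VAE(input_dim=6, latent_dim=6, kl_weight=0.0,
                  rng=np.random.default_rng(4))
        vae.loss_trace(x, epochs=800, lr=1e-2)
        _, _, terms = vae.forward(x, sample=False)
        assert terms["recon"] < 0.05


@pytest.fixture(scope="module")
def small_benchmark():
    records = gen_toy_molecules(SynthSpec(n=90, label_noise=0.0, seed=21))
    split = split_dataset(records, seed=21)
    cfg = HybridConfig(encoder_epochs=10, vae_epochs=20, patience=4,
                       max_len=72, seed=21)
    return records, split, train_hybrid(records, split, cfg)


class TestHybridPipeline:
    def test_learns_motif_labels(self, small_benchmark):
        records, split, clf = small_benchmark
        y = np.array([r.label for r in split.test])
        acc = (clf.predict([r.smiles for r in split.test]) == y).mean()
        assert acc >= 0.75

    def test_scores_are_probabilities(self, small_benchmark):
        _, split, clf = small_benchmark
        p = clf.predict_proba([r.smiles for r in split.test])
        assert p.shape[1] == 2
        assert np.all((p >= 0) & (p <= 1))
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_repeated_molecule_scores_identically(self, small_benchmark):
        _, split, clf = small_benchmark
        s = split.test[0].smiles
        p = clf.predict_proba([s, s])
        assert p[0, 1] == p[1, 1]

    def test_latent_codes_inference_mode(self, small_benchmark):
        _, split, clf = small_benchmark
        code = clf.latent_codes([r.smiles for r in split.test[:4]])
        assert np.array_equal(code.z, code.mu)
        assert code.mu.shape == (4, clf.config_.latent_dim)

    def test_predict_hybrid_rejects_per_record(self, small_benchmark):
        _, split, clf = small_benchmark
        inputs = [split.test[0].smiles, "C(", split.test[1].smiles]
        scores, labels, rejections = predict_hybrid(clf, inputs)
        assert len(rejections) == 1 and rejections[0][0] == 1
        assert np.isnan(scores[1]) and labels[1] == -1
        assert np.isfinite(scores[0]) and labels[0] in (0, 1)

    def test_save_load_round_trip(self, small_benchmark, tmp_path):
        _, split, clf = small_benchmark
        clf.save(tmp_path / "model")
        loaded = HybridToxicityClassifier.load(tmp_path / "model")
        smiles = [r.smiles for r in split.test]
        assert np.allclose(loaded.predict_proba(smiles),
                           clf.predict_proba(smiles))

    def test_single_class_training_raises(self):
        recs = gen_toy_molecules(SynthSpec(n=20, positive_fraction=1.0,
                                           label_noise=0.0, seed=1))
        clf = HybridToxicityClassifier()
        with pytest.raises(ValueError, match="both classes"):
            clf.fit([r.smiles for r in recs], [r.label for r in recs],
                    X_val=[recs[0].smiles], y_val=[1])


def test_training_determinism_same_seed():
    records = gen_toy_molecules(SynthSpec(n=60, label_noise=0.0, seed=31))
    split = split_dataset(records, seed=31)
    cfg = HybridConfig(encoder_epochs=4, vae_epochs=6, patience=3,
                       max_len=72, seed=31)
    smiles = [r.smiles for r in split.test]
    a = train_hybrid(records, split, cfg).predict_proba(smiles)
    b = train_hybrid(records, split, cfg).predict_proba(smiles)
    assert np.array_equal(a, b)
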
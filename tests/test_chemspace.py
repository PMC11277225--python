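"""Embeddings, Ward clustering, and representative-molecule selection."""

import itertools

import numpy as np
import pytest

from reprotox import (BitFingerprint, ChemicalSpaceClusterer, pca_embed,
                      select_representative, tanimoto, tsne_embed,
                      ward_cluster)


def _fp(bits8):
    arr = np.array(bits8, dtype=np.uint8)
    return BitFingerprint(bits=arr, scheme="morgan", nbits=arr.size, radius=2)


class TestPCA:
    def test_identical_inputs_collapse_to_origin(self):
        fps = [_fp([1, 0, 1, 0, 1, 0, 0, 0])] * 5
        emb = pca_embed(fps)
        assert np.allclose(emb.coords, 0.0)

    def test_component_order_by_explained_variance(self, toy_fingerprints):
        emb = pca_embed(toy_fingerprints)
        ev = emb.params["explained_variance_ratio"]
        assert ev[0] >= ev[1]

    def test_matches_brute_force_eigendecomposition(self):
        vecs = [[1, 1, 0, 0, 0, 0, 1, 0],
                [1, 1, 1, 0, 0, 0, 0, 0],
                [0, 0, 0, 1, 1, 1, 0, 1],
                [0, 0, 1, 1, 1, 0, 0, 1]]
        X = np.array(vecs, dtype=float)
        emb = pca_embed([_fp(v) for v in vecs])
        # independent oracle: eigendecomposition of the 8x8 covariance
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        w, V = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1][:2]
        proj = np.empty((4, 2))
        for j, k in enumerate(order):
            v = V[:, k]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            proj[:, j] = Xc @ v
        assert np.allclose(emb.coords, proj, atol=1e-8)

    def test_too_few_inputs_raise(self):
        with pytest.raises(ValueError):
            pca_embed([_fp([1] * 8)] * 2)


class TestTSNE:
    def test_seed_determinism(self, toy_fingerprints):
        with pytest.warns(UserWarning):
            a = tsne_embed(toy_fingerprints, seed=5)
            b = tsne_embed(toy_fingerprints, seed=5)
        assert np.array_equal(a.coords, b.coords)
        assert a.coords.shape == (len(toy_fingerprints), 3)

    def test_separated_blobs_stay_separated(self, rng):
        # two fingerprint blobs with disjoint active bit regions
        fps = []
        for i in range(15):
            bits = np.zeros(64, dtype=np.uint8)
            bits[rng.choice(24, size=12, replace=False)] = 1
            fps.append(_fp(bits))
        for i in range(15):
            bits = np.zeros(64, dtype=np.uint8)
            bits[40 + rng.choice(24, size=12, replace=False)] = 1
            fps.append(_fp(bits))
        with pytest.warns(UserWarning):
            emb = tsne_embed(fps, seed=3)
        a, b = emb.coords[:15], emb.coords[15:]
        intra = np.mean([np.linalg.norm(x - y) for x in a for y in a])
        inter = np.mean([np.linalg.norm(x - y) for x in a for y in b])
        assert inter > intra

    def test_small_sample_auto_lowers_perplexity(self, toy_fingerprints):
        with pytest.warns(UserWarning, match="perplexity lowered"):
            emb = tsne_embed(toy_fingerprints[:20], perplexity=30, seed=1)
        assert emb.params["perplexity"] < 30

    def test_tiny_sample_raises(self):
        with pytest.raises(ValueError):
            tsne_embed([_fp([1] * 8)] * 4, seed=0)


def _ward_objective(X, partition):
    total = 0.0
    for cluster in partition:
        pts = X[list(cluster)]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return total


class TestWard:
    def test_k1_and_kn_degenerate_cases(self, rng):
        X = rng.normal(size=(6, 3))
        assert np.all(ward_cluster(X, k=1) == 0)
        assert sorted(ward_cluster(X, k=6)) == list(range(6))

    def test_k_out_of_range_raises(self, rng):
        with pytest.raises(ValueError):
            ward_cluster(rng.normal(size=(4, 3)), k=5)

    def test_two_triads_match_exhaustive_objective_minimum(self):
        rng = np.random.default_rng(8)
        triad1 = rng.normal(size=(3, 3)) * 0.05 + np.array([0, 0, 0])
        triad2 = rng.normal(size=(3, 3)) * 0.05 + np.array([10, 10, 10])
        X = np.vstack([triad1, triad2])
        labels = ward_cluster(X, k=2)
        got = frozenset(frozenset(np.flatnonzero(labels == c)) for c in (0, 1))
        # oracle: enumerate all 2-partitions, minimize within-cluster variance
        best, best_obj = None, np.inf
        for r in range(1, 6):
            for subset in itertools.combinations(range(6), r):
                part = (frozenset(subset),
                        frozenset(set(range(6)) - set(subset)))
                obj = _ward_objective(X, part)
                if obj < best_obj:
                    best_obj, best = obj, frozenset(part)
        assert got == best


class TestRepresentatives:
    def test_identical_molecules_first_index_wins(self):
        fps = [_fp([1, 0, 1, 0, 0, 0, 0, 0])] * 4
        result = select_representative(fps, np.zeros(4, dtype=int))
        assert result.representatives == (0,)
        assert result.mean_similarity == (1.0,)

    def test_singleton_cluster_represents_itself(self):
        fps = [_fp([1, 0, 0, 0, 0, 0, 0, 0]), _fp([0, 1, 1, 1, 0, 0, 0, 0])]
        result = select_representative(fps, np.array([0, 1]))
        assert result.representatives == (0, 1)
        assert result.mean_similarity[1] == 1.0

    def test_matches_exhaustive_argmax_on_random_clusters(self, rng):
        for _ in range(50):
            size = int(rng.integers(2, 9))
            fps = [_fp((rng.random(8) < 0.4).astype(np.uint8))
                   for _ in range(size)]
            result = select_representative(fps, np.zeros(size, dtype=int))
            # oracle: brute-force mean Tanimoto over the full matrix
            means = []
            for i in range(size):
                sims = [tanimoto(fps[i], fps[j]) for j in range(size) if j != i]
                means.append(np.mean(sims))
            chosen = result.representatives[0]
            # the chosen member attains the maximum; exact index must agree
            # whenever the argmax is unique beyond float rounding
            assert means[chosen] == pytest.approx(max(means), abs=1e-12)
            gap = sorted(means)[-1] - (sorted(means)[-2] if size > 1 else 0)
            if gap > 1e-9:
                assert chosen == int(np.argmax(means))
            assert result.mean_similarity[0] == pytest.approx(max(means))

    def test_label_permutation_leaves_representatives_unchanged(self, rng):
        fps = [_fp((rng.random(8) < 0.5).astype(np.uint8)) for _ in range(10)]
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2, 2])
        base = select_representative(fps, labels)
        permuted = np.array([2, 2, 2, 0, 0, 0, 1, 1, 1, 1])
        alt = select_representative(fps, permuted)
        assert set(base.representatives) == set(alt.representatives)


def test_clusterer_estimator_workflow(toy_fingerprints):
    est = ChemicalSpaceClusterer(n_clusters=3, random_state=0)
    with pytest.warns(UserWarning):
        labels = est.fit_predict(toy_fingerprints)
    assert sorted(set(labels)) == [0, 1, 2]
    assert len(est.representatives_) == 3
    for c, rep in enumerate(est.representatives_):
        assert labels[rep] == c
    assert all(0.0 <= s <= 1.0 for s in est.mean_similarity_)
    assert est.get_params()["n_clusters"] == 3
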
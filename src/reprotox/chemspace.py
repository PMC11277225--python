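"""Chemical-space embedding, Ward clustering, and representative selection.

The clustering workflow embeds 2048-bit circular fingerprints into three
dimensions with t-SNE (perplexity 30), cuts a Ward-linkage dendrogram of the
embedded coordinates at k clusters (k = 3 by default), and then — back in
fingerprint space — names as each cluster's representative the member with
the highest average Tanimoto similarity to its co-members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .featurize import tanimoto

__all__ = [
    "EmbeddingCoords", "ClusterResult", "pca_embed", "tsne_embed",
    "ward_cluster", "select_representative", "ChemicalSpaceClusterer",
]


@dataclass(frozen=True)
class EmbeddingCoords:
    coords: np.ndarray  # molecules x d
    method: str         # "pca" | "tsne"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=np.float64)
        if not np.all(np.isfinite(c)):
            raise ValueError("embedding produced non-finite coordinates")
        object.__setattr__(self, "coords", c)


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray               # per-molecule cluster index in 0..k-1
    k: int
    representatives: tuple[int, ...]  # per-cluster member index
    mean_similarity: tuple[float, ...]
    linkage: str = "ward"


def _stack(fingerprints) -> np.ndarray:
    if isinstance(fingerprints, np.ndarray):
        return fingerprints.astype(np.float64)
    return np.stack([fp.bits for fp in fingerprints]).astype(np.float64)


def pca_embed(fingerprints) -> EmbeddingCoords:
    """Project fingerprints onto the top two principal components.

    Components are ordered by descending explained variance and the sign of
    each is fixed so its largest-magnitude loading is positive.
    """
    X = _stack(fingerprints)
    if X.shape[0] < 3:
        raise ValueError("PCA embedding needs at least 3 fingerprints")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(2):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1.0
    return EmbeddingCoords(coords=coords, method="pca",
                           params={"explained_variance_ratio":
                                   pca.explained_variance_ratio_.tolist()})


def tsne_embed(fingerprints, perplexity: float = 30.0,
               seed: int = 42) -> EmbeddingCoords:
    """Embed fingerprints into 3 dimensions with exact-gradient t-SNE.

    Deterministic under ``seed``.  If the sample is too small for the
    requested perplexity it is lowered automatically with a warning.
    """
    X = _stack(fingerprints)
    n = X.shape[0]
    if n < 5:
        raise ValueError("t-SNE embedding needs at least 5 fingerprints")
    eff = perplexity
    if n <= 3 * perplexity:
        eff = max(2.0, (n - 1) / 3.0)
        warnings.warn(f"perplexity lowered from {perplexity} to {eff:.1f} "
                      f"for n={n}")
    tsne = TSNE(n_components=3, perplexity=eff, random_state=seed,
                method="exact", init="pca", max_iter=500)
    coords = tsne.fit_transform(X)
    return EmbeddingCoords(coords=coords.astype(np.float64), method="tsne",
                           params={"perplexity": eff, "seed": seed})


def ward_cluster(coords, k: int = 3) -> np.ndarray:
    """Cut a Ward-linkage dendrogram at k clusters.

    Labels are renumbered to 0..k-1 in order of first appearance.
    """
    X = coords.coords if isinstance(coords, EmbeddingCoords) else np.asarray(coords)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if k == n:
        return np.arange(n)
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    remap, labels = {}, np.empty(n, dtype=np.intp)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    return labels


def select_representative(fingerprints, labels) -> ClusterResult:
    """Pick each cluster's most central member by average Tanimoto similarity.

    For every cluster, the full pairwise Tanimoto matrix over its members is
    computed and the member with the highest mean similarity to co-members
    (self excluded) is the representative; ties break to the lowest index.
    Singleton clusters represent themselves with mean similarity 1.0.
    """
    fps = list(fingerprints)
    labels = np.asarray(labels)
    if len(fps) != labels.shape[0]:
        raise ValueError("labels must align with fingerprints")
    k = int(labels.max()) + 1 if labels.size else 0
    reps, sims = [], []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        if members.size == 1:
            reps.append(int(members[0]))
            sims.append(1.0)
            continue
        sim = np.array([[tanimoto(fps[i], fps[j]) for j in members]
                        for i in members])
        mean_sim = (sim.sum(axis=1) - np.diag(sim)) / (members.size - 1)
        best = int(np.argmax(mean_sim))  # argmax takes the first maximum
        reps.append(int(members[best]))
        sims.append(float(mean_sim[best]))
    return ClusterResult(labels=labels, k=k, representatives=tuple(reps),
                         mean_similarity=tuple(sims))


class ChemicalSpaceClusterer(BaseEstimator, ClusterMixin):
    """t-SNE + Ward clustering with Tanimoto representatives, as an estimator.

    Parameters
    ----------
    n_clusters : int, default 3
        Number of clusters to cut the Ward dendrogram into.
    perplexity : float, default 30.0
        t-SNE perplexity (auto-lowered for small samples).
    random_state : int, default 42
        Seed for the t-SNE embedding.

    Attributes
    ----------
    labels_ : ndarray of shape (n_molecules,)
    embedding_ : EmbeddingCoords
    representatives_ : tuple of member indices, one per cluster
    mean_similarity_ : tuple of floats
    """

    def __init__(self, n_clusters: int = 3, perplexity: float = 30.0,
                 random_state: int = 42):
        self.n_clusters = n_clusters
        self.perplexity = perplexity
        self.random_state = random_state

    def fit(self, X, y=None):
        fps = list(X)
        self.embedding_ = tsne_embed(fps, perplexity=self.perplexity,
                                     seed=self.random_state)
        self.labels_ = ward_cluster(self.embedding_, k=self.n_clusters)
        result = select_representative(fps, self.labels_)
        self.representatives_ = result.representatives
        self.mean_similarity_ = result.mean_similarity
        self.result_ = result
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
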
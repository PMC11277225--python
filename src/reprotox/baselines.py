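"""Classical baseline classifiers with the reference hyperparameter grids.

Five model families — Naive Bayes, K-nearest neighbours, random forest,
support-vector machine, and a one-hidden-layer neural network — are trained
on either binary fingerprints or filtered continuous descriptors.  Every
grid combination is fitted on the training part, the winner is chosen by
balanced accuracy on the validation part (ties break to the first
combination in enumeration order), and the test part is never touched
during selection.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .metrics import MetricsReport, compute_metrics, confusion_counts
from .standardize import DatasetSplit

__all__ = ["HyperGrid", "default_grids", "BaselineClassifier",
           "grid_search_fit", "evaluate_baseline", "split_indices",
           "MODEL_KINDS"]

MODEL_KINDS = ("naive_bayes", "knn", "random_forest", "svm", "neural_net")


@dataclass(frozen=True)
class HyperGrid:
    model_kind: str
    grid: dict[str, tuple]

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        for k, v in self.grid.items():
            if len(v) == 0:
                raise ValueError(f"empty candidate list for {k!r}")

    def combinations(self):
        """Enumerate parameter assignments in deterministic order."""
        if not self.grid:
            yield {}
            return
        keys = list(self.grid)
        for values in itertools.product(*(self.grid[k] for k in keys)):
            yield dict(zip(keys, values))

    def size(self) -> int:
        return int(np.prod([len(v) for v in self.grid.values()])) if self.grid else 1


def default_grids() -> dict[str, HyperGrid]:
    """The reference hyperparameter grids for the five baseline families."""
    return {
        "naive_bayes": HyperGrid("naive_bayes", {
            "alpha": (0.01, 0.1, 1.0),
            "binarize": (0.0, 0.5, 0.8),
        }),
        "knn": HyperGrid("knn", {
            "n_neighbors": (3, 5, 7, 10, 15, 20),
            "metric": ("manhattan", "euclidean", "jaccard"),
        }),
        "random_forest": HyperGrid("random_forest", {
            "n_estimators": (100, 200, 300),
            "criterion": ("gini", "entropy"),
            "max_depth": (5, 10, 20, 30, None),
            "min_samples_leaf": tuple(range(1, 11)),
            "max_features": ("log2", "sqrt", None),
        }),
        "svm": HyperGrid("svm", {
            "gamma": ("auto", 0.1, 0.2),
            "C": (0.1, 1.0, 10.0, 100.0),
        }),
        "neural_net": HyperGrid("neural_net", {}),
    }


def _build_estimator(model_kind: str, params: dict, feature_kind: str, seed: int):
    if model_kind == "naive_bayes":
        if feature_kind == "fingerprint":
            return BernoulliNB(**params)
        # alpha/binarize are Bernoulli-only; Gaussian NB for continuous input
        return GaussianNB()
    if model_kind == "knn":
        return KNeighborsClassifier(**params)
    if model_kind == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if model_kind == "svm":
        return SVC(kernel="rbf", random_state=seed, **params)
    if model_kind == "neural_net":
        return MLPClassifier(hidden_layer_sizes=(128,), activation="relu",
                             early_stopping=True, random_state=seed,
                             max_iter=300, **params)
    raise ValueError(f"unknown model kind {model_kind!r}")


def _scores(est, X) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, list(est.classes_).index(1)]
    return est.decision_function(X)


class BaselineClassifier(BaseEstimator, ClassifierMixin):
    """Grid-searched classical baseline over fingerprints or descriptors.

    Parameters
    ----------
    model_kind : {"naive_bayes", "knn", "random_forest", "svm", "neural_net"}
    feature_kind : {"fingerprint", "descriptors"}, default "fingerprint"
        Chooses Bernoulli vs Gaussian Naive Bayes and boolean casting for
        the Jaccard KNN metric.
    grid : HyperGrid or None
        ``None`` uses the reference grid for ``model_kind``.
    seed : int, default 42
        Random state for stochastic learners.

    Attributes
    ----------
    chosen_params_ : dict — winning grid combination.
    best_estimator_ : the refitted winner.
    validation_ba_ : balanced accuracy of the winner on the validation part.
    manifest_ : dict — seed, split hash, feature spec.
    """

    def __init__(self, model_kind: str = "svm",
                 feature_kind: str = "fingerprint",
                 grid: HyperGrid | None = None, seed: int = 42):
        self.model_kind = model_kind
        self.feature_kind = feature_kind
        self.grid = grid
        self.seed = seed

    def _cast(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        return X

    def fit(self, X, y, X_val=None, y_val=None):
        X = self._cast(X)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        if X_val is None:
            raise ValueError("BaselineClassifier.fit requires a validation "
                             "part (X_val, y_val) for grid selection")
        X_val = self._cast(X_val)
        y_val = np.asarray(y_val).astype(int)
        grid = self.grid or default_grids()[self.model_kind]
        if self.model_kind == "naive_bayes" and self.feature_kind == "descriptors":
            grid = HyperGrid("naive_bayes", {})
        best = None
        for params in grid.combinations():
            est = _build_estimator(self.model_kind, params,
                                   self.feature_kind, self.seed)
            Xf, Xv = X, X_val
            if self.model_kind == "knn" and params.get("metric") == "jaccard":
                Xf, Xv = X.astype(bool), X_val.astype(bool)
            est.fit(Xf, y)
            pred = est.predict(Xv)
            c = confusion_counts(y_val, pred)
            ba = compute_metrics(c).BA
            if best is None or ba > best[0]:
                best = (ba, params, est)
        self.validation_ba_, self.chosen_params_, self.best_estimator_ = best
        self._jaccard = (self.model_kind == "knn"
                         and self.chosen_params_.get("metric") == "jaccard")
        self.classes_ = np.array([0, 1])
        self.manifest_ = {
            "model_kind": self.model_kind,
            "feature_kind": self.feature_kind,
            "chosen_params": {k: (None if v is None else v)
                              for k, v in self.chosen_params_.items()},
            "seed": self.seed,
            "grid_size": grid.size(),
            "train_hash": _array_hash(X),
            "validation_hash": _array_hash(X_val),
        }
        return self

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        X = self._cast(X)
        if self._jaccard:
            X = X.astype(bool)
        return self.best_estimator_.predict(X)

    def decision_scores(self, X) -> np.ndarray:
        """Continuous scores for AUC (probability of class 1 where available)."""
        check_is_fitted(self, "best_estimator_")
        X = self._cast(X)
        if self._jaccard:
            X = X.astype(bool)
        return _scores(self.best_estimator_, X)


def _array_hash(X: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest()[:16]


def split_indices(records, split: DatasetSplit) -> dict[str, np.ndarray]:
    """Positions of each split part within the original record order."""
    pos = {rec.id: i for i, rec in enumerate(records)}
    return {name: np.array([pos[r.id] for r in part], dtype=np.intp)
            for name, part in split.parts().items()}


def grid_search_fit(model_kind: str, features, labels, split,
                    grid: HyperGrid | None = None, seed: int = 42,
                    records=None, feature_kind: str = "fingerprint",
                    ) -> BaselineClassifier:
    """Fit one baseline family with validation-part grid selection.

    ``split`` is either a :class:`DatasetSplit` (with ``records`` giving the
    feature row order) or a mapping of part name to row indices.  The test
    part is never consulted.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if isinstance(split, DatasetSplit):
        if records is None:
            raise ValueError("records are required to align a DatasetSplit "
                             "with the feature matrix")
        idx = split_indices(records, split)
    else:
        idx = {k: np.asarray(v, dtype=np.intp) for k, v in split.items()}
    tr, va = idx["train"], idx["validation"]
    clf = BaselineClassifier(model_kind=model_kind, feature_kind=feature_kind,
                             grid=grid, seed=seed)
    clf.fit(X[tr], y[tr], X_val=X[va], y_val=y[va])
    return clf


def evaluate_baseline(model: BaselineClassifier, features, labels,
                      ) -> MetricsReport:
    """Metrics report of a fitted baseline on held-out data."""
    check_is_fitted(model, "best_estimator_")
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    pred = model.predict(X)
    scores = model.decision_scores(X)
    return compute_metrics(confusion_counts(y, pred), y_true=y, scores=scores)
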
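"""Classifiers behind a uniform fit/predict contract.

The four light classifiers used inside the feature-selection wrapper
loop — nearest class centroid, 1-nearest-neighbour, linear discriminant
analysis and Gaussian naive Bayes — are implemented natively on numpy
so the genetic search stays fast.  Random forest and linear SVM enter
through scikit-learn adapters, seeded for reproducibility.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["make_classifier", "CentroidClassifier", "OneNN", "LDA", "GaussianNB"]


class CentroidClassifier:
    """Assign to the nearest class mean (Euclidean)."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CentroidClassifier":
        self.classes_ = np.unique(y)
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = cdist(X, self.means_)
        return self.classes_[np.argmin(d, axis=1)]


class OneNN:
    """Brute-force 1-nearest-neighbour."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneNN":
        self.X_, self.y_ = np.asarray(X, dtype=float), np.asarray(y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = cdist(X, self.X_)
        return self.y_[np.argmin(d, axis=1)]


class LDA:
    """Linear discriminant analysis with a pooled, lightly regularized
    covariance; discriminants evaluated in closed form."""

    def __init__(self, reg: float = 1e-6):
        self.reg = reg

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LDA":
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        n, p = X.shape
        means = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        pooled = np.zeros((p, p))
        for c, m in zip(self.classes_, means):
            Xc = X[y == c] - m
            pooled += Xc.T @ Xc
        pooled /= max(n - len(self.classes_), 1)
        pooled += self.reg * max(np.trace(pooled) / p, 1.0) * np.eye(p)
        self.means_ = means
        self.W_ = np.linalg.solve(pooled, means.T)  # (p, k)
        priors = np.array([(y == c).mean() for c in self.classes_])
        self.b_ = -0.5 * np.sum(means.T * self.W_, axis=0) + np.log(priors)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = np.asarray(X, dtype=float) @ self.W_ + self.b_
        return self.classes_[np.argmax(scores, axis=1)]


class GaussianNB:
    """Gaussian naive Bayes with variance smoothing."""

    def __init__(self, var_smoothing: float = 1e-9):
        self.var_smoothing = var_smoothing

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianNB":
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        self.theta_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        self.var_ = np.stack([X[y == c].var(axis=0) for c in self.classes_])
        self.var_ += self.var_smoothing * max(X.var(axis=0).max(), 1e-12)
        self.log_priors_ = np.log(
            np.array([(y == c).mean() for c in self.classes_])
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        ll = np.empty((len(X), len(self.classes_)))
        for k in range(len(self.classes_)):
            ll[:, k] = self.log_priors_[k] - 0.5 * np.sum(
                np.log(2 * np.pi * self.var_[k])
                + (X - self.theta_[k]) ** 2 / self.var_[k],
                axis=1,
            )
        return self.classes_[np.argmax(ll, axis=1)]


class _SklearnAdapter:
    def __init__(self, factory):
        self._factory = factory

    def fit(self, X, y):
        self._model = self._factory()
        self._model.fit(X, y)
        return self

    def predict(self, X):
        return self._model.predict(X)


def make_classifier(name: str, seed: int = 0):
    """Factory for the six study classifiers.

    ``knn`` uses K = 1; ``rf`` uses 8 trees; ``svm`` is a linear,
    one-vs-rest SVM with C = 1.
    """
    name = name.lower()
    if name == "centroid":
        return CentroidClassifier()
    if name == "knn":
        return OneNN()
    if name == "lda":
        return LDA()
    if name == "nb":
        return GaussianNB()
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier

        return _SklearnAdapter(
            lambda: RandomForestClassifier(n_estimators=8, random_state=seed)
        )
    if name == "svm":
        from sklearn.svm import LinearSVC

        return _SklearnAdapter(lambda: LinearSVC(C=1.0, random_state=seed))
    raise ValueError(f"unknown classifier {name!r}")
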
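"""Fuzzy K-nearest-neighbor classification.

Unlike crisp KNN, FKNN assigns each query a graded membership in every
class: the memberships of the k nearest training points are averaged with
inverse-distance weights d^(-2/(m-1)), where the fuzzy strength m > 1
controls how sharply weight decays with distance (m -> 1 concentrates all
weight on the nearest neighbor; large m approaches an unweighted average).
The predicted class is the one with maximal membership.

Training-point memberships are either crisp one-hot columns or the
Keller-style neighborhood scheme, 0.51 + 0.49 * (fraction of a point's own
k neighbors sharing its label) for the point's class and 0.49 * fraction
for the others.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["FuzzyKNN"]


class FuzzyKNN(BaseEstimator, ClassifierMixin):
    """Fuzzy K-nearest-neighbor classifier.

    Parameters
    ----------
    k : int, default=5
        Number of neighbors used for prediction (and for the neighborhood
        membership initialization).
    m : float, default=2.0
        Fuzzy strength; must exceed 1.  The distance weight is
        ``1 / d**(2/(m-1))``.
    init_scheme : {"crisp", "neighborhood"}, default="crisp"
        How training-point class memberships are assigned.

    Attributes
    ----------
    classes_ : ndarray
        Sorted unique class labels.
    X_ : ndarray of shape (n, D)
        Training points.
    memberships_ : ndarray of shape (n, C)
        Per-training-point class memberships; rows sum to 1.
    """

    def __init__(self, k: int = 5, m: float = 2.0, init_scheme: str = "crisp"):
        self.k = k
        self.m = m
        self.init_scheme = init_scheme

    def fit(self, X, y) -> "FuzzyKNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n = X.shape[0]
        if y.shape[0] != n:
            raise ValueError("X and y length mismatch")
        if self.m <= 1:
            raise ValueError(f"fuzzy strength m must exceed 1, got {self.m}")
        if not 1 <= self.k <= n:
            raise ValueError(f"k must be in [1, n={n}], got {self.k}")
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        if self.init_scheme not in ("crisp", "neighborhood"):
            raise ValueError("init_scheme must be 'crisp' or 'neighborhood'")

        C = classes.size
        memberships = np.zeros((n, C))
        if self.init_scheme == "crisp":
            memberships[np.arange(n), y_idx] = 1.0
        else:
            # Keller neighborhood scheme over each point's k neighbors
            # (excluding the point itself)
            dist = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
            np.fill_diagonal(dist, np.inf)
            kk = min(self.k, n - 1)
            for j in range(n):
                nn = np.argsort(dist[j], kind="stable")[:kk]
                frac = np.bincount(y_idx[nn], minlength=C) / kk
                memberships[j] = 0.49 * frac
                memberships[j, y_idx[j]] += 0.51

        self.classes_ = classes
        self.X_ = X
        self.y_index_ = y_idx
        self.memberships_ = memberships
        return self

    def predict_memberships(self, X) -> np.ndarray:
        """Class-membership vectors (rows sum to 1) for each query row."""
        check_is_fitted(self, "X_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.X_.shape[1]:
            raise ValueError("query dimensionality mismatch")
        out = np.empty((X.shape[0], self.classes_.size))
        exponent = 2.0 / (self.m - 1.0)
        for q, x in enumerate(X):
            d = np.linalg.norm(self.X_ - x, axis=1)
            exact = d == 0.0
            if np.any(exact):
                # distance weights diverge at an exact match: all weight
                # concentrates there (ties averaged)
                out[q] = self.memberships_[exact].mean(axis=0)
                continue
            nn = np.argsort(d, kind="stable")[: self.k]
            w = d[nn] ** (-exponent)
            if not np.all(np.isfinite(w)):  # extreme m or tiny distances
                w = np.where(np.isfinite(w), 0.0, 1.0)
            out[q] = (w @ self.memberships_[nn]) / w.sum()
        return out

    def predict(self, X) -> np.ndarray:
        """Class with maximal membership; ties go to the lowest class."""
        mu = self.predict_memberships(X)
        return self.classes_[np.argmax(mu, axis=1)]
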
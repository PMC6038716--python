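"""Shrinkage-regularized linear discriminant analysis with pairwise
discriminants.

The decoder solves, for every class pair (a, b), the linear system
``Sigma_shrunk w = mu_a - mu_b`` on the pooled within-class covariance and
scores a trial by its signed distance from the pairwise decision boundary,
``w^T x - w^T (mu_a + mu_b) / 2``.  With many channels and few trials the
empirical covariance is singular, so it is shrunk analytically toward a
scaled identity (Ledoit-Wolf coefficient estimated from the class-centered
data); a pseudo-inverse is the last-resort fallback.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.linalg import LinAlgError, solve
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.covariance import ledoit_wolf_shrinkage

__all__ = ["ShrinkageLDA"]


class ShrinkageLDA(BaseEstimator, ClassifierMixin):
    """LDA classifier exposing one discriminant per class pair.

    Parameters
    ----------
    shrinkage : "auto" or float in [0, 1]
        Covariance regularization ``(1 - lam) S + lam * (tr S / p) I``.
        "auto" estimates ``lam`` by the Ledoit-Wolf formula on the
        class-centered training data; 0 is plain pooled-covariance LDA.

    Attributes
    ----------
    classes_ : ndarray
        Class labels in sorted order.
    means_ : ndarray (n_classes, n_features)
    covariance_ : ndarray (n_features, n_features)
        Shrunk pooled within-class covariance.
    shrinkage_ : float
        The shrinkage coefficient actually used.
    pairs_ : list of (int, int)
        Class-index pairs, one per discriminant, ``combinations(range(k), 2)``.
    weights_ : ndarray (n_pairs, n_features)
    biases_ : ndarray (n_pairs,)
    """

    def __init__(self, shrinkage: str | float = "auto"):
        self.shrinkage = shrinkage

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (trials x features)")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least two classes")
        n, p = X.shape
        counts = np.bincount(y_idx, minlength=k)
        if counts.min() < 2:
            bad = self.classes_[counts < 2]
            raise ValueError(f"class(es) {bad.tolist()} have fewer than 2 trials")
        means = np.stack([X[y_idx == i].mean(axis=0) for i in range(k)])
        centered = X - means[y_idx]
        # pooled within-class covariance, ddof = n - k
        S = centered.T @ centered / (n - k)
        if self.shrinkage == "auto":
            lam = float(ledoit_wolf_shrinkage(centered, assume_centered=True))
        else:
            lam = float(self.shrinkage)
            if not 0.0 <= lam <= 1.0:
                raise ValueError("shrinkage must be in [0, 1]")
        nu = np.trace(S) / p
        S_shrunk = (1.0 - lam) * S + lam * nu * np.eye(p)
        self.means_ = means
        self.covariance_ = S_shrunk
        self.shrinkage_ = lam
        self.pairs_ = list(combinations(range(k), 2))
        W = np.empty((len(self.pairs_), p))
        b = np.empty(len(self.pairs_))
        for d, (a, bb) in enumerate(self.pairs_):
            delta = means[a] - means[bb]
            try:
                w = solve(S_shrunk, delta, assume_a="pos")
            except (LinAlgError, np.linalg.LinAlgError):
                w = np.linalg.pinv(S_shrunk) @ delta
            W[d] = w
            b[d] = -w @ (means[a] + means[bb]) / 2.0
        self.weights_ = W
        self.biases_ = b
        return self

    def _check_fitted_X(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("ShrinkageLDA is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.weights_.shape[1]:
            raise ValueError(
                f"X must be (n, {self.weights_.shape[1]}), got {X.shape}"
            )
        return X

    def pairwise_decision_values(self, X: np.ndarray) -> np.ndarray:
        """Signed distances (up to covariance metric) from each pairwise
        boundary; shape (n_trials, n_pairs), positive favours the first
        class of the pair."""
        X = self._check_fitted_X(X)
        return X @ self.weights_.T + self.biases_

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """sklearn-style decision values: 1-D for binary problems, else the
        pairwise matrix."""
        dv = self.pairwise_decision_values(X)
        return dv[:, 0] if len(self.classes_) == 2 else dv

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Pairwise-vote prediction (ties broken toward the lower class)."""
        dv = self.pairwise_decision_values(X)
        k = len(self.classes_)
        votes = np.zeros((len(dv), k))
        margins = np.zeros((len(dv), k))
        for d, (a, b) in enumerate(self.pairs_):
            winner = np.where(dv[:, d] > 0, a, b)
            votes[np.arange(len(dv)), winner] += 1
            margins[:, a] += dv[:, d]
            margins[:, b] -= dv[:, d]
        # votes decide; summed margins break vote ties
        best = votes + 1e-9 * np.tanh(margins)
        return self.classes_[np.argmax(best, axis=1)]
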
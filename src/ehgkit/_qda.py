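"""Minimal Gaussian quadratic discriminant used in hot loops.

Fits one Gaussian per class (own mean and covariance, priors from class
frequencies) and scores by log-likelihood.  Functionally the same model as
``sklearn.discriminant_analysis.QuadraticDiscriminantAnalysis`` (a test
asserts agreement), but with explicit covariance regularization
(λ·trace(Σ)/d added to the diagonal when Σ is singular) and low per-fit
overhead, which matters inside the sequential-forward-selection inner loop.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_triangular

_BASE_LAMBDA = 1e-6


class FastQDA:
    """Two-class (or multi-class) quadratic discriminant on numpy arrays."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FastQDA":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes to fit QDA")
        n, d = X.shape
        self._params = []
        for c in self.classes_:
            Xc = X[y == c]
            if Xc.shape[0] < 2:
                raise ValueError(
                    f"class {c!r} has {Xc.shape[0]} sample(s); need >= 2")
            mu = Xc.mean(axis=0)
            cov = np.atleast_2d(np.cov(Xc, rowvar=False, ddof=1))
            chol, logdet = self._factor(cov, d)
            self._params.append(
                (mu, chol, logdet, np.log(Xc.shape[0] / n)))
        return self

    @staticmethod
    def _factor(cov: np.ndarray, d: int):
        """Cholesky factor of (possibly regularized) covariance."""
        lam = 0.0
        scale = np.trace(cov) / d
        if scale <= 0:
            scale = 1.0
        for _ in range(8):
            try:
                chol = np.linalg.cholesky(cov + lam * scale * np.eye(d))
                logdet = 2.0 * np.log(np.diag(chol)).sum()
                return chol, logdet
            except np.linalg.LinAlgError:
                lam = _BASE_LAMBDA if lam == 0 else lam * 100.0
        raise np.linalg.LinAlgError(
            "class covariance remained singular after regularization")

    def _log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        ll = np.empty((X.shape[0], len(self._params)))
        for j, (mu, chol, logdet, logprior) in enumerate(self._params):
            diff = X - mu
            # solve L z = diff^T  ->  mahalanobis = ||z||^2
            sol = solve_triangular(chol, diff.T, lower=True)
            maha = (sol ** 2).sum(axis=0)
            ll[:, j] = logprior - 0.5 * (logdet + maha)
        return ll

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self._log_likelihood(X), axis=1)]

    def predict_proba_of(self, X: np.ndarray, positive) -> np.ndarray:
        """Posterior probability of class ``positive``."""
        ll = self._log_likelihood(X)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        p /= p.sum(axis=1, keepdims=True)
        j = int(np.nonzero(self.classes_ == positive)[0][0])
        return p[:, j]
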
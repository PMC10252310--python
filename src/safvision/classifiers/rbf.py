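"""Radial basis function network classifier.

A hidden layer of Gaussian units h_j(x) = exp(−‖x − c_j‖² / (2σ²)) with a
single shared spread σ, centers placed by seeded k-means on the training
data, and a linear output layer solved in closed form by regularized least
squares against one-hot class targets.  The predicted label is the arg-max
output.  Optionally the output layer is fine-tuned by one of the named
first-order training algorithms, starting from the closed-form solution.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

from ._opt import minimize_network
from .base import SpiceClassifier


class RBFNetworkClassifier(SpiceClassifier):
    """Gaussian-hidden-layer network with a ridge-solved linear output.

    Parameters
    ----------
    n_hidden : int
        Number of Gaussian hidden units (k-means centers); capped at the
        training-set size.
    spread : float
        Shared Gaussian spread σ (> 0) on the standardized feature scale.
    ridge : float
        L2 regularization of the output-layer solve.
    training_algorithm : str or None
        None keeps the closed-form output layer; a T3..T13 symbol fine-tunes
        it with the shared optimizer interface; T1/T2 are recorded as
        metadata only (the closed-form solve already minimises the same
        least-squares objective).
    """

    def __init__(self, n_hidden: int = 25, spread: float = 1.0,
                 ridge: float = 1e-6, training_algorithm: str | None = None,
                 max_iter: int = 50, standardize: bool = True,
                 random_state: int | None = None):
        super().__init__(standardize=standardize, random_state=random_state)
        self.n_hidden = n_hidden
        self.spread = spread
        self.ridge = ridge
        self.training_algorithm = training_algorithm
        self.max_iter = max_iter

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        d2 = (np.sum(X ** 2, axis=1)[:, None]
              + np.sum(self.centers_ ** 2, axis=1)[None, :]
              - 2.0 * X @ self.centers_.T)
        np.maximum(d2, 0.0, out=d2)
        return np.exp(-d2 / (2.0 * self.spread ** 2))

    def _fit(self, X: np.ndarray, y_idx: np.ndarray) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be > 0")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        n_centers = min(self.n_hidden, X.shape[0])
        seed = int(self._rng_.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=n_centers, n_init=4, random_state=seed)
        km.fit(X)
        self.centers_ = km.cluster_centers_

        n_classes = self.classes_.size
        T = np.eye(n_classes)[y_idx]
        Phi = self._hidden(X)
        Phi1 = np.hstack([Phi, np.ones((Phi.shape[0], 1))])
        A = Phi1.T @ Phi1 + self.ridge * np.eye(Phi1.shape[1])
        W = np.linalg.solve(A, Phi1.T @ T)

        algo = self.training_algorithm
        if algo in ("T1", "T2") or algo is None:
            self.algorithm_used_ = algo          # metadata only
        else:
            w0 = W.ravel()

            def fun(wv: np.ndarray):
                Wm = wv.reshape(W.shape)
                r = Phi1 @ Wm - T
                loss = 0.5 * float(np.sum(r * r)) \
                    + 0.5 * self.ridge * float(wv @ wv)
                grad = (Phi1.T @ r + self.ridge * Wm).ravel()
                return loss, grad

            W = minimize_network(fun, w0, algo, self.max_iter).reshape(W.shape)
            self.algorithm_used_ = algo
        self.weights_ = W

    def decision_function(self, X):
        from sklearn.utils.validation import check_array, check_is_fitted
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=np.float64)
        Phi = self._hidden(self._transform(X))
        return np.hstack([Phi, np.ones((Phi.shape[0], 1))]) @ self.weights_

    def _predict_indices(self, X: np.ndarray) -> np.ndarray:
        Phi = self._hidden(X)
        out = np.hstack([Phi, np.ones((Phi.shape[0], 1))]) @ self.weights_
        return np.argmax(out, axis=1)
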
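"""Support vector machine family (one-vs-one RBF kernel, sklearn backend)."""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .base import SpiceClassifier


class SVMClassifier(SpiceClassifier):
    """Maximum-margin classifier with an RBF kernel and one-vs-one voting.

    The quadratic-programming backend is scikit-learn's SVC; this wrapper
    adds the common z-scoring and the shared estimator contract.
    """

    def __init__(self, C: float = 10.0, kernel: str = "rbf",
                 gamma: str | float = "scale", standardize: bool = True,
                 random_state: int | None = None):
        super().__init__(standardize=standardize, random_state=random_state)
        self.C = C
        self.kernel = kernel
        self.gamma = gamma

    def _fit(self, X: np.ndarray, y_idx: np.ndarray) -> None:
        self.svc_ = SVC(C=self.C, kernel=self.kernel, gamma=self.gamma,
                        decision_function_shape="ovo",
                        random_state=self.random_state)
        self.svc_.fit(X, y_idx)

    def _predict_indices(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.svc_.predict(X), dtype=np.int64)


def tune_svm(X, y, Cs=(0.1, 1.0, 10.0, 100.0),
             gammas=("scale", 0.01, 0.1, 1.0), cv: int = 5,
             random_state: int | None = None) -> SVMClassifier:
    """Pick C and gamma by a cross-validated grid and return the fitted model."""
    X = np.asarray(X, dtype=np.float64)
    mean, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mean) / np.where(sd > 0, sd, 1.0)
    grid = GridSearchCV(SVC(kernel="rbf"), {"C": list(Cs), "gamma": list(gammas)},
                        cv=cv)
    grid.fit(Xs, y)
    best = SVMClassifier(C=grid.best_params_["C"], gamma=grid.best_params_["gamma"],
                         random_state=random_state)
    return best.fit(X, y)
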
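"""k-nearest-neighbor classifier with explicit, documented tie-breaking."""

from __future__ import annotations

import numpy as np

from .base import SpiceClassifier


class KNNClassifier(SpiceClassifier):
    """Memorise the training set; classify by majority vote of the k nearest
    training points under Euclidean distance.

    Vote ties break toward the class with the smaller summed distance among
    the tied neighbors, then toward the lexicographically smaller class code.
    """

    def __init__(self, k: int = 1, standardize: bool = True,
                 random_state: int | None = None):
        super().__init__(standardize=standardize, random_state=random_state)
        self.k = k

    def _fit(self, X: np.ndarray, y_idx: np.ndarray) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > X.shape[0]:
            raise ValueError(f"k={self.k} exceeds training size {X.shape[0]}")
        self.X_train_ = X
        self.y_train_ = y_idx

    def _predict_indices(self, X: np.ndarray) -> np.ndarray:
        # squared distances suffice for ranking and for the tie-break sums
        d2 = (np.sum(X ** 2, axis=1)[:, None]
              + np.sum(self.X_train_ ** 2, axis=1)[None, :]
              - 2.0 * X @ self.X_train_.T)
        np.maximum(d2, 0.0, out=d2)
        order = np.argsort(d2, axis=1, kind="stable")[:, :self.k]
        n_classes = self.classes_.size
        out = np.empty(X.shape[0], dtype=np.int64)
        for i in range(X.shape[0]):
            nbr = order[i]
            labels = self.y_train_[nbr]
            votes = np.bincount(labels, minlength=n_classes)
            best = np.flatnonzero(votes == votes.max())
            if best.size > 1:
                dists = np.sqrt(d2[i, nbr])
                sums = np.array([dists[labels == c].sum() for c in best])
                best = best[np.flatnonzero(sums == sums.min())]
            out[i] = best.min()   # classes_ is sorted: min index = lexicographic
        return out
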
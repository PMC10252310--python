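"""Learning vector quantization (LVQ1) classifier.

The input space is partitioned by labeled codebook (prototype) vectors, a
configurable number per class, initialised at class-wise k-means centers.
The LVQ1 rule moves the winning prototype toward a same-class input and away
from a different-class input, with a linearly decaying learning rate.
Prediction assigns the label of the nearest prototype.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

from .base import SpiceClassifier


class LVQClassifier(SpiceClassifier):
    def __init__(self, codebooks_per_class: int = 2, lr_initial: float = 0.1,
                 epochs: int = 100, standardize: bool = True,
                 random_state: int | None = None):
        super().__init__(standardize=standardize, random_state=random_state)
        self.codebooks_per_class = codebooks_per_class
        self.lr_initial = lr_initial
        self.epochs = epochs

    def _fit(self, X: np.ndarray, y_idx: np.ndarray) -> None:
        if self.codebooks_per_class < 1:
            raise ValueError("codebooks_per_class must be >= 1")
        protos, proto_labels = [], []
        # one shared k-means seed keeps initialisation equivariant under
        # class relabeling (each class's prototypes depend on its data only)
        km_seed = int(self._rng_.integers(0, 2**31 - 1))
        for c in range(self.classes_.size):
            Xc = X[y_idx == c]
            k = min(self.codebooks_per_class, Xc.shape[0])
            if k == 1:
                centers = Xc.mean(axis=0, keepdims=True)
            else:
                km = KMeans(n_clusters=k, n_init=4, random_state=km_seed)
                centers = km.fit(Xc).cluster_centers_
                centers = centers[np.lexsort(centers.T)]  # class-local order
            protos.append(centers)
            proto_labels.extend([c] * k)
        W = np.vstack(protos)
        labels = np.asarray(proto_labels)

        n_steps = self.epochs * X.shape[0]
        step = 0
        for _ in range(self.epochs):
            order = self._rng_.permutation(X.shape[0])
            for i in order:
                lr = self.lr_initial * (1.0 - step / max(n_steps, 1))
                x = X[i]
                win = int(np.argmin(((W - x) ** 2).sum(axis=1)))
                sign = 1.0 if labels[win] == y_idx[i] else -1.0
                W[win] += sign * lr * (x - W[win])
                step += 1
        self.prototypes_ = W
        self.prototype_labels_ = labels

    def _predict_indices(self, X: np.ndarray) -> np.ndarray:
        d2 = (np.sum(X ** 2, axis=1)[:, None]
              + np.sum(self.prototypes_ ** 2, axis=1)[None, :]
              - 2.0 * X @ self.prototypes_.T)
        return self.prototype_labels_[np.argmin(d2, axis=1)]
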
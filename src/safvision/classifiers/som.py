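"""Self-organizing map used as a classifier.

A rectangular grid of competitive units is trained unsupervised with a
Gaussian neighborhood whose width and learning rate decay exponentially.
After training, each unit is labeled by the majority class of the training
samples mapped to it (unvisited units inherit the label of the nearest
labeled unit); prediction maps a sample to its best-matching unit's label.
Because training ignores the labels, the classifier is exactly equivariant
under class relabeling.
"""

from __future__ import annotations

import numpy as np

from .base import SpiceClassifier


class SOMClassifier(SpiceClassifier):
    def __init__(self, grid: tuple[int, int] = (10, 10), epochs: int = 200,
                 lr_initial: float = 0.5, sigma_initial: float | None = None,
                 standardize: bool = True, random_state: int | None = None):
        super().__init__(standardize=standardize, random_state=random_state)
        self.grid = grid
        self.epochs = epochs
        self.lr_initial = lr_initial
        self.sigma_initial = sigma_initial

    def _fit(self, X: np.ndarray, y_idx: np.ndarray) -> None:
        gh, gw = self.grid
        n_units = gh * gw
        rows, cols = np.divmod(np.arange(n_units), gw)
        coords = np.stack([rows, cols], axis=1).astype(np.float64)
        grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)

        sigma0 = self.sigma_initial or max(gh, gw) / 2.0
        sigma_final, lr_final = 0.5, 0.01
        n_steps = self.epochs * X.shape[0]

        weights = self._rng_.normal(0.0, 0.5, (n_units, X.shape[1]))
        step = 0
        for _ in range(self.epochs):
            order = self._rng_.permutation(X.shape[0])
            for i in order:
                frac = step / max(n_steps - 1, 1)
                lr = self.lr_initial * (lr_final / self.lr_initial) ** frac
                sig = sigma0 * (sigma_final / sigma0) ** frac
                x = X[i]
                bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
                h = np.exp(-grid_d2[bmu] / (2.0 * sig ** 2))
                weights += lr * h[:, None] * (x - weights)
                step += 1
        self.weights_ = weights
        self.grid_coords_ = coords

        # post-hoc labeling by majority vote of mapped training samples
        bmus = np.argmin(
            ((X[:, None, :] - weights[None, :, :]) ** 2).sum(-1), axis=1)
        n_classes = self.classes_.size
        labels = np.full(n_units, -1, dtype=np.int64)
        for u in np.unique(bmus):
            mapped = np.flatnonzero(bmus == u)
            votes = np.bincount(y_idx[mapped], minlength=n_classes)
            best = np.flatnonzero(votes == votes.max())
            if best.size == 1:
                labels[u] = int(best[0])
            else:
                # vote tie: label-symmetric break by the closest mapped sample
                d2 = ((X[mapped] - weights[u]) ** 2).sum(axis=1)
                order = mapped[np.argsort(d2, kind="stable")]
                for i in order:
                    if y_idx[i] in best:
                        labels[u] = int(y_idx[i])
                        break
        unlabeled = labels < 0
        if unlabeled.any():
            lab_units = np.flatnonzero(~unlabeled)
            d2 = ((weights[unlabeled][:, None, :]
                   - weights[lab_units][None, :, :]) ** 2).sum(-1)
            labels[unlabeled] = labels[lab_units[np.argmin(d2, axis=1)]]
        self.unit_labels_ = labels

    def _predict_indices(self, X: np.ndarray) -> np.ndarray:
        d2 = (np.sum(X ** 2, axis=1)[:, None]
              + np.sum(self.weights_ ** 2, axis=1)[None, :]
              - 2.0 * X @ self.weights_.T)
        return self.unit_labels_[np.argmin(d2, axis=1)]
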
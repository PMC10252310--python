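"""Shared estimator plumbing: scaling, label handling, accuracy, persistence."""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

MODEL_FORMAT_VERSION = 1


def accuracy_counts(y_true, y_pred) -> tuple[int, int]:
    """(correct, misclassified) counts for the accuracy ratio."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    if y_true.size == 0:
        raise ValueError("empty input")
    n_p = int(np.sum(y_true == y_pred))
    return n_p, int(y_true.size - n_p)


def accuracy(y_true, y_pred) -> float:
    """Classification accuracy in percent: 100 * n_p / (n_p + n_mp)."""
    n_p, n_mp = accuracy_counts(y_true, y_pred)
    return 100.0 * n_p / (n_p + n_mp)


def per_class_accuracy(y_true, y_pred) -> dict:
    """Accuracy (percent) restricted to each true class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = {}
    for label in np.unique(y_true):
        sel = y_true == label
        out[label] = accuracy(y_true[sel], y_pred[sel])
    return out


class SpiceClassifier(ClassifierMixin, BaseEstimator):
    """Base class: validation, optional z-scoring, label encoding.

    Subclasses implement ``_fit(X, y_idx)`` and ``_predict_indices(X)`` on
    the scaled feature space; class labels are mapped to indices into the
    sorted ``classes_`` array.
    """

    def __init__(self, standardize: bool = True, random_state: int | None = None):
        self.standardize = standardize
        self.random_state = random_state

    # -- scaling -----------------------------------------------------------
    def _fit_scaler(self, X: np.ndarray) -> np.ndarray:
        if self.standardize:
            self.scale_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_std_ = np.where(sd > 0, sd, 1.0)
        else:
            self.scale_mean_ = np.zeros(X.shape[1])
            self.scale_std_ = np.ones(X.shape[1])
        return (X - self.scale_mean_) / self.scale_std_

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scale_mean_) / self.scale_std_

    # -- sklearn contract --------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training set must contain at least 2 classes")
        self.n_features_in_ = X.shape[1]
        Xs = self._fit_scaler(X)
        self._rng_ = np.random.default_rng(self.random_state)
        self._fit(Xs, y_idx)
        return self

    def predict(self, X):
        check_is_fitted(self, "classes_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature length {X.shape[1]} != trained length {self.n_features_in_}")
        idx = self._predict_indices(self._transform(X))
        return self.classes_[idx]

    # -- subclass hooks ----------------------------------------------------
    def _fit(self, X: np.ndarray, y_idx: np.ndarray) -> None:
        raise NotImplementedError

    def _predict_indices(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def save_model(model, path: str | Path) -> Path:
    """Persist a fitted estimator as a versioned archive."""
    check_is_fitted(model, "classes_")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "class_name": type(model).__name__,
        "module": type(model).__module__,
        "params": model.get_params(),
        "state": {k: v for k, v in model.__dict__.items() if k.endswith("_")},
    }
    path = Path(path)
    joblib.dump(payload, path)
    return path


def load_model(path: str | Path):
    """Load an estimator saved with :func:`save_model`."""
    import importlib

    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    cls = getattr(importlib.import_module(payload["module"]), payload["class_name"])
    model = cls(**payload["params"])
    model.__dict__.update(payload["state"])
    return model
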
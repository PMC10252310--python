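"""Seeded, re-runnable experiment designs over the feature tables.

Covers the study's five designs: side-by-side classifier comparison,
one-factor-at-a-time RBF hyperparameter sweeps (hidden neurons, spread,
training algorithm), feature-group sensitivity analysis, generalizability
under a shrinking training fraction, and LSD mean separation of chemistry
or feature values.  Every report is a pure function of (data, seeds, spec):
identical reruns produce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .classifiers import RBFNetworkClassifier, accuracy
from .features import FEATURE_NAMES, SELECTED_14

#: Table-style feature groups over the 21-element vector
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "All": FEATURE_NAMES,
    "Selected14": SELECTED_14,
    "HSI": ("h_ave", "h_std", "s_ave", "s_std", "i_ave", "i_std"),
    "RGB": ("r_ave", "r_std", "g_ave", "g_std", "b_ave", "b_std"),
    "Lab": ("l_ave", "l_std", "a_ave", "a_std", "bstar_ave", "bstar_std"),
    "HSIstd": ("h_std", "s_std", "i_std"),
    "HSIave": ("h_ave", "s_ave", "i_ave"),
    "RGBave": ("r_ave", "g_ave", "b_ave"),
    "Labave": ("l_ave", "a_ave", "bstar_ave"),
    "RGBstd": ("r_std", "g_std", "b_std"),
    "Labstd": ("l_std", "a_std", "bstar_std"),
    "texture": ("smoothness", "uniformity", "entropy"),
}


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split: per-class train count = round(f * size)."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1) "
                             "(1.0 would leave the test set empty)")


def split(y, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return disjoint, exhaustive (train_idx, test_idx) index arrays."""
    y = np.asarray(y)
    rng = np.random.default_rng(spec.seed)
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    if spec.stratified:
        for label in np.unique(y):
            idx = np.flatnonzero(y == label)
            if idx.size < 2:
                raise ValueError(f"class {label!r} has fewer than 2 members")
            n_train = int(np.floor(spec.train_fraction * idx.size + 0.5))
            n_train = min(max(n_train, 1), idx.size - 1)
            perm = rng.permutation(idx)
            train.append(perm[:n_train])
            test.append(perm[n_train:])
    else:
        perm = rng.permutation(y.size)
        n_train = int(np.floor(spec.train_fraction * y.size + 0.5))
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _evaluate(model, X, y, train_idx, test_idx) -> dict:
    """Train/test/total accuracy row; total pools train and test predictions."""
    model.fit(X[train_idx], y[train_idx])
    pred_train = model.predict(X[train_idx])
    pred_test = model.predict(X[test_idx])
    y_all = np.concatenate([y[train_idx], y[test_idx]])
    pred_all = np.concatenate([pred_train, pred_test])
    return {
        "train": accuracy(y[train_idx], pred_train),
        "test": accuracy(y[test_idx], pred_test),
        "total": accuracy(y_all, pred_all),
    }


def compare_classifiers(X, y, specs: dict, split_spec: SplitSpec) -> pd.DataFrame:
    """Train every named estimator on one identical split.

    ``specs`` maps a family name to an (unfitted) estimator; returns a
    DataFrame with train/test/total accuracy per family.
    """
    if not specs:
        raise ValueError("need at least one classifier spec")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    train_idx, test_idx = split(y, split_spec)
    rows = {}
    for name, model in specs.items():
        rows[name] = _evaluate(clone(model), X, y, train_idx, test_idx)
    out = pd.DataFrame(rows).T
    out.index.name = "classifier"
    return out


def sweep_rbf(X, y, split_spec: SplitSpec,
              neurons: list[int] | None = None,
              spreads: list[float] | None = None,
              algorithms: list[str] | None = None,
              base: RBFNetworkClassifier | None = None) -> pd.DataFrame:
    """One-factor-at-a-time sweeps of the RBF design parameters.

    Each swept factor varies while the other two stay at the ``base``
    estimator's values; returns a tidy frame with columns (factor, value,
    train, test, total).
    """
    if not any([neurons, spreads, algorithms]):
        raise ValueError("at least one nonempty sweep grid is required")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    base = base if base is not None else RBFNetworkClassifier(random_state=0)
    train_idx, test_idx = split(y, split_spec)

    rows = []
    for factor, grid in (("neurons", neurons), ("spread", spreads),
                         ("algorithm", algorithms)):
        for value in (grid or []):
            model = clone(base)
            if factor == "neurons":
                model.set_params(n_hidden=int(value))
            elif factor == "spread":
                model.set_params(spread=float(value))
            else:
                model.set_params(training_algorithm=value)
            row = _evaluate(model, X, y, train_idx, test_idx)
            rows.append({"factor": factor, "value": value, **row})
    return pd.DataFrame(rows)


def sensitivity_analysis(features: pd.DataFrame, y,
                         split_spec: SplitSpec,
                         groups: dict[str, tuple[str, ...]] | None = None,
                         base: RBFNetworkClassifier | None = None) -> pd.DataFrame:
    """Accuracy of the RBF model per feature group, sorted by total accuracy.

    ``features`` is a frame whose columns include the 21 feature names.
    """
    groups = groups if groups is not None else FEATURE_GROUPS
    base = base if base is not None else RBFNetworkClassifier(random_state=0)
    y = np.asarray(y)
    for name, members in groups.items():
        unknown = set(members) - set(features.columns)
        if unknown:
            raise ValueError(f"group {name!r} references unknown features "
                             f"{sorted(unknown)}")
    train_idx, test_idx = split(y, split_spec)
    rows = {}
    for name, members in groups.items():
        Xg = features.loc[:, list(members)].to_numpy(dtype=np.float64)
        rows[name] = _evaluate(clone(base), Xg, y, train_idx, test_idx)
    out = pd.DataFrame(rows).T.sort_values("total", ascending=False)
    out.index.name = "features"
    return out


def generalizability(X, y, fractions=(0.8, 0.7, 0.6, 0.5),
                     base=None, seed: int = 0) -> pd.DataFrame:
    """Re-evaluate one estimator while shrinking the training fraction."""
    if not len(fractions):
        raise ValueError("empty fraction list")
    base = base if base is not None else RBFNetworkClassifier(random_state=0)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    rows = []
    for frac in fractions:
        spec = SplitSpec(train_fraction=float(frac), seed=seed)
        train_idx, test_idx = split(y, spec)
        row = _evaluate(clone(base), X, y, train_idx, test_idx)
        rows.append({"training_size_pct": round(100 * float(frac)), **row})
    return pd.DataFrame(rows).set_index("training_size_pct")


def per_class_accuracy_report(model, X, y, split_spec: SplitSpec) -> pd.DataFrame:
    """Per-class train/test/total accuracy plus the sample-weighted All column.

    A class absent from a partition yields NaN (undefined), never 0.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    train_idx, test_idx = split(y, split_spec)
    model = clone(model)
    model.fit(X[train_idx], y[train_idx])
    preds = {
        "Train": (y[train_idx], model.predict(X[train_idx])),
        "Test": (y[test_idx], model.predict(X[test_idx])),
    }
    preds["Total"] = (np.concatenate([preds["Train"][0], preds["Test"][0]]),
                      np.concatenate([preds["Train"][1], preds["Test"][1]]))
    classes = list(np.unique(y))
    table = {}
    for phase, (yt, yp) in preds.items():
        row = {}
        for c in classes:
            sel = yt == c
            row[str(c)] = accuracy(yt[sel], yp[sel]) if sel.any() else np.nan
        row["All"] = accuracy(yt, yp)
        table[phase] = row
    return pd.DataFrame(table).T


def repeated_split_accuracy(X, y, base, fraction: float, seeds) -> float:
    """Mean test accuracy over several split seeds (soft-monotonicity checks)."""
    accs = []
    for s in seeds:
        spec = SplitSpec(train_fraction=fraction, seed=int(s))
        train_idx, test_idx = split(np.asarray(y), spec)
        accs.append(_evaluate(clone(base), np.asarray(X, dtype=np.float64),
                              np.asarray(y), train_idx, test_idx)["test"])
    return float(np.mean(accs))
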
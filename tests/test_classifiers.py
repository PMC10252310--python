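"""The six classifier families: contracts, invariances, sanity accuracy."""

from __future__ import annotations

import numpy as np
import pytest

from safvision.classifiers import (FAMILIES, KNNClassifier, LVQClassifier,
                                   MLPNetworkClassifier, RBFNetworkClassifier,
                                   SOMClassifier, SVMClassifier, accuracy,
                                   accuracy_counts, load_model,
                                   per_class_accuracy, save_model)


def _two_clusters(rng, n=100, d=6.0):
    """Two well-separated Gaussian clusters (d' ~ 6)."""
    half = n // 2
    X = np.vstack([rng.normal(0.0, 1.0, (half, 2)),
                   rng.normal([d, 0.0], 1.0, (n - half, 2))])
    y = np.array(["low"] * half + ["high"] * (n - half))
    perm = rng.permutation(n)
    return X[perm], y[perm]


def _fast_params(name):
    return {"SOM": {"epochs": 30}, "LVQ": {"epochs": 30}}.get(name, {})


# --- accuracy metric -------------------------------------------------------


def test_accuracy_ratio():
    assert accuracy(["a", "b", "c", "d"], ["a", "b", "c", "d"]) == 100.0
    assert accuracy(["a", "b", "c", "d"], ["a", "b", "c", "x"]) == 75.0
    assert accuracy(["a", "b"], ["b", "a"]) == 0.0
    assert accuracy_counts([1, 1, 2], [1, 2, 2]) == (2, 1)
    with pytest.raises(ValueError):
        accuracy([], [])


def test_per_class_accuracy_breakdown():
    out = per_class_accuracy(["a", "a", "b", "b"], ["a", "x", "b", "b"])
    assert out["a"] == 50.0 and out["b"] == 100.0


# --- shared contracts ------------------------------------------------------


@pytest.mark.parametrize("name", list(FAMILIES))
def test_every_family_on_separated_clusters(name, rng):
    X, y = _two_clusters(rng)
    model = FAMILIES[name](random_state=0, **_fast_params(name))
    model.fit(X[:70], y[:70])
    assert accuracy(y[70:], model.predict(X[70:])) >= 95.0


@pytest.mark.parametrize("name", list(FAMILIES))
def test_label_permutation_equivariance(name, rng):
    X = rng.normal(size=(60, 3))
    y = np.array(list("abc") * 20)
    perm = {"a": "c", "b": "a", "c": "b"}
    m1 = FAMILIES[name](random_state=7, **_fast_params(name)).fit(X, y)
    m2 = FAMILIES[name](random_state=7, **_fast_params(name)).fit(
        X, np.array([perm[v] for v in y]))
    p1 = np.array([perm[v] for v in m1.predict(X)])
    assert np.array_equal(p1, m2.predict(X))


@pytest.mark.parametrize("cls", [KNNClassifier, RBFNetworkClassifier,
                                 SOMClassifier, LVQClassifier])
def test_feature_scaling_contract(cls, rng):
    X, y = _two_clusters(rng, n=80)
    kwargs = {"epochs": 30} if cls in (SOMClassifier, LVQClassifier) else {}
    m1 = cls(random_state=3, **kwargs).fit(X, y)
    X_scaled = X.copy()
    X_scaled[:, 0] *= 1000.0
    m2 = cls(random_state=3, **kwargs).fit(X_scaled, y)
    assert np.array_equal(m1.predict(X), m2.predict(X_scaled))


@pytest.mark.parametrize("name", list(FAMILIES))
def test_single_class_rejected(name):
    X = np.zeros((10, 2))
    y = np.array(["only"] * 10)
    with pytest.raises(ValueError):
        FAMILIES[name](random_state=0).fit(X, y)


def test_feature_length_mismatch_rejected(rng):
    X, y = _two_clusters(rng, n=40)
    model = KNNClassifier(random_state=0).fit(X, y)
    with pytest.raises(ValueError, match="feature length"):
        model.predict(np.zeros((3, 5)))


# --- KNN -------------------------------------------------------------------


def test_knn_k1_training_points_return_own_labels(rng):
    X = rng.normal(size=(30, 4))
    y = rng.choice(["u", "v", "w"], size=30)
    while len(set(y)) < 2:
        y = rng.choice(["u", "v", "w"], size=30)
    model = KNNClassifier(k=1, random_state=0).fit(X, y)
    assert accuracy(y, model.predict(X)) == 100.0


def test_knn_tie_broken_by_summed_distance():
    X = np.array([[0.0], [1.0]])
    y = np.array(["near", "far"])
    model = KNNClassifier(k=2, standardize=False).fit(X, y)
    assert model.predict([[0.4]])[0] == "near"
    assert model.predict([[0.6]])[0] == "far"


def test_knn_k_exceeding_training_size_rejected(rng):
    X, y = _two_clusters(rng, n=10)
    with pytest.raises(ValueError, match="exceeds"):
        KNNClassifier(k=11).fit(X, y)


# --- RBF -------------------------------------------------------------------


def test_rbf_interpolating_regime_perfect_training(rng):
    X, y = _two_clusters(rng, n=40)
    model = RBFNetworkClassifier(n_hidden=40, spread=0.1,
                                 random_state=0).fit(X, y)
    assert accuracy(y, model.predict(X)) == 100.0


def test_rbf_invalid_spread_rejected(rng):
    X, y = _two_clusters(rng, n=20)
    with pytest.raises(ValueError, match="spread"):
        RBFNetworkClassifier(spread=0.0).fit(X, y)


def test_rbf_spread_sweep_interior_optimum(rng):
    """Accuracy rises then falls with spread (peak not at the sweep edges).

    XOR-arranged clusters: a tiny spread leaves test points outside every
    Gaussian's reach, a huge spread degenerates to a (useless here) linear
    rule, and only an intermediate spread resolves the structure.
    """
    centers = {"a": [(0, 0), (4, 4)], "b": [(0, 4), (4, 0)]}
    X, y = [], []
    for label, cs in centers.items():
        for c in cs:
            X.append(rng.normal(c, 0.8, (30, 2)))
            y.extend([label] * 30)
    X = np.vstack(X)
    y = np.array(y)
    perm = rng.permutation(len(y))
    X, y = X[perm], y[perm]
    accs = []
    for spread in (0.01, 1.0, 1000.0):
        model = RBFNetworkClassifier(n_hidden=12, spread=spread,
                                     random_state=0).fit(X[:90], y[:90])
        accs.append(accuracy(y[90:], model.predict(X[90:])))
    assert max(accs) == accs[1] and accs[1] > accs[0] and accs[1] > accs[2]


def test_rbf_output_fine_tuning_algorithms_run(rng):
    X, y = _two_clusters(rng, n=60)
    for algo in ("T3", "T4", "T9"):
        model = RBFNetworkClassifier(n_hidden=8, training_algorithm=algo,
                                     random_state=0).fit(X, y)
        assert model.algorithm_used_ == algo
        assert accuracy(y, model.predict(X)) >= 95.0


# --- LVQ -------------------------------------------------------------------


def test_lvq_class_mean_prototypes_give_nearest_mean_rule(rng):
    X, y = _two_clusters(rng, n=60)
    model = LVQClassifier(codebooks_per_class=1, epochs=0,
                          standardize=False, random_state=0).fit(X, y)
    mean_high = X[y == "high"].mean(axis=0)
    mean_low = X[y == "low"].mean(axis=0)
    probe = np.array([[0.2, 0.1], [5.5, -0.4]])
    want = ["high" if np.linalg.norm(p - mean_high) < np.linalg.norm(p - mean_low)
            else "low" for p in probe]
    assert list(model.predict(probe)) == want


# --- persistence -----------------------------------------------------------


def test_model_save_load_roundtrip(tmp_path, rng):
    X, y = _two_clusters(rng, n=50)
    model = RBFNetworkClassifier(n_hidden=10, random_state=0).fit(X, y)
    path = save_model(model, tmp_path / "model.joblib")
    loaded = load_model(path)
    assert np.array_equal(model.predict(X), loaded.predict(X))
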
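"""Splits, comparison reports, sweeps, sensitivity and generalizability."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.dummy import DummyClassifier

from safvision.classifiers import KNNClassifier, RBFNetworkClassifier
from safvision.experiments import (FEATURE_GROUPS, SplitSpec,
                                   compare_classifiers, generalizability,
                                   per_class_accuracy_report,
                                   repeated_split_accuracy,
                                   sensitivity_analysis, split, sweep_rbf)
from safvision.features import FEATURE_NAMES


def _paper_sized_labels():
    return np.repeat([f"C{i}" for i in range(7)], 60)


def test_split_counts_match_rounded_fractions():
    y = _paper_sized_labels()
    train, test = split(y, SplitSpec(train_fraction=0.8, seed=0))
    assert (len(train), len(test)) == (336, 84)
    for label in np.unique(y):
        assert (y[train] == label).sum() == 48
        assert (y[test] == label).sum() == 12
    # disjoint and exhaustive
    assert np.array_equal(np.sort(np.concatenate([train, test])),
                          np.arange(420))


def test_full_fraction_rejected():
    with pytest.raises(ValueError, match="strictly"):
        SplitSpec(train_fraction=1.0)


def test_split_seed_determinism():
    y = _paper_sized_labels()
    a = split(y, SplitSpec(seed=9))
    b = split(y, SplitSpec(seed=9))
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    c = split(y, SplitSpec(seed=10))
    assert not np.array_equal(a[0], c[0])


def test_tiny_class_rejected():
    with pytest.raises(ValueError, match="fewer than 2"):
        split(np.array(["a", "a", "b"]), SplitSpec())


# --- comparison ------------------------------------------------------------


def test_compare_classifiers_with_majority_baseline(small_features):
    _, X, y = small_features
    report = compare_classifiers(
        X, y,
        {"KNN": KNNClassifier(random_state=0),
         "majority": DummyClassifier(strategy="most_frequent")},
        SplitSpec(seed=1))
    assert list(report.columns) == ["train", "test", "total"]
    # conflict-free synthetic features: KNN memorises the training partition
    assert report.loc["KNN", "train"] == 100.0
    # a majority-class dummy scores the largest class share (balanced: 1/7)
    assert report.loc["majority", "total"] == pytest.approx(100 / 7, abs=0.5)


def test_compare_classifiers_reports_are_byte_identical(small_features):
    _, X, y = small_features
    specs = {"KNN": KNNClassifier(random_state=0)}
    a = compare_classifiers(X, y, specs, SplitSpec(seed=4)).to_csv()
    b = compare_classifiers(X, y, specs, SplitSpec(seed=4)).to_csv()
    assert a == b


def test_compare_classifiers_requires_specs(small_features):
    _, X, y = small_features
    with pytest.raises(ValueError):
        compare_classifiers(X, y, {}, SplitSpec())


# --- sweeps ----------------------------------------------------------------


def test_neuron_sweep_training_accuracy_trends_up(small_features):
    _, X, y = small_features
    out = sweep_rbf(X, y, SplitSpec(seed=2), neurons=[2, 8, 20],
                    base=RBFNetworkClassifier(spread=1.0, random_state=0))
    train = out[out["factor"] == "neurons"]["train"].to_numpy()
    assert train[-1] >= train[0]


def test_single_point_grid_gives_one_row(small_features):
    _, X, y = small_features
    out = sweep_rbf(X, y, SplitSpec(seed=2), spreads=[1.0])
    assert len(out) == 1 and out.iloc[0]["factor"] == "spread"


def test_empty_grids_rejected(small_features):
    _, X, y = small_features
    with pytest.raises(ValueError):
        sweep_rbf(X, y, SplitSpec(seed=2))


# --- sensitivity -----------------------------------------------------------


def test_sensitivity_rows_and_texture_rank(small_features):
    table, _, y = small_features
    report = sensitivity_analysis(table, y, SplitSpec(seed=3))
    assert {"All", "Selected14", "texture"} <= set(report.index)
    assert list(report["total"]) == sorted(report["total"], reverse=True)
    # color carries the class signal by construction; texture alone ranks low
    assert list(report.index).index("texture") >= len(report) - 3


def test_sensitivity_unknown_feature_rejected(small_features):
    table, _, y = small_features
    with pytest.raises(ValueError, match="unknown features"):
        sensitivity_analysis(table, y, SplitSpec(),
                             groups={"bad": ("no_such_feature",)})


def test_feature_groups_match_the_table_layout():
    assert len(FEATURE_GROUPS["All"]) == 21
    assert len(FEATURE_GROUPS["Selected14"]) == 14
    for name, members in FEATURE_GROUPS.items():
        assert set(members) <= set(FEATURE_NAMES), name


# --- generalizability ------------------------------------------------------


def test_generalizability_four_rows(small_features):
    _, X, y = small_features
    report = generalizability(X, y, fractions=(0.8, 0.7, 0.6, 0.5),
                              base=KNNClassifier(random_state=0), seed=0)
    assert list(report.index) == [80, 70, 60, 50]
    assert report.shape == (4, 3)


def test_generalizability_empty_fractions_rejected(small_features):
    _, X, y = small_features
    with pytest.raises(ValueError):
        generalizability(X, y, fractions=())


def test_half_training_not_better_than_four_fifths(small_features):
    """Soft monotonicity: less training data should not help (2-pt slack)."""
    _, X, y = small_features
    base = KNNClassifier(k=3, random_state=0)
    seeds = range(5)
    acc_half = repeated_split_accuracy(X, y, base, 0.5, seeds)
    acc_most = repeated_split_accuracy(X, y, base, 0.8, seeds)
    assert acc_half <= acc_most + 2.0


# --- per-class report ------------------------------------------------------


def test_perfect_classifier_fills_the_table_with_100(rng):
    y = np.repeat(["a", "b", "c"], 20)
    X = (np.array([0, 1, 2]).repeat(20)[:, None]
         + rng.normal(0, 0.01, (60, 1)))
    report = per_class_accuracy_report(KNNClassifier(random_state=0), X, y,
                                       SplitSpec(seed=0))
    assert np.allclose(report.to_numpy(), 100.0)


def test_all_column_is_weighted_mean_of_class_cells(small_features):
    _, X, y = small_features
    report = per_class_accuracy_report(KNNClassifier(k=3, random_state=0),
                                       X, y, SplitSpec(seed=1))
    counts = {c: (y == c).sum() for c in np.unique(y)}
    total_row = report.loc["Total"]
    weighted = sum(total_row[c] * counts[c] for c in counts) / sum(counts.values())
    assert total_row["All"] == pytest.approx(weighted)


def test_class_absent_from_test_fold_is_nan_not_zero():
    y = np.array(["a"] * 20 + ["b"] * 20 + ["rare"] * 2)
    X = np.concatenate([np.zeros(20), np.ones(20), np.full(2, 5.0)])[:, None]
    found = None
    for seed in range(60):  # a non-stratified split that drops 'rare' from test
        spec = SplitSpec(train_fraction=0.8, stratified=False, seed=seed)
        _, test_idx = split(y, spec)
        if "rare" not in y[test_idx]:
            found = spec
            break
    assert found is not None
    report = per_class_accuracy_report(KNNClassifier(random_state=0), X, y, found)
    assert np.isnan(report.loc["Test", "rare"])
    assert report.loc["Train", "rare"] == 100.0
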
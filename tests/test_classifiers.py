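"""Supervised stages: losses, mono/poly, deep features, preprocessing, harness."""

import math

import numpy as np
import pandas as pd
import pytest

from hemamorph.classifiers import (
    EIGHT_FAMILIES,
    MonoPolyConfig,
    ResidualBackbone,
    binary_cross_entropy,
    compare_classifiers,
    deep_features,
    discretize,
    generate_report,
    outlier_filter,
    train_mono_poly,
)


class TestBinaryCrossEntropy:
    def test_near_perfect_prediction(self):
        assert binary_cross_entropy(np.array([1.0]), np.array([1 - 1e-12])) < 1e-9

    def test_uninformative_prediction(self):
        val = binary_cross_entropy(np.array([1.0]), np.array([0.5]))
        assert val == pytest.approx(math.log(2), abs=1e-12)
        assert val == pytest.approx(0.693147, abs=1e-6)

    def test_two_sample_closed_form(self):
        val = binary_cross_entropy(np.array([1.0, 0.0]), np.array([0.9, 0.1]))
        assert val == pytest.approx(-math.log(0.9), abs=1e-9)
        assert val == pytest.approx(0.105361, abs=1e-6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            binary_cross_entropy(np.array([1.0]), np.array([0.5, 0.5]))


def lobe_feature_table(n_per_class: int, seed: int):
    """Separable mono/poly construction: lobe count is discriminative."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for _ in range(n_per_class):
        rows.append({"lobe_count": 1, "area": rng.normal(120, 8), "ecc": rng.uniform(0, 0.3)})
        labels.append("mononuclear")
        rows.append({"lobe_count": rng.integers(2, 5), "area": rng.normal(100, 8), "ecc": rng.uniform(0, 0.3)})
        labels.append("polynuclear")
    return pd.DataFrame(rows), labels


class TestMonoPoly:
    def test_separable_lobe_counts_high_accuracy(self):
        table, labels = lobe_feature_table(200, seed=42)
        model = train_mono_poly(table, labels, seed=42)
        hold_table, hold_labels = lobe_feature_table(50, seed=43)
        preds = model.predict(hold_table)
        acc = np.mean(preds == np.array(hold_labels))
        assert acc >= 0.95

    def test_zero_epochs_predicts_prior(self):
        table, labels = lobe_feature_table(10, seed=0)
        model = train_mono_poly(table, labels, MonoPolyConfig(epochs=0), seed=0)
        preds = model.predict(table)
        assert len(set(preds)) == 1

    def test_single_class_rejected(self):
        table, labels = lobe_feature_table(10, seed=1)
        with pytest.raises(ValueError):
            train_mono_poly(table, ["mononuclear"] * len(table), seed=0)

    def test_fixed_seed_identical_curves(self):
        table, labels = lobe_feature_table(40, seed=2)
        m1 = train_mono_poly(table, labels, seed=5)
        m2 = train_mono_poly(table, labels, seed=5)
        assert m1.val_curve == m2.val_curve


@pytest.fixture(scope="module")
def backbone():
    return ResidualBackbone(seed=42)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(4)
    X = np.vstack([rng.normal(0, 0.3, (60, 4)), rng.normal(3, 0.3, (60, 4))])
    y = ["neg"] * 60 + ["pos"] * 60
    return pd.DataFrame(X), y


class TestDeepFeatures:
    def test_embedding_length_is_2048(self, backbone):
        patch = np.random.default_rng(0).uniform(0, 1, (40, 40, 3))
        assert deep_features(patch, backbone).shape == (2048,)

    def test_identical_patches_identical_vectors(self, backbone):
        patch = np.random.default_rng(1).uniform(0, 1, (40, 40, 3))
        assert np.array_equal(deep_features(patch, backbone), deep_features(patch, backbone))

    def test_different_patches_differ(self, backbone):
        p1 = np.random.default_rng(2).uniform(0, 1, (40, 40, 3))
        p2 = np.random.default_rng(3).uniform(0, 1, (40, 40, 3))
        assert np.any(deep_features(p1, backbone) != deep_features(p2, backbone))

    def test_invalid_patch_rejected(self, backbone):
        with pytest.raises(ValueError):
            deep_features(np.zeros((40, 40)), backbone)
        with pytest.raises(ValueError):
            deep_features(np.zeros((4, 4, 3)), backbone)


class TestOutlierFilter:
    def test_single_far_point_removed(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 1, (99, 3)))
        X.loc[99] = [100.0, 100.0, 100.0]
        for method in ("isolation_forest", "elliptic_envelope"):
            keep = outlier_filter(X, method, contamination=0.01, seed=0)
            assert not keep[99]
            assert keep[:99].all()

    def test_zero_contamination_keeps_all(self):
        X = pd.DataFrame(np.random.default_rng(1).normal(0, 1, (20, 3)))
        assert outlier_filter(X, contamination=0).all()

    def test_constant_feature_rejected_for_elliptic(self):
        X = pd.DataFrame(np.random.default_rng(2).normal(0, 1, (20, 3)))
        X[1] = 5.0
        with pytest.raises(ValueError, match="degenerate"):
            outlier_filter(X, "elliptic_envelope", contamination=0.1)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            outlier_filter(pd.DataFrame(np.zeros((5, 2))), contamination=0.1)


class TestDiscretize:
    def test_kmeans_three_level_example(self):
        t = pd.DataFrame({"a": [0.0, 0.0, 5.0, 5.0, 10.0, 10.0]})
        assert discretize(t, 3)["a"].tolist() == [0, 0, 1, 1, 2, 2]

    def test_monotone_in_feature_value(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame({"x": rng.uniform(0, 10, 60)})
        binned = discretize(t, 4)
        order = np.argsort(t["x"].to_numpy())
        ids = binned["x"].to_numpy()[order]
        assert all(a <= b for a, b in zip(ids, ids[1:]))

    def test_bijective_when_bins_equal_distinct_values(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        assert sorted(set(discretize(t, 3)["a"])) == [0, 1, 2]

    def test_too_few_distinct_values_names_column(self):
        t = pd.DataFrame({"bad": [1.0, 1.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="bad"):
            discretize(t, 3)


class TestHarness:
    def test_eight_families_registered(self):
        assert len(EIGHT_FAMILIES) == 8

    def test_all_families_reach_high_precision(self, separable):
        table, y = separable
        res = compare_classifiers(table, y, seed=0)
        assert set(res.metrics["Model"]) == set(EIGHT_FAMILIES)
        assert (res.metrics["Model Precision"] >= 0.95).all()
        assert len(res.top3) == 3

    def test_deterministic_given_seed(self, separable):
        table, y = separable
        a = compare_classifiers(table, y, seed=1)
        b = compare_classifiers(table, y, seed=1)
        cols = ["Model", "Model Precision", "F1 Score"]
        assert a.metrics[cols].equals(b.metrics[cols])
        assert a.ranking == b.ranking

    def test_preprocessing_modes(self, separable):
        table, y = separable
        for mode in ("outlier:isolation_forest", "discretize"):
            res = compare_classifiers(table, y, preprocessing=mode, seed=0)
            assert len(res.metrics) == 8

    def test_unknown_preprocessing_rejected(self, separable):
        table, y = separable
        with pytest.raises(ValueError):
            compare_classifiers(table, y, preprocessing="pca")

    def test_outlier_then_discretize_composes(self, separable):
        """Filtering never adds rows; discretization preserves column order."""
        table, _ = separable
        keep = outlier_filter(table, contamination=0.05, seed=0)
        filtered = table[keep]
        assert len(filtered) <= len(table)
        binned = discretize(filtered, n_bins=4, seed=0)
        assert list(binned.columns) == list(table.columns)
        assert len(binned) == len(filtered)


class TestReportGeneration:
    def test_separable_labels_low_misclassification(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.2, (50, 3)), rng.normal(4, 0.2, (50, 3))])
        y = ["normal"] * 50 + ["abnormal"] * 50
        report = generate_report([], pd.DataFrame(X), y, seed=0)
        assert report["rf_misclassification_rate"] <= 0.05
        assert set(report["models"]) == {
            "RandomForestClassifier",
            "DecisionTreeClassifier",
            "GradientBoostingClassifier",
        }

    def test_all_fifteen_anomaly_labels_zero_filled(self):
        from hemamorph.anomaly_rules import RBC_SHAPE_LABELS

        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(3, 1, (30, 2))])
        report = generate_report([], pd.DataFrame(X), ["a"] * 30 + ["b"] * 30, seed=0)
        assert set(report["anomaly_counts"]) == set(RBC_SHAPE_LABELS)
        assert all(v == 0 for v in report["anomaly_counts"].values())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            generate_report([], pd.DataFrame(), [], seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(2, 1, (30, 2))]))
        y = ["a"] * 30 + ["b"] * 30
        assert generate_report([], X, y, seed=3) == generate_report([], X, y, seed=3)
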
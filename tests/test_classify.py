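"""Subset enumeration, linear SVM training and one-subject-out evaluation."""

import numpy as np
import pandas as pd
import pytest

import hrvtbi as h
from hrvtbi.classify import (
    DEFAULT_SIGNIFICANT,
    ParameterSubset,
    accuracy_grid,
    build_feature_matrix,
    enumerate_models,
    evaluate_subset,
    predict,
    train_linear_svm,
)
from hrvtbi.features import PARAMETER_NAMES
from hrvtbi.series import ParameterError

#: The 22 parameter combinations of the reference design, by label.
EXPECTED_SUBSETS = {
    "1,2", "1-3", "1-4", "1-5", "1-6", "1-7", "1-8",
    "2,3", "2-4", "2-5", "2-6", "2-7", "2-8",
    "3,4", "3-5", "3-6", "3-7", "3-8",
    "2,4", "2,4,5", "2,4,5,6", "2,4,5,6,7",
}


def _synthetic_table(rng, sep=0.0, phases=("Hp", "Tp")):
    """Feature table whose post-phase arms are shifted by ``sep`` in every
    significant parameter; other parameters are pure noise."""
    rows = []
    for phase in ["Hb", "Hh", "Hp", "Tb", "Th", "Tp"]:
        arm = "tbi_hemorrhage" if phase.startswith("T") else "control_hemorrhage"
        for s in range(6):
            row = {"subject_id": f"{phase[0]}{s:02d}", "arm": arm, "phase": phase}
            for i, p in enumerate(PARAMETER_NAMES, start=1):
                shift = -sep if (phase == "Tp" and i in DEFAULT_SIGNIFICANT) else 0.0
                row[p] = rng.normal(10.0 + shift, 1.0)
            rows.append(row)
    return pd.DataFrame(rows)


class TestEnumeration:
    def test_default_enumeration_is_the_22_reference_subsets(self):
        subsets = enumerate_models()
        assert len(subsets) == 22
        assert {s.label for s in subsets} == EXPECTED_SUBSETS

    def test_contiguous_family_alone_has_18_members(self):
        ranges = [s for s in enumerate_models() if s.family.startswith("range")]
        assert len(ranges) == 18  # 7 + 6 + 5 ranges starting at 1, 2, 3

    def test_significant_prefix_fraction_is_100(self):
        subsets = {s.label: s for s in enumerate_models()}
        assert subsets["2,4,5,6,7"].significant_fraction == 100.0
        assert subsets["2,4"].significant_fraction == 100.0

    def test_fraction_of_mixed_subset(self):
        subsets = {s.label: s for s in enumerate_models()}
        assert subsets["1,2"].significant_fraction == pytest.approx(50.0)
        assert subsets["1-8"].significant_fraction == pytest.approx(62.5)

    def test_subset_validation(self):
        with pytest.raises(ParameterError):
            ParameterSubset((3,), 0.0)
        with pytest.raises(ParameterError):
            ParameterSubset((4, 2), 0.0)
        with pytest.raises(ParameterError):
            ParameterSubset((0, 2), 0.0)


class TestFeatureMatrix:
    def test_shape_and_labels(self, rng):
        table = _synthetic_table(rng)
        subset = ParameterSubset((2, 4, 5, 6, 7), 100.0)
        X, y, ids = build_feature_matrix(table, subset)
        assert X.shape == (12, 5)
        assert y.sum() == 6 and y.size == 12
        assert len(ids) == 12

    def test_unknown_policy_rejected(self, rng):
        with pytest.raises(ParameterError):
            build_feature_matrix(
                _synthetic_table(rng), ParameterSubset((1, 2), 0.0), "weekly"
            )


class TestTrainLinearSVM:
    def test_separable_1d(self):
        X = np.array([[-1.0], [-1.1], [1.0], [1.1]])
        y = np.array([0, 0, 1, 1])
        model = train_linear_svm(X, y)
        assert predict(model, [-1.0])[0] == "control"
        assert predict(model, [1.0])[0] == "TBI"
        boundary = -model.bias / model.weights[0] * model.scale[0] + model.center[0]
        assert -1.0 < boundary < 1.0

    def test_duplication_invariance_on_separable_data(self, rng):
        # separable data with a large C trains at zero slack, where the
        # max-margin solution is invariant to duplicating every row
        X = np.vstack([rng.normal(-3.0, 0.5, size=(5, 3)),
                       rng.normal(3.0, 0.5, size=(5, 3))])
        y = np.array([0] * 5 + [1] * 5)
        m1 = train_linear_svm(X, y, C=100.0)
        m2 = train_linear_svm(np.vstack([X, X]), np.concatenate([y, y]), C=100.0)
        np.testing.assert_allclose(
            m1.decision(X), m2.decision(X), rtol=1e-5, atol=1e-6
        )

    def test_xor_not_linearly_separable(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([0, 0, 1, 1])
        model = train_linear_svm(X, y, C=1e6)
        preds = (model.decision(X) > 0).astype(int)
        assert np.mean(preds == y) <= 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            train_linear_svm(np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_standardized_mode_centers_training_columns(self, rng):
        X = rng.normal(loc=50.0, scale=7.0, size=(12, 4))
        y = np.array([0] * 6 + [1] * 6)
        model = train_linear_svm(X, y, standardize=True)
        Xs = (X - model.center) / model.scale
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xs.std(axis=0), 1.0, rtol=1e-12)


class TestPredict:
    def test_boundary_tie_goes_to_control(self):
        model = h.LinearModel(
            subset=ParameterSubset((1, 2), 0.0),
            weights=np.array([1.0, 0.0]),
            bias=0.0,
            center=np.zeros(2),
            scale=np.ones(2),
        )
        label, margin = predict(model, [0.0, 5.0])
        assert margin == 0.0
        assert label == "control"

    def test_training_rows_reproduce_decision_values(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 6 + [1] * 6)
        model = train_linear_svm(X, y)
        d1 = model.decision(X)
        d2 = np.array([predict(model, row)[1] for row in X])
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_mean_model_separates_class_centroids(self, rng):
        table = _synthetic_table(rng, sep=8.0)
        subset = ParameterSubset((2, 4, 5, 6, 7), 100.0)
        res = evaluate_subset(subset, table, n_repeats=20, seed=0)
        X, y, _ = build_feature_matrix(table, subset)
        c0, c1 = X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)
        assert predict(res.mean_model, c0)[0] == "control"
        assert predict(res.mean_model, c1)[0] == "TBI"


class TestEvaluateSubset:
    def test_separated_arms_reach_100(self, rng):
        table = _synthetic_table(rng, sep=30.0)
        res = evaluate_subset(
            ParameterSubset((2, 4, 5, 6, 7), 100.0), table, n_repeats=50, seed=1
        )
        assert res.mean_accuracy == 100.0

    def test_accuracy_bounded_and_deterministic(self, fast_features):
        subset = ParameterSubset((2, 4), 100.0)
        r1 = evaluate_subset(subset, fast_features, n_repeats=30, seed=9)
        r2 = evaluate_subset(subset, fast_features, n_repeats=30, seed=9)
        assert 0.0 <= r1.mean_accuracy <= 100.0
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)
        np.testing.assert_allclose(
            r1.mean_model.weights, r2.mean_model.weights
        )

    def test_permuted_labels_near_chance(self, rng):
        table = _synthetic_table(rng, sep=8.0)
        accs = [
            evaluate_subset(
                ParameterSubset((2, 4, 5, 6, 7), 100.0),
                table, n_repeats=100, seed=s, permute_labels=True,
            ).mean_accuracy
            for s in range(3)
        ]
        assert abs(np.mean(accs) - 50.0) < 7.5

    def test_mean_model_of_identical_folds_equals_each_fold(self):
        # all controls identical, all TBI identical -> every fold sees the
        # same geometry, so the mean model equals any single fold's model
        rows = []
        for phase, arm in (("Hp", "control_hemorrhage"), ("Tp", "tbi_hemorrhage")):
            for s in range(6):
                row = {"subject_id": f"{phase[0]}{s}", "arm": arm, "phase": phase}
                for i, p in enumerate(PARAMETER_NAMES, start=1):
                    row[p] = 1.0 if arm == "control_hemorrhage" else 3.0 + i
                rows.append(row)
        for phase in ("Hb", "Hh", "Tb", "Th"):
            arm = "tbi_hemorrhage" if phase.startswith("T") else "control_hemorrhage"
            for s in range(6):
                row = {"subject_id": f"{phase[0]}{s}", "arm": arm, "phase": phase}
                row.update({p: 1.0 for p in PARAMETER_NAMES})
                rows.append(row)
        table = pd.DataFrame(rows)
        subset = ParameterSubset((2, 4), 100.0)
        res = evaluate_subset(subset, table, n_repeats=10, seed=0)
        X, y, _ = build_feature_matrix(table, subset)
        single = train_linear_svm(X[2:], y[2:], subset=subset)
        np.testing.assert_allclose(res.mean_model.weights, single.weights, rtol=1e-6)
        np.testing.assert_allclose(res.mean_model.bias, single.bias, rtol=1e-6)

    def test_column_rescaling_invariance_when_standardized(self, rng):
        table = _synthetic_table(rng, sep=4.0)
        scaled = table.copy()
        scaled["SDNN"] = scaled["SDNN"] * 1000.0
        subset = ParameterSubset((2, 4, 5), 100.0)
        r1 = evaluate_subset(subset, table, n_repeats=40, seed=3, standardize=True)
        r2 = evaluate_subset(subset, scaled, n_repeats=40, seed=3, standardize=True)
        np.testing.assert_allclose(r1.accuracies, r2.accuracies)


class TestAccuracyGrid:
    def test_grid_rows_and_band_partition(self, fast_features):
        subsets = enumerate_models()
        grid, bands = accuracy_grid(subsets, fast_features, n_repeats=10, seed=2)
        assert len(grid) == 22
        assert bands["n_subsets"].sum() == 22
        assert set(bands["family"]) == {
            "range1", "range2", "range3", "significant_prefix"
        }
        # bands ordered by mean significant fraction, 100% band last
        assert bands.iloc[-1]["family"] == "significant_prefix"
        assert bands.iloc[-1]["percent_significant"] == pytest.approx(100.0)

    def test_empty_subset_list_rejected(self, fast_features):
        with pytest.raises(ParameterError):
            accuracy_grid([], fast_features)
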
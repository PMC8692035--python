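"""Screening models: feature assembly, CV regression/classification, bands."""

import numpy as np
import pytest
from sklearn.model_selection import KFold

from morphofit import (CohortParams, assemble_features,
                       cross_validated_classifier, cross_validated_regression,
                       generate_cohort, percentile_bands)
from morphofit.io import PatientRecord
from morphofit.synthetic import (default_quadratic_coefficients,
                                 generate_screening_truth)


def _degrade(record, field="body_depth"):
    kwargs = {"patient_id": record.patient_id, "sex": record.sex,
              "age": record.age, "height": record.height,
              "weight": record.weight, "bmi": record.bmi,
              "asis_distance": record.asis_distance,
              "xiphoid_pubis_distance": record.xiphoid_pubis_distance,
              "body_depth": record.body_depth,
              "body_width": record.body_width,
              "body_circumference": record.body_circumference}
    kwargs[field] = None
    return PatientRecord(**kwargs)


class TestAssembleFeatures:
    def test_missing_field_excluded_with_reason(self):
        records, _ = generate_cohort(CohortParams(n=20, seed=0))
        records[3] = _degrade(records[3], "body_depth")
        X, excluded = assemble_features(records)
        assert len(X) == 19
        pid, missing = excluded[0]
        assert pid == records[3].patient_id
        assert "body_depth" in missing

    def test_complete_cohort_no_exclusions(self):
        records, _ = generate_cohort(CohortParams(n=30, seed=1))
        X, excluded = assemble_features(records)
        assert len(X) == 30 and not excluded

    def test_582_degraded_of_642_leaves_560(self):
        records, _ = generate_cohort(CohortParams(n=642, seed=2))
        rng = np.random.default_rng(0)
        for i in rng.choice(642, size=82, replace=False):
            records[i] = _degrade(records[i], "body_circumference")
        X, excluded = assemble_features(records)
        assert len(X) == 560
        assert len(excluded) == 82

    def test_sex_encoding(self):
        records, _ = generate_cohort(CohortParams(n=12, seed=3))
        X, _ = assemble_features(records)
        enc = dict(zip((r.patient_id for r in records),
                       (r.sex for r in records)))
        for pid, val in X["sex"].items():
            assert val == (0.0 if enc[pid] == "female" else 1.0)

    def test_too_few_complete_cases_rejected(self):
        records, _ = generate_cohort(CohortParams(n=12, seed=4))
        records = [_degrade(r) for r in records[:8]] + list(records[8:])
        with pytest.raises(ValueError, match="10"):
            assemble_features(records)


@pytest.fixture(scope="module")
def quadratic_data():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(500, 8))
    coef = default_quadratic_coefficients(8, seed=0)
    y_clean = generate_screening_truth(X, coef, 0.0)
    return X, y_clean, coef


class TestRegression:
    def test_realizable_quadratic_high_r2(self, quadratic_data):
        X, y, _ = quadratic_data
        rep = cross_validated_regression(X, y, seed=0)
        assert rep.r_squared >= 0.99

    def test_permuted_response_near_zero_r2(self, quadratic_data):
        X, y, _ = quadratic_data
        yp = np.random.default_rng(17).permutation(y)
        rep = cross_validated_regression(X, yp, seed=17)
        assert rep.r_squared <= 0.1

    def test_metric_consistency(self, quadratic_data):
        X, y, coef = quadratic_data
        noisy = y + np.random.default_rng(3).normal(
            scale=0.2 * y.std(), size=len(y))
        rep = cross_validated_regression(X, noisy, seed=0)
        assert rep.rmse >= rep.mae >= 0
        assert rep.r_squared <= 1

    def test_degenerate_response_rejected(self, quadratic_data):
        X, _, _ = quadratic_data
        with pytest.raises(ValueError, match="variance"):
            cross_validated_regression(X, np.ones(len(X)), seed=0)

    def test_no_leakage_between_folds(self, quadratic_data):
        """Perturbing one sample must not change out-of-fold predictions of
        other samples sharing its test fold (the fold's model and its
        standardization never see either sample)."""
        X, y, _ = quadratic_data
        X = X.copy()
        folds = list(KFold(10, shuffle=True, random_state=0).split(X))
        test_fold = folds[0][1]
        i, j = test_fold[0], test_fold[1]
        base = cross_validated_regression(X, y, seed=0)
        X2 = X.copy()
        X2[i] = X2[i] * 100 + 50  # wild out-of-fold outlier
        pert = cross_validated_regression(X2, y, seed=0)
        assert pert.predictions[j] == pytest.approx(base.predictions[j],
                                                    rel=1e-12)


class TestPercentileBands:
    def test_uniform_1_to_100_balanced(self):
        labels, edges = percentile_bands(np.arange(1.0, 101.0))
        counts = np.bincount(labels, minlength=4)
        assert (counts == 25).all()
        assert edges[1] == pytest.approx(50.5)

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            percentile_bands(np.full(40, 7.0))

    def test_edge_value_goes_to_upper_band(self):
        y = np.arange(1.0, 101.0)
        labels, edges = percentile_bands(y)
        k = np.argmin(np.abs(y - edges[2]))
        if y[k] >= edges[2]:
            assert labels[k] == 3

    def test_continuous_responses_balanced_within_one(self, rng):
        y = rng.normal(size=203)
        labels, _ = percentile_bands(y)
        counts = np.bincount(labels, minlength=4)
        assert np.ptp(counts) <= 1 + 1  # interpolation edges: near-quartile


class TestClassifier:
    def test_separable_clusters_high_accuracy(self, rng):
        p = 8
        centers = np.zeros((4, p))
        centers[1, 0] = centers[2, 1] = centers[3, 2] = 6.0
        labels = np.repeat(np.arange(4), 100)
        X = centers[labels] + rng.normal(size=(400, p))
        rep = cross_validated_classifier(X, labels, seed=23)
        assert rep.accuracy >= 0.9
        assert rep.confusion.sum() == 400
        np.testing.assert_array_equal(rep.confusion.sum(axis=1),
                                      np.full(4, 100))

    def test_shuffled_labels_chance_accuracy(self, rng):
        X = rng.normal(size=(400, 8))
        labels = np.random.default_rng(5).permutation(
            np.repeat(np.arange(4), 100))
        rep = cross_validated_classifier(X, labels, seed=23)
        se = np.sqrt(0.25 * 0.75 / 400)
        assert abs(rep.accuracy - 0.25) <= 3 * se

    def test_perfect_single_feature_separation_auc_one(self, rng):
        x0 = np.concatenate([np.arange(50) + 200 * k for k in range(4)])
        X = np.column_stack([x0, rng.normal(size=200)])
        labels = np.repeat(np.arange(4), 50)
        rep = cross_validated_classifier(X, labels, seed=1)
        for cls in rep.roc_curves.values():
            assert cls["auc"] == pytest.approx(1.0, abs=1e-9)

    def test_kernel_scale_presets(self, rng):
        X = rng.normal(size=(100, 8))
        labels = np.repeat(np.arange(4), 25)
        for scale in ("medium", "coarse"):
            rep = cross_validated_classifier(X, labels, kernel_scale=scale,
                                             folds=5, seed=0)
            assert 0 <= rep.accuracy <= 1
        with pytest.raises(ValueError):
            cross_validated_classifier(X, labels, kernel_scale="fine")

    def test_stratification_impossible_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        labels = np.array([0] * 17 + [1] * 3)
        with pytest.raises(ValueError, match="stratified"):
            cross_validated_classifier(X, labels, folds=10, seed=0)

    def test_extreme_bands_have_best_auc(self, quadratic_data):
        """Ordered quartile bands: the outer bands separate best, echoing
        the qualitative ROC finding on device-size classes."""
        X, y, _ = quadratic_data
        labels, _ = percentile_bands(y)
        rep = cross_validated_classifier(X, labels, seed=3)
        auc = {int(k): v["auc"] for k, v in rep.roc_curves.items()}
        assert min(auc[0], auc[3]) >= max(auc[1], auc[2])

    def test_determinism(self, rng):
        X = rng.normal(size=(120, 8))
        labels = np.repeat(np.arange(4), 30)
        a = cross_validated_classifier(X, labels, seed=9)
        b = cross_validated_classifier(X, labels, seed=9)
        np.testing.assert_array_equal(a.confusion, b.confusion)
        assert a.accuracy == b.accuracy
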
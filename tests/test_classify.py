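"""Scaling, linear SVM, RFE, AdaBoost, and the LOOCV pipeline."""

import math

import numpy as np
import pytest

from connclass.classify import (
    CVReport,
    FoldResult,
    SVMAdaBoost,
    SVMRFE,
    adaboost_train,
    apply_scaler,
    fit_scaler,
    loocv_pipeline,
    performance,
    rfe,
    train_linear_svm,
    vote_weight,
)
from connclass.features import FeatureTable


def make_table(X, y, kind="W-RSN", names=None):
    X = np.asarray(X, float)
    names = names or [f"f{i}" for i in range(X.shape[1])]
    return FeatureTable(
        kind=kind, names=names, values=X, labels=np.asarray(y, int),
        subject_ids=[f"s{i}" for i in range(X.shape[0])],
    )


class TestScaler:
    def test_two_point_column(self):
        params = fit_scaler(np.array([[0.0], [2.0]]))
        assert params.center[0] == pytest.approx(1.0)
        assert params.scale[0] == pytest.approx(1.0)  # population SD
        assert np.allclose(apply_scaler(params, [[0.0], [2.0]]).ravel(), [-1, 1])

    def test_test_value_at_training_mean_maps_to_zero(self):
        params = fit_scaler(np.array([[1.0, 5.0], [3.0, 9.0]]))
        assert np.allclose(apply_scaler(params, [[2.0, 7.0]]), 0.0)

    def test_training_columns_standardized(self):
        X = np.random.default_rng(0).normal(3, 5, size=(40, 6))
        scaled = apply_scaler(fit_scaler(X), X)
        assert np.abs(scaled.mean(axis=0)).max() < 1e-10
        assert np.abs(scaled.std(axis=0) - 1).max() < 1e-10

    def test_zero_variance_feature_named(self):
        X = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="W:ECN:9-11"):
            fit_scaler(X, feature_names=["ok", "W:ECN:9-11"])

    def test_minmax_option(self):
        X = np.array([[0.0], [4.0], [2.0]])
        params = fit_scaler(X, method="minmax")
        assert np.allclose(apply_scaler(params, X).ravel(), [0.0, 1.0, 0.5])


class TestLinearSVM:
    def test_symmetric_pair_boundary_at_zero(self):
        model = train_linear_svm(np.array([[-1.0], [1.0]]), [0, 1])
        assert model.bias == pytest.approx(0.0, abs=1e-8)
        assert list(model.predict(np.array([[-1.0], [1.0]]))) == [0, 1]

    def test_separable_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 0.5, (20, 2)), rng.normal(3, 0.5, (20, 2))])
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        model = train_linear_svm(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_xor_not_linearly_separable(self):
        """No linear separator exceeds 3/4 on XOR (exhaustive over the 4
        labelings a halfplane can realize)."""
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([0, 1, 1, 0])
        model = train_linear_svm(X, y)
        assert (model.predict(X) == y).mean() <= 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_linear_svm(np.zeros((4, 2)), [1, 1, 1, 1])

    def test_sample_weights_steer_the_fit(self):
        # one mislabeled point: heavy weight on it flips the boundary side
        X = np.array([[-2.0], [-1.0], [1.0], [0.5]])
        y = np.array([0, 0, 1, 0])
        unweighted = train_linear_svm(X, y)
        weighted = train_linear_svm(X, y, sample_weight=np.array([1, 1, 1, 50.0]))
        assert unweighted.predict(np.array([[0.5]]))[0] != weighted.predict(
            np.array([[0.5]])
        )[0] or (weighted.predict(X) == y).sum() >= (unweighted.predict(X) == y).sum()


class TestRFE:
    @pytest.mark.parametrize(
        "n_features,elim_frac,expected",
        [(119, 0.9, 12), (119, 0.5, 60), (119, 0.0, 119), (10, 0.5, 5), (56, 0.9, 6)],
    )
    def test_retained_count_uses_ceiling(self, n_features, elim_frac, expected):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, n_features))
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]  # both classes present
        assert rfe(X, y, elim_frac).size == expected

    def test_elim_zero_is_identity(self):
        X = np.random.default_rng(3).normal(size=(10, 7))
        assert np.array_equal(rfe(X, [0, 1] * 5, 0.0), np.arange(7))

    def test_informative_feature_survives(self):
        """One informative + three noise features: the informative one is
        retained at 50% elimination in >= 19/20 seeds (weight-ranking oracle)."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.r_[np.zeros(20, int), np.ones(20, int)]
            X = rng.normal(size=(40, 4))
            X[:, 2] = y * 4.0 + rng.normal(scale=0.3, size=40)
            if 2 in rfe(X, y, 0.5):
                hits += 1
        assert hits >= 19

    def test_estimator_interface_transforms(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(24, 20))
        y = rng.integers(0, 2, 24)
        y[:2] = [0, 1]
        sel = SVMRFE(elim_frac=0.5).fit(X, y)
        assert sel.transform(X).shape == (24, 10)
        assert sel.support_.sum() == 10

    def test_invalid_elim_frac_rejected(self):
        with pytest.raises(ValueError, match="elim_frac"):
            rfe(np.zeros((4, 3)), [0, 1, 0, 1], 1.0)


class TestAdaBoost:
    def test_vote_weight_formula(self):
        assert vote_weight(0.5) == pytest.approx(0.0)
        assert vote_weight(0.1) == pytest.approx(0.5 * math.log(9.0))
        assert vote_weight(0.0) == pytest.approx(0.5 * math.log((1 - 1e-10) / 1e-10))

    def test_separable_data_stops_after_one_round(self):
        X = np.array([[-2.0], [-1.5], [1.5], [2.0]])
        y = np.array([0, 0, 1, 1])
        ens = adaboost_train(X, y, n_rounds=10)
        assert len(ens.members) == 1
        assert ens.history == [0.0]

    def test_single_member_predicts_like_base_svm(self):
        X = np.array([[-2.0], [-1.5], [1.5], [2.0]])
        y = np.array([0, 0, 1, 1])
        ens = adaboost_train(X, y, n_rounds=1)
        base = train_linear_svm(X, y)
        grid = np.linspace(-3, 3, 21)[:, None]
        assert np.array_equal(ens.predict(grid), base.predict(grid))

    def test_training_error_respects_boosting_bound(self):
        """Ensemble training error <= prod_m 2 sqrt(eps_m (1 - eps_m)) on a
        non-separable 1-D dataset."""
        rng = np.random.default_rng(5)
        X = np.r_[rng.normal(-0.5, 1.0, 60), rng.normal(0.5, 1.0, 60)][:, None]
        y = np.r_[np.zeros(60, int), np.ones(60, int)]
        ens = adaboost_train(X, y, n_rounds=8)
        err = (ens.predict(X) != y).mean()
        bound = np.prod([2 * np.sqrt(e * (1 - e)) for e in ens.history if e < 0.5])
        assert 0.0 < ens.history[0]
        assert err <= bound + 1e-12

    def test_estimator_interface(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 5))
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        clf = SVMAdaBoost(n_rounds=3).fit(X, y)
        assert set(clf.predict(X)) <= {0, 1}
        assert clf.decision_function(X).shape == (30,)


class TestPerformance:
    @staticmethod
    def folds_from_counts(tp, tn, fp, fn):
        folds = []
        folds += [FoldResult(f"a{i}", 1, 1, frozenset()) for i in range(tp)]
        folds += [FoldResult(f"b{i}", 0, 0, frozenset()) for i in range(tn)]
        folds += [FoldResult(f"c{i}", 1, 0, frozenset()) for i in range(fp)]
        folds += [FoldResult(f"d{i}", 0, 1, frozenset()) for i in range(fn)]
        return folds

    def test_printed_accuracy_formula(self):
        folds = self.folds_from_counts(tp=15, tn=14, fp=7, fn=6)
        accuracy, precision = performance(folds)
        assert accuracy == pytest.approx(29 / 42)
        assert precision == pytest.approx(15 / 22)

    def test_as_printed_precision_variant(self):
        folds = self.folds_from_counts(tp=15, tn=14, fp=7, fn=6)
        _, precision = performance(folds, precision_mode="as-printed")
        assert precision == pytest.approx(15 / 29)

    def test_perfect_prediction(self):
        folds = self.folds_from_counts(tp=5, tn=5, fp=0, fn=0)
        assert performance(folds) == (1.0, 1.0)

    def test_constant_negative_prediction_on_balanced_labels(self):
        folds = self.folds_from_counts(tp=0, tn=10, fp=0, fn=10)
        accuracy, precision = performance(folds)
        assert accuracy == 0.5
        assert precision == 0.0


class TestLOOCV:
    def test_wide_margin_single_feature_is_perfect(self):
        rng = np.random.default_rng(7)
        n = 12
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        X = rng.normal(size=(n, 5))
        X[:, 3] = y * 10.0 + rng.normal(scale=0.1, size=n)
        for elim in (0.0, 0.5, 0.9):
            report = loocv_pipeline(make_table(X, y), elim_frac=elim)
            assert report.accuracy == 1.0

    def test_one_fold_per_subject(self, tiny_tables):
        report = loocv_pipeline(tiny_tables["REP"], elim_frac=0.5)
        assert len(report.folds) == tiny_tables["REP"].n_subjects
        assert {f.held_out for f in report.folds} == set(tiny_tables["REP"].subject_ids)

    def test_no_leakage_from_held_out_subject(self):
        """Corrupting the held-out row never changes that fold's feature
        selection (scaler and RFE are fitted on the training fold only)."""
        rng = np.random.default_rng(8)
        n = 14
        y = rng.integers(0, 2, n)
        y[:4] = [0, 0, 1, 1]
        X = rng.normal(size=(n, 30))
        mutated = X.copy()
        mutated[5] = 1e3 * rng.normal(size=30)
        rep_a = loocv_pipeline(make_table(X, y), elim_frac=0.9)
        rep_b = loocv_pipeline(make_table(mutated, y), elim_frac=0.9)
        assert rep_a.folds[5].selected_features == rep_b.folds[5].selected_features

    def test_deterministic_given_inputs(self, tiny_tables):
        a = loocv_pipeline(tiny_tables["W-RSN"], elim_frac=0.9, seed=0)
        b = loocv_pipeline(tiny_tables["W-RSN"], elim_frac=0.9, seed=0)
        assert a.to_dict() == b.to_dict()

    def test_selected_feature_counts_match_elimination(self, tiny_tables):
        report = loocv_pipeline(tiny_tables["W-RSN"], elim_frac=0.9)
        assert all(len(f.selected_features) == 12 for f in report.folds)
        report0 = loocv_pipeline(tiny_tables["W-RSN"], elim_frac=0.0)
        assert all(len(f.selected_features) == 119 for f in report0.folds)

    def test_report_round_trips_through_dict(self, tiny_tables):
        report = loocv_pipeline(tiny_tables["B-RSN"], elim_frac=0.5)
        again = CVReport.from_dict(report.to_dict())
        assert again.to_dict() == report.to_dict()

    def test_too_few_subjects_per_class_rejected(self):
        X = np.random.default_rng(9).normal(size=(5, 3))
        with pytest.raises(ValueError, match="2 subjects per class"):
            loocv_pipeline(make_table(X, [0, 0, 0, 0, 1]))
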
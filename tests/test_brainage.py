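"""Age model fitting, CV component selection, BAG and its age adjustment."""

import numpy as np
import pandas as pd
import pytest

from motionbag import (
    InputError,
    adjust_bag,
    compute_bag,
    cv_select_components,
    fit_bag_adjustment,
    predict_age,
    train_age_model,
    train_within_session,
)
from motionbag.brainage import Beta2
from motionbag.exceptions import FitError


@pytest.fixture(scope="module")
def scores_rng():
    return np.random.default_rng(777)


class TestTrainAgeModel:
    def test_exact_unregularized_fit(self, scores_rng):
        S = scores_rng.normal(size=(40, 3))
        y = 2.0 * S[:, 0] + 30.0
        m = train_age_model(S, y, k=1, regularization="none")
        assert m.coef[0] == pytest.approx(2.0, abs=1e-8)
        assert m.intercept == pytest.approx(30.0, abs=1e-8)

    def test_ridge_limit_shrinks_to_mean(self, scores_rng):
        S = scores_rng.normal(size=(50, 4))
        y = scores_rng.normal(40, 8, size=50)
        m = train_age_model(S, y, k=4, regularization="l2", lam=1e12)
        assert np.abs(m.coef).max() < 1e-6
        assert m.intercept == pytest.approx(y.mean(), rel=1e-4)

    def test_ridge_matches_closed_form(self, scores_rng):
        """Ridge solution equals (S'S + lam I)^-1 S'y on centered data."""
        S = scores_rng.normal(size=(60, 5))
        y = scores_rng.normal(40, 8, size=60)
        lam = 3.7
        m = train_age_model(S, y, k=5, regularization="l2", lam=lam)
        Sc = S - S.mean(axis=0)
        yc = y - y.mean()
        w = np.linalg.solve(Sc.T @ Sc + lam * np.eye(5), Sc.T @ yc)
        np.testing.assert_allclose(m.coef, w, atol=1e-8)

    def test_singular_design_suggests_regularization(self, scores_rng):
        S = np.repeat(scores_rng.normal(size=(30, 1)), 2, axis=1)  # collinear
        y = scores_rng.normal(size=30)
        with pytest.raises(FitError, match="regulariz"):
            train_age_model(S, y, k=2, regularization="none")

    def test_lasso_zeroes_irrelevant_components(self, scores_rng):
        S = scores_rng.normal(size=(200, 6))
        y = 3.0 * S[:, 0] + 0.01 * scores_rng.normal(size=200)
        m = train_age_model(S, y, k=6, regularization="l1", lam=0.05)
        assert np.abs(m.coef[0]) > 2.5
        assert np.abs(m.coef[1:]).max() < 0.05


class TestPredict:
    def test_zero_scores_give_intercept(self, scores_rng):
        S = scores_rng.normal(size=(20, 2))
        m = train_age_model(S, scores_rng.normal(40, 5, 20), k=2)
        pred = predict_age(m, np.zeros((7, 2)))
        np.testing.assert_allclose(pred, m.intercept)

    def test_linearity(self, scores_rng):
        S = scores_rng.normal(size=(20, 2))
        m = train_age_model(S, scores_rng.normal(40, 5, 20), k=2)
        a = 2.5
        lhs = predict_age(m, a * S) - m.intercept
        rhs = a * (predict_age(m, S) - m.intercept)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_too_few_columns(self, scores_rng):
        S = scores_rng.normal(size=(20, 3))
        m = train_age_model(S, scores_rng.normal(40, 5, 20), k=3)
        with pytest.raises(InputError):
            predict_age(m, S[:, :2])


class TestCVSelection:
    def test_noiseless_single_component(self, scores_rng):
        S = scores_rng.normal(size=(100, 10))
        y = 1.5 * S[:, 0] + 35.0
        curve = cv_select_components(S, y, range(1, 11), folds=10, seed=0)
        assert curve.k_star == 1
        assert curve.rmse[0] < 1e-6

    def test_singleton_range(self, scores_rng):
        S = scores_rng.normal(size=(50, 8))
        y = scores_rng.normal(40, 8, 50)
        curve = cv_select_components(S, y, [5], folds=5, seed=0)
        assert curve.k_star == 5

    def test_oof_predictions_align_with_folds(self, scores_rng):
        S = scores_rng.normal(size=(60, 4))
        y = 2.0 * S[:, 1] + scores_rng.normal(0, 1, 60) + 40
        curve = cv_select_components(S, y, range(1, 5), folds=6, seed=3)
        assert len(curve.oof_pred) == 60
        assert sorted(np.unique(curve.fold_ids)) == list(range(6))

    def test_fewer_rows_than_folds(self, scores_rng):
        S = scores_rng.normal(size=(5, 2))
        with pytest.raises(InputError):
            cv_select_components(S, np.arange(5.0), [1], folds=10)


class TestBAG:
    def test_elementwise_difference(self):
        np.testing.assert_allclose(compute_bag([40.0], [35.0]), [5.0])
        np.testing.assert_allclose(compute_bag([30.0, 20.0], [30.0, 20.0]), 0.0)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            compute_bag([1.0, 2.0], [1.0])

    def test_adjustment_exact_line(self):
        ages = np.linspace(20, 50, 30)
        delta1 = 0.5 * ages - 10.0
        b2 = fit_bag_adjustment(delta1, ages)
        assert b2.slope == pytest.approx(0.5, abs=1e-10)
        assert b2.intercept == pytest.approx(-10.0, abs=1e-10)
        np.testing.assert_allclose(adjust_bag(delta1, ages, b2), 0.0, atol=1e-10)

    def test_constant_delta1(self):
        ages = np.linspace(20, 50, 10)
        b2 = fit_bag_adjustment(np.full(10, 3.0), ages)
        assert b2.slope == pytest.approx(0.0, abs=1e-12)
        assert b2.intercept == pytest.approx(3.0, abs=1e-10)

    def test_identity_adjustment(self):
        d = np.array([1.0, -2.0, 3.0])
        np.testing.assert_array_equal(adjust_bag(d, np.array([30.0, 40, 50]), Beta2(0.0, 0.0)), d)

    def test_residual_oracle(self, scores_rng):
        ages = scores_rng.uniform(18, 50, 200)
        delta1 = -0.3 * ages + scores_rng.normal(0, 2, 200)
        b2 = fit_bag_adjustment(delta1, ages)
        d2 = adjust_bag(delta1, ages, b2)
        # brute-force OLS residuals
        A = np.column_stack([np.ones(200), ages])
        beta = np.linalg.lstsq(A, delta1, rcond=None)[0]
        np.testing.assert_allclose(d2, delta1 - A @ beta, atol=1e-9)
        assert abs(d2.mean()) < 1e-8
        assert abs(np.corrcoef(d2, ages)[0, 1]) < 1e-8

    def test_constant_ages_error(self):
        with pytest.raises(InputError):
            fit_bag_adjustment(np.arange(5.0), np.full(5, 30.0))


@pytest.fixture(scope="module")
def session_data():
    rng = np.random.default_rng(5)
    n = 45
    ages = rng.uniform(18, 50, n)
    scores = np.zeros((3 * n, 3))
    rows, meta = [], []
    for i in range(n):
        for s in ("STAND", "HM1", "HM2"):
            rows.append(f"sub{i:03d}_{s}")
            meta.append({"scan_id": f"sub{i:03d}_{s}", "subject_id": f"sub{i:03d}",
                         "age": ages[i], "session": s})
    scores[:, 0] = np.repeat(ages, 3) * 0.8  # noiseless age signal
    scores[:, 1:] = rng.normal(size=(3 * n, 2))
    sdf = pd.DataFrame(scores, index=pd.Index(rows, name="scan_id"),
                       columns=["PC1", "PC2", "PC3"])
    return sdf, pd.DataFrame(meta)


class TestWithinSession:
    def test_noiseless_cv_predictions(self, session_data):
        sdf, meta = session_data
        res = train_within_session(sdf, meta, "STAND", k=1, folds=5, seed=1)
        ages = meta.set_index("scan_id").loc[sdf.index, "age"].to_numpy()
        rmse = np.sqrt(np.mean((res.predictions.to_numpy() - ages) ** 2))
        assert rmse < 1e-6

    def test_no_scan_predicted_by_its_own_fold_model(self, session_data):
        sdf, meta = session_data
        res = train_within_session(sdf, meta, "STAND", k=2, folds=5, seed=2)
        stand_ids = meta.loc[meta["session"] == "STAND", "scan_id"]
        for sid in stand_ids:
            f = res.fold_ids[sid]
            assert sid not in res.fold_train_ids[f]
        # and every STAND scan is assigned to exactly one fold
        assert set(res.fold_ids) == set(stand_ids)

    def test_training_session_symmetry(self, session_data):
        """Swapping the training session only changes which scans get CV
        predictions; the protocol itself is symmetric."""
        sdf, meta = session_data
        r1 = train_within_session(sdf, meta, "STAND", k=1, folds=5, seed=3)
        r2 = train_within_session(sdf, meta, "HM2", k=1, folds=5, seed=3)
        assert set(r1.fold_ids) == set(meta.loc[meta.session == "STAND", "scan_id"])
        assert set(r2.fold_ids) == set(meta.loc[meta.session == "HM2", "scan_id"])

    def test_duplicate_subject_in_session_errors(self, session_data):
        sdf, meta = session_data
        meta2 = meta.copy()
        meta2.loc[meta2.index[1], "session"] = "STAND"  # second STAND for subject 0
        with pytest.raises(InputError, match="duplicate subject"):
            train_within_session(sdf, meta2, "STAND", k=1, folds=5, seed=1)
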
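import math

import numpy as np
import pytest
from scipy import stats

from bagpipe import (
    FeatureTable,
    Hyperparameters,
    cross_validate,
    fit_age_model,
    nested_grid_search,
    pearson_ci,
    predict_age,
    regression_metrics,
)
from bagpipe.brainage import load_model, out_of_fold_predictions, save_model

FAST = Hyperparameters(max_depth=2, n_estimators=40, learning_rate=0.3)


def _strong_signal(n=120, p=6, seed=0):
    """Noiseless monotone features of age: trees should interpolate."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(18, 87, n)
    slopes = rng.uniform(0.5, 2.0, p) * rng.choice([-1, 1], p)
    values = age[:, None] * slopes[None, :]
    ft = FeatureTable("T1", [f"s{i}" for i in range(n)], [f"f{j}" for j in range(p)], values)
    return ft, age


class TestFitPredict:
    def test_deterministic_given_seed(self):
        ft, age = _strong_signal()
        held, _ = _strong_signal(n=30, seed=1)
        m1 = fit_age_model(ft, age, FAST, seed=4)
        m2 = fit_age_model(ft, age, FAST, seed=4)
        np.testing.assert_array_equal(predict_age(m1, held), predict_age(m2, held))

    def test_interpolates_noiseless_signal(self):
        ft, age = _strong_signal(n=500)
        model = fit_age_model(ft, age, Hyperparameters(), seed=0)
        r2, _, _ = regression_metrics(predict_age(model, ft), age)
        assert r2 >= 0.99

    def test_missing_training_feature_named(self):
        ft, age = _strong_signal()
        model = fit_age_model(ft, age, FAST)
        crippled = FeatureTable(
            "T1", ft.subject_ids, ft.feature_names[:-1], ft.values[:, :-1]
        )
        with pytest.raises(ValueError, match="f5"):
            predict_age(model, crippled)

    def test_feature_match_is_order_insensitive(self):
        ft, age = _strong_signal()
        model = fit_age_model(ft, age, FAST)
        shuffled = FeatureTable(
            "T1", ft.subject_ids, ft.feature_names[::-1], ft.values[:, ::-1]
        )
        np.testing.assert_allclose(
            predict_age(model, shuffled), predict_age(model, ft)
        )

    def test_permuting_rows_permutes_predictions(self):
        ft, age = _strong_signal()
        model = fit_age_model(ft, age, FAST)
        perm = np.random.default_rng(2).permutation(ft.n_subjects)
        permuted = FeatureTable(
            "T1", [ft.subject_ids[i] for i in perm], ft.feature_names, ft.values[perm]
        )
        np.testing.assert_allclose(
            predict_age(model, permuted), predict_age(model, ft)[perm]
        )

    def test_noiseless_patient_transfer_mae_under_two_years(self):
        """Trained on a noiseless synthetic cohort, the model predicts
        noiseless patients to within 2 years MAE."""
        from bagpipe import SyntheticConfig, generate_cohort

        config = SyntheticConfig(
            n_train=300, n_patient=100, n_features_t1=20, n_features_dti=20,
            sigma_range=(0.0, 0.0), seed=23,
        )
        tr_cohort, tr_t1, _, _ = generate_cohort(config, "training")
        pat_cohort, pat_t1, _, _ = generate_cohort(config, "patient")
        model = fit_age_model(tr_t1, tr_cohort.data["age"].to_numpy(), seed=0)
        preds = predict_age(model, pat_t1)
        mae = np.mean(np.abs(preds - pat_cohort.data["age"].to_numpy()))
        assert mae <= 2.0

    def test_single_subject_rejected(self):
        ft = FeatureTable("T1", ["a"], ["f"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="2 subjects"):
            fit_age_model(ft, np.array([30.0]))

    def test_save_load_round_trip(self, tmp_path):
        ft, age = _strong_signal()
        model = fit_age_model(ft, age, FAST, seed=9)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert back.feature_names == model.feature_names
        assert back.hyper == model.hyper
        np.testing.assert_allclose(predict_age(back, ft), predict_age(model, ft))


class TestCrossValidate:
    def test_record_bookkeeping(self):
        ft, age = _strong_signal(n=50)
        cv = cross_validate(ft, age, k=5, reps=2, hyper=FAST, seed=0)
        assert len(cv.records) == 10

    def test_same_seed_identical(self):
        ft, age = _strong_signal(n=60)
        a = cross_validate(ft, age, k=3, reps=2, hyper=FAST, seed=5)
        b = cross_validate(ft, age, k=3, reps=2, hyper=FAST, seed=5)
        assert a.records == b.records

    def test_k_exceeding_n_rejected(self):
        ft, age = _strong_signal(n=4)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(ft, age, k=5, reps=1, hyper=FAST)

    def test_rmse_dominates_mae_every_fold(self):
        ft, age = _strong_signal(n=60, seed=3)
        cv = cross_validate(ft, age, k=4, reps=3, hyper=FAST, seed=1)
        for rec in cv.records:
            assert rec["rmse"] >= rec["mae"] >= 0
            assert rec["r2"] <= 1

    def test_out_of_fold_never_beats_in_sample_on_average(self):
        """Across seeded runs, mean held-out R^2 <= mean in-sample R^2."""
        rng = np.random.default_rng(0)
        oof_r2, ins_r2 = [], []
        for seed in range(8):
            n, p = 80, 5
            age = rng.uniform(18, 87, n)
            values = age[:, None] * 0.5 + rng.normal(0, 8, (n, p))
            ft = FeatureTable("T1", [f"s{i}" for i in range(n)], [f"f{j}" for j in range(p)], values)
            cv = cross_validate(ft, age, k=4, reps=1, hyper=FAST, seed=seed)
            oof_r2.append(cv.aggregate()["r2"][0])
            model = fit_age_model(ft, age, FAST, seed=seed)
            ins_r2.append(regression_metrics(predict_age(model, ft), age)[0])
        assert np.mean(oof_r2) <= np.mean(ins_r2)

    def test_out_of_fold_predictions_cover_each_subject_once(self):
        ft, age = _strong_signal(n=40)
        oof = out_of_fold_predictions(ft, age, k=5, hyper=FAST, seed=2)
        assert oof.shape == (40,)
        assert np.all(np.isfinite(oof))


class TestNestedGridSearch:
    def test_single_point_grid_equals_plain_cv(self):
        ft, age = _strong_signal(n=60, seed=4)
        grid = {"max_depth": [2], "n_estimators": [40], "learning_rate": [0.3]}
        best, outer = nested_grid_search(ft, age, grid, outer_k=4, inner_k=3, seed=7)
        plain = cross_validate(ft, age, k=4, reps=1, hyper=FAST, seed=7)
        assert best == FAST
        for a, b in zip(outer.records, plain.records):
            assert a["r2"] == pytest.approx(b["r2"], abs=1e-12)

    def test_best_is_grid_member(self):
        ft, age = _strong_signal(n=60, seed=5)
        grid = {"max_depth": [1, 2], "n_estimators": [20, 40]}
        best, _ = nested_grid_search(ft, age, grid, outer_k=3, inner_k=3, seed=1)
        assert best.max_depth in (1, 2) and best.n_estimators in (20, 40)

    def test_nested_tracks_plain_cv(self):
        """On a synthetic cohort, nested-CV mean R^2 stays within 0.05
        of plain CV — hyperparameter search does not inflate accuracy."""
        from bagpipe import SyntheticConfig, generate_cohort

        config = SyntheticConfig(n_train=150, n_features_t1=20, n_features_dti=20, seed=17)
        cohort, t1, _, _ = generate_cohort(config, "training")
        ages = cohort.data["age"].to_numpy()
        grid = {"max_depth": [2, 3], "n_estimators": [60], "learning_rate": [0.2]}
        _, outer = nested_grid_search(t1, ages, grid, outer_k=5, inner_k=3, seed=2)
        plain = cross_validate(
            t1, ages, k=5, reps=1,
            hyper=Hyperparameters(3, 60, 0.2), seed=2,
        )
        nested_r2 = outer.aggregate()["r2"][0]
        plain_r2 = plain.aggregate()["r2"][0]
        assert abs(nested_r2 - plain_r2) <= 0.05

    def test_non_positive_grid_rejected(self):
        ft, age = _strong_signal(n=30)
        with pytest.raises(ValueError):
            nested_grid_search(ft, age, {"max_depth": [0]}, outer_k=3, inner_k=3)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        omega = np.array([20.0, 30.0, 40.0])
        assert regression_metrics(omega, omega) == (1.0, 0.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self):
        omega = np.array([20.0, 40.0, 60.0])
        y = np.full(3, omega.mean())
        r2, _, _ = regression_metrics(y, omega)
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        omega = np.array([20.0, 40.0, 60.0])
        y = np.array([30.0, 40.0, 50.0])
        r2, rmse, mae = regression_metrics(y, omega)
        assert r2 == pytest.approx(0.75)
        assert rmse == pytest.approx(math.sqrt(200.0 / 3.0))
        assert mae == pytest.approx(20.0 / 3.0)

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regression_metrics(np.array([1.0, 2.0]), np.array([5.0, 5.0]))


class TestPearsonCI:
    def test_fisher_z_example(self):
        """r=0.8 at n=4: z=atanh(0.8)=1.0986, SE=1, CI=tanh(z -/+ 1.96)."""
        omega = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        res = pearson_ci(y, omega)
        assert res.r == pytest.approx(0.8)
        zcrit = stats.norm.ppf(0.975)
        assert res.ci_low == pytest.approx(math.tanh(math.atanh(0.8) - zcrit), abs=1e-9)
        assert res.ci_high == pytest.approx(math.tanh(math.atanh(0.8) + zcrit), abs=1e-9)
        assert res.ci_low == pytest.approx(-0.697, abs=5e-3)
        assert res.ci_high == pytest.approx(0.996, abs=5e-3)

    def test_perfect_linear_relation_collapses_ci(self):
        omega = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_ci(2 * omega + 5, omega)
        assert res.r == pytest.approx(1.0)
        assert (res.ci_low, res.ci_high) == (res.r, res.r)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        omega = rng.uniform(0, 10, 20)
        y = omega + rng.normal(0, 2, 20)
        assert pearson_ci(-y, omega).r == pytest.approx(-pearson_ci(y, omega).r)

    def test_interval_brackets_r(self):
        rng = np.random.default_rng(4)
        omega = rng.uniform(0, 10, 30)
        y = omega + rng.normal(0, 3, 30)
        res = pearson_ci(y, omega)
        assert -1 <= res.ci_low <= res.r <= res.ci_high <= 1
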
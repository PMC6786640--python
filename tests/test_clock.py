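import warnings

import numpy as np
import pytest
from scipy.linalg import hadamard

from proteoclock import (
    CONTROL,
    EXPOSED,
    NORMAL_CLOCK,
    ClockModel,
    ClockPrediction,
    FitSettings,
    SplitSpec,
    SyntheticConfig,
    ValidationError,
    fit_clock,
    generate_dataset,
    predict_ages,
    r_squared,
    solve_elastic_net,
    split_cohort,
)
from proteoclock.clock import elastic_net_loss
from proteoclock.simulate import TABLE1_COUNTS
from .conftest import make_tiny_dataset


def _prediction_list(actual, predicted):
    return [
        ClockPrediction(f"s{i}", float(a), float(p))
        for i, (a, p) in enumerate(zip(actual, predicted))
    ]


class TestSplitCohort:
    def test_study_design_split(self):
        ds, _ = generate_dataset(SyntheticConfig(seed=0))
        train, test = split_cohort(ds, CONTROL, SplitSpec(seed=0))
        n_ctl = sum(n for (g, a), n in TABLE1_COUNTS.items() if g == CONTROL)
        assert train.n_samples + test.n_samples == n_ctl == 60
        # rounding toward training: per-age ceil(2/3 * n)
        expected_train = sum(
            int(np.ceil(2 / 3 * n))
            for (g, a), n in TABLE1_COUNTS.items()
            if g == CONTROL
        )
        assert train.n_samples == expected_train
        assert not set(train.sample_ids) & set(test.sample_ids)

    def test_exact_division(self):
        ds = make_tiny_dataset(
            n=8, groups=[CONTROL] * 8, ages=[30] * 4 + [60] * 4, seed=3
        )
        train, test = split_cohort(ds, CONTROL, SplitSpec(train_fraction=0.5, seed=1))
        assert sum(s.age_days == 30 for s in train.samples) == 2
        assert sum(s.age_days == 30 for s in test.samples) == 2

    def test_deterministic(self):
        ds, _ = generate_dataset(SyntheticConfig(seed=4))
        a = split_cohort(ds, EXPOSED, SplitSpec(seed=9))
        b = split_cohort(ds, EXPOSED, SplitSpec(seed=9))
        assert a[0].sample_ids == b[0].sample_ids
        assert a[1].sample_ids == b[1].sample_ids

    def test_tiny_stratum_goes_to_training(self):
        ds = make_tiny_dataset(
            n=7, groups=[CONTROL] * 7, ages=[30, 30, 30, 60, 60, 60, 90], seed=2
        )
        with pytest.warns(UserWarning, match="wholly to training"):
            train, _ = split_cohort(ds, CONTROL, SplitSpec(seed=0))
        assert any(s.age_days == 90 for s in train.samples)


class TestElasticNetSolver:
    def test_ridge_closed_form(self):
        """gamma1 = 0 reduces to ridge: (X'X + gamma2 I)^-1 X'y on centered data."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.normal(60, 20, size=8)
        for g2 in (0.5, 3.0, 50.0):
            beta, intercept = solve_elastic_net(X, y, 0.0, g2)
            Xc = X - X.mean(0)
            oracle = np.linalg.solve(Xc.T @ Xc + g2 * np.eye(3), Xc.T @ (y - y.mean()))
            np.testing.assert_allclose(beta, oracle, atol=1e-6)

    def test_soft_threshold_on_orthogonal_design(self):
        """gamma2 = 0 on an orthogonal design soft-thresholds the OLS solution."""
        X = hadamard(8).astype(float)[:, 1:4]  # X'X = 8 I, columns mean zero
        rng = np.random.default_rng(1)
        y = rng.normal(90, 30, size=8)
        c = X.T @ (y - y.mean())
        for g1 in (1.0, 10.0, 60.0):
            beta, _ = solve_elastic_net(X, y, g1, 0.0)
            ols = c / 8.0
            oracle = np.sign(ols) * np.maximum(np.abs(ols) - g1 / 16.0, 0.0)
            np.testing.assert_allclose(beta, oracle, atol=1e-6)

    def test_loss_below_reference_points(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 6))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.normal(90, 30, size=20)
        g1, g2 = 4.0, 2.0
        beta, b0 = solve_elastic_net(X, y, g1, g2)
        fitted = elastic_net_loss(X, y, beta, b0, g1, g2)
        at_zero = elastic_net_loss(X, y, np.zeros(6), y.mean(), g1, g2)
        ols = np.linalg.lstsq(
            np.column_stack([X, np.ones(20)]), y, rcond=None
        )[0]
        at_ols = elastic_net_loss(X, y, ols[:-1], ols[-1], g1, g2)
        assert fitted <= at_zero + 1e-8
        assert fitted <= at_ols + 1e-8


class TestFitClock:
    def test_noiseless_recovery(self):
        cfg = SyntheticConfig(
            n_features=12, n_shared_clock_features=10, n_divergent_clock_features=0,
            noise_sd=1e-6, seed=3,
        )
        ds, truth = generate_dataset(cfg)
        model = fit_clock(
            ds.select_group(CONTROL),
            FitSettings(gamma1_grid=(0.1,), gamma2_grid=(1e-8,), cv_folds=3),
        )
        assert model.training_r2 == pytest.approx(1.0, abs=1e-6)
        for b, f in zip(model.beta, model.feature_ids):
            if f in truth.background_feature_ids:
                assert abs(b) < 1e-6

    def test_ridge_path_through_fit_clock(self):
        """A one-point grid at gamma1=0 must reproduce the ridge closed form."""
        ds = make_tiny_dataset(n=8, groups=[CONTROL] * 8,
                               ages=[30, 30, 60, 60, 90, 90, 120, 120], seed=5)
        g2 = 7.0
        model = fit_clock(
            ds, FitSettings(gamma1_grid=(0.0,), gamma2_grid=(g2,), cv_folds=2)
        )
        X = (ds.intensities - model.feature_means) / model.feature_sds
        y = ds.ages
        Xc = X - X.mean(0)
        oracle = np.linalg.solve(
            Xc.T @ Xc + g2 * np.eye(X.shape[1]), Xc.T @ (y - y.mean())
        )
        np.testing.assert_allclose(model.beta, oracle, atol=1e-6)

    def test_sparsity_monotone_in_gamma1(self):
        ds, _ = generate_dataset(SyntheticConfig(n_features=30,
                                                 n_shared_clock_features=6,
                                                 n_divergent_clock_features=6,
                                                 seed=6))
        train = ds.select_group(CONTROL)
        counts = []
        for g1 in (0.5, 5.0, 50.0, 500.0, 5000.0):
            m = fit_clock(train, FitSettings(gamma1_grid=(g1,), gamma2_grid=(1.0,),
                                             cv_folds=3))
            counts.append(m.n_selected)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_constant_feature_dropped_with_warning(self):
        ds = make_tiny_dataset(n=8, groups=[CONTROL] * 8,
                               ages=[30, 30, 60, 60, 90, 90, 120, 120], seed=7)
        X = ds.intensities.copy()
        X[:, 1] = 42.0
        ds2 = type(ds)(X, ds.feature_ids, ds.samples)
        with pytest.warns(UserWarning, match="constant feature"):
            model = fit_clock(ds2, FitSettings(gamma1_grid=(1.0,), gamma2_grid=(1.0,),
                                               cv_folds=2))
        assert "f2" not in model.feature_ids

    def test_single_age_rejected(self):
        ds = make_tiny_dataset(n=6, groups=[CONTROL] * 6, ages=[60] * 6)
        with pytest.raises(ValidationError, match="single age"):
            fit_clock(ds, FitSettings(cv_folds=2))

    def test_model_json_round_trip(self, tmp_path):
        ds = make_tiny_dataset(n=8, groups=[CONTROL] * 8,
                               ages=[30, 30, 60, 60, 90, 90, 120, 120], seed=8)
        model = fit_clock(ds, FitSettings(gamma1_grid=(1.0,), gamma2_grid=(1.0,),
                                          cv_folds=2))
        path = tmp_path / "clock.json"
        model.save(path)
        back = ClockModel.load(path)
        np.testing.assert_array_equal(back.beta, model.beta)
        np.testing.assert_array_equal(back.feature_means, model.feature_means)
        assert back.intercept == model.intercept
        assert back.training_r2 == model.training_r2
        assert back.provenance == model.provenance


class TestPredictAges:
    def test_training_set_consistency(self):
        ds = make_tiny_dataset(n=9, groups=[CONTROL] * 9,
                               ages=[30, 30, 30, 60, 60, 60, 90, 90, 90], seed=9)
        model = fit_clock(ds, FitSettings(gamma1_grid=(1.0,), gamma2_grid=(1.0,),
                                          cv_folds=3))
        assert r_squared(predict_ages(model, ds)) == pytest.approx(model.training_r2)

    def test_zero_beta_predicts_intercept(self):
        ds = make_tiny_dataset(n=4)
        model = ClockModel(
            beta=np.zeros(3), intercept=75.0, gamma1=1.0, gamma2=1.0,
            feature_ids=ds.feature_ids, feature_means=np.zeros(3),
            feature_sds=np.ones(3), training_sample_ids=[], training_r2=0.0,
        )
        preds = predict_ages(model, ds)
        assert all(p.predicted_age == 75.0 for p in preds)

    def test_missing_feature_named(self):
        ds = make_tiny_dataset(n=4)
        model = ClockModel(
            beta=np.zeros(2), intercept=0.0, gamma1=0.0, gamma2=0.0,
            feature_ids=["f1", "zz"], feature_means=np.zeros(2),
            feature_sds=np.ones(2), training_sample_ids=[], training_r2=0.0,
        )
        with pytest.raises(ValidationError, match="zz"):
            predict_ages(model, ds)


class TestRSquared:
    def test_identity_and_affine_invariance(self):
        actual = [30, 60, 90, 120]
        assert r_squared(_prediction_list(actual, actual)) == pytest.approx(1.0)
        assert r_squared(
            _prediction_list(actual, [2 * a + 7 for a in actual])
        ) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # Pearson correlation of (30,60,90) with (30,90,60) is 0.5
        assert r_squared(
            _prediction_list([30, 60, 90], [30, 90, 60])
        ) == pytest.approx(0.25)

    def test_constant_predictions_warn_and_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert r_squared(_prediction_list([30, 60, 90], [50, 50, 50])) == 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            r_squared(_prediction_list([30, 60], [30, 60]))
        with pytest.raises(ValidationError):
            r_squared(_prediction_list([60, 60, 60], [30, 60, 90]))

    def test_coefficient_of_determination_option(self):
        preds = _prediction_list([30, 60, 90], [35, 60, 85])
        cod = r_squared(preds, method="cod")
        ss_res = 25 + 0 + 25
        ss_tot = 1800
        assert cod == pytest.approx(1 - ss_res / ss_tot)


def test_within_group_beats_cross_group(study_runs):
    """Each clock reads its own cohort's age far better than the other's."""
    own = np.mean([r.r2_normal_test for r in study_runs]
                  + [r.r2_tumor_test for r in study_runs])
    cross = np.mean([r.r2_normal_cross for r in study_runs]
                    + [r.r2_tumor_cross for r in study_runs])
    assert own - cross >= 0.2
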
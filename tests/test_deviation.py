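import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proteoclock import (
    CONTROL,
    EXPOSED,
    DeviationPoint,
    FitSettings,
    SplitSpec,
    SyntheticConfig,
    ValidationError,
    clock_distance,
    clock_distances,
    deviation_points,
    evaluate_2d_predictor,
    fit_clock,
    generate_null_dataset,
    rank_auc,
    split_cohort,
)
from proteoclock.clock import ClockModel
from .conftest import SMALL_FIT, SMALL_NULL_KWARGS, make_tiny_dataset


def brute_force_auc(scores, positive):
    """Independent oracle: exhaustive positive-negative pair counting."""
    pos = [s for s, p in zip(scores, positive) if p]
    neg = [s for s, p in zip(scores, positive) if not p]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def _constant_model(feature_ids, intercept, label="normal_clock"):
    p = len(feature_ids)
    return ClockModel(
        beta=np.zeros(p), intercept=intercept, gamma1=0.0, gamma2=0.0,
        feature_ids=list(feature_ids), feature_means=np.zeros(p),
        feature_sds=np.ones(p), training_sample_ids=[], training_r2=0.0,
        label=label,
    )


def _point(score_n, score_t, group=EXPOSED, age=30, sid="s"):
    return DeviationPoint(sample_id=sid, d_normal=score_n, d_tumor=score_t,
                          age_days=age, group=group)


class TestClockDistance:
    def test_on_the_line_is_zero(self):
        # intercept-only model predicting exactly the samples' ages
        ds = make_tiny_dataset(n=4, ages=[60, 60, 60, 60])
        model = _constant_model(ds.feature_ids, 60.0)
        np.testing.assert_allclose(clock_distances(model, ds), 0.0)

    def test_absolute_residual_arithmetic(self):
        ds = make_tiny_dataset(n=4, ages=[60, 60, 60, 60])
        model = _constant_model(ds.feature_ids, 75.0)
        assert clock_distance(model, ds, "s0") == pytest.approx(15.0)

    def test_invariant_to_ignored_features(self, tiny_dataset):
        ds = tiny_dataset
        model = _constant_model(ds.feature_ids[:2], 50.0)
        base = clock_distances(model, ds)
        extra = type(ds)(
            np.column_stack([ds.intensities, np.full(ds.n_samples, 9.0)]),
            ds.feature_ids + ["dead"], ds.samples,
        )
        np.testing.assert_array_equal(clock_distances(model, extra), base)

    def test_signed_and_squared_modes(self):
        ds = make_tiny_dataset(n=4, ages=[60, 60, 60, 60])
        model = _constant_model(ds.feature_ids, 50.0)
        assert clock_distance(model, ds, "s0", mode="signed") == pytest.approx(-10.0)
        assert clock_distance(model, ds, "s0", mode="squared") == pytest.approx(100.0)


class TestDeviationPoints:
    def test_delta_pr_arithmetic(self):
        p = _point(20.0, 5.0)
        assert p.delta_pr == 15.0
        assert _point(7.0, 7.0).delta_pr == 0.0

    def test_antisymmetric_under_clock_swap(self, tiny_dataset):
        ds = tiny_dataset
        normal = _constant_model(ds.feature_ids, 40.0, "normal_clock")
        tumor = _constant_model(ds.feature_ids, 80.0, "tumor_clock")
        fwd = deviation_points(ds, normal, tumor)
        rev = deviation_points(ds, tumor, normal)
        for a, b in zip(fwd, rev):
            assert a.delta_pr == pytest.approx(-b.delta_pr)

    def test_exposed_more_tumor_like_at_every_age(self, study_runs):
        """Mean delta_pr separates the groups at every sampling age."""
        for age in (30, 60, 90, 120, 150):
            gaps = []
            for run in study_runs:
                exp = [p.delta_pr for p in run.points
                       if p.age_days == age and p.group == EXPOSED]
                ctl = [p.delta_pr for p in run.points
                       if p.age_days == age and p.group == CONTROL]
                gaps.append(np.mean(exp) - np.mean(ctl))
            assert np.mean(gaps) > 0, f"no separation at age {age}"


class TestRankAuc:
    def test_perfect_separation(self):
        assert rank_auc([1, 2, 3, 10, 11], [False, False, False, True, True]) == 1.0

    def test_all_ties_half_credit(self):
        assert rank_auc([5, 5, 5, 5], [True, False, True, False]) == 0.5

    def test_hand_counted_pairs(self):
        # positives {0.9, 0.8}, negatives {0.7, 0.85}: 3 concordant of 4 pairs
        scores = [0.9, 0.8, 0.7, 0.85]
        positive = [True, True, False, False]
        assert rank_auc(scores, positive) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            rank_auc([1, 2], [True, True])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        n=st.integers(2, 12),
        data=st.data(),
    )
    def test_rank_formulation_matches_pair_counting(self, n, data):
        """The rank (Mann-Whitney) AUC equals exhaustive pair counting."""
        # discrete scores force ties; labels must include both classes
        scores = data.draw(
            st.lists(st.integers(0, 5), min_size=n, max_size=n).map(
                lambda xs: [x / 2 for x in xs]
            )
        )
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: any(ls) and not all(ls)
            )
        )
        assert rank_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels)
        )


class TestEvaluate2DPredictor:
    def _points(self, scores, groups, ages):
        return [
            DeviationPoint(f"s{i}", d_normal=float(s), d_tumor=0.0,
                           age_days=a, group=g)
            for i, (s, g, a) in enumerate(zip(scores, groups, ages))
        ]

    def test_pools_late_ages(self):
        pts = self._points(
            [1, 2, 3, 4], [EXPOSED, CONTROL, EXPOSED, CONTROL],
            [120, 120, 150, 150],
        )
        rocs = evaluate_2d_predictor(pts)
        assert list(rocs) == [(120, 150)]
        assert rocs[(120, 150)].n_positive == 2

    def test_single_class_stratum_skipped(self):
        pts = self._points([1, 2, 3, 4], [EXPOSED, EXPOSED, EXPOSED, CONTROL],
                           [30, 30, 60, 60])
        with pytest.warns(UserWarning, match="single class"):
            rocs = evaluate_2d_predictor(pts)
        assert (30,) not in rocs and (60,) in rocs

    def test_roc_operating_points_are_monotone(self):
        rng = np.random.default_rng(0)
        pts = self._points(rng.normal(size=30),
                           [EXPOSED, CONTROL] * 15, [30] * 30)
        roc = evaluate_2d_predictor(pts)[(30,)]
        assert np.all(np.diff(roc.tpr) >= 0) and np.all(np.diff(roc.fpr) >= 0)

    def test_logistic_scorer_runs(self, study_runs):
        run = study_runs[0]
        rocs = evaluate_2d_predictor(run.points, scorer="logistic", seed=0)
        assert all(0.0 <= r.auc <= 1.0 for r in rocs.values())


def test_null_cohort_auc_centers_on_half():
    """On exchangeable cohorts the delta_pr classifier carries no signal."""
    aucs = []
    for seed in range(20):
        ds = generate_null_dataset(SyntheticConfig(**SMALL_NULL_KWARGS, seed=seed))
        normal_train, _ = split_cohort(ds, CONTROL, SplitSpec(seed=seed))
        tumor_train, _ = split_cohort(ds, EXPOSED, SplitSpec(seed=seed + 1))
        normal = fit_clock(normal_train, SMALL_FIT, label="normal_clock")
        tumor = fit_clock(tumor_train, SMALL_FIT, label="tumor_clock")
        train_ids = set(normal.training_sample_ids) | set(tumor.training_sample_ids)
        points = [p for p in deviation_points(ds, normal, tumor)
                  if p.sample_id not in train_ids]
        rocs = evaluate_2d_predictor(points)
        aucs.extend(r.auc for r in rocs.values())
    assert abs(np.mean(aucs) - 0.5) < 0.06
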
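import warnings
from types import SimpleNamespace

import numpy as np
import pytest

from proteoclock import (
    CONTROL,
    EXPOSED,
    NORMAL_CLOCK,
    TUMOR_CLOCK,
    FitSettings,
    ProteomicDataset,
    SampleRecord,
    SplitSpec,
    SyntheticConfig,
    deviation_points,
    entropy_profile_from_model,
    evaluate_2d_predictor,
    fit_clock,
    generate_dataset,
    predict_ages,
    r_squared,
    split_cohort,
)

#: reduced generator settings for fast module-level statistical checks
SMALL_NULL_KWARGS = dict(
    n_features=40, n_shared_clock_features=8, n_divergent_clock_features=12
)
SMALL_FIT = FitSettings(gamma1_grid=(5.0, 50.0), gamma2_grid=(1.0, 100.0), cv_folds=3)


def make_tiny_dataset(n=4, p=3, seed=0, groups=None, ages=None):
    rng = np.random.default_rng(seed)
    groups = groups or [CONTROL, CONTROL, EXPOSED, EXPOSED][:n]
    ages = ages or [30, 60, 30, 60][:n]
    samples = [
        SampleRecord(f"s{i}", f"r{i}", groups[i], ages[i]) for i in range(n)
    ]
    X = rng.uniform(10, 100, size=(n, p))
    return ProteomicDataset(X, [f"f{j+1}" for j in range(p)], samples)


@pytest.fixture
def tiny_dataset():
    return make_tiny_dataset()


def _one_study_run(seed: int) -> SimpleNamespace:
    """Full study workflow on one default synthetic cohort."""
    dataset, truth = generate_dataset(SyntheticConfig(seed=seed))
    ctl_train, ctl_test = split_cohort(dataset, CONTROL, SplitSpec(seed=seed))
    exp_train, exp_test = split_cohort(dataset, EXPOSED, SplitSpec(seed=seed + 1000))
    normal = fit_clock(ctl_train, FitSettings(seed=seed), label=NORMAL_CLOCK)
    tumor = fit_clock(exp_train, FitSettings(seed=seed), label=TUMOR_CLOCK)
    exp_all = dataset.select_group(EXPOSED)
    ctl_all = dataset.select_group(CONTROL)
    # the 2D predictor is judged on held-out samples only: training rats sit
    # artificially close to their own clock's line
    all_points = deviation_points(dataset, normal, tumor)
    test_ids = set(ctl_test.sample_ids) | set(exp_test.sample_ids)
    points = [p for p in all_points if p.sample_id in test_ids]
    rocs = evaluate_2d_predictor(points)
    return SimpleNamespace(
        seed=seed,
        dataset=dataset,
        truth=truth,
        normal=normal,
        tumor=tumor,
        r2_normal_test=r_squared(predict_ages(normal, ctl_test)),
        r2_tumor_test=r_squared(predict_ages(tumor, exp_test)),
        r2_normal_cross=r_squared(predict_ages(normal, exp_all)),
        r2_tumor_cross=r_squared(predict_ages(tumor, ctl_all)),
        points=points,
        rocs=rocs,
        entropy_normal=entropy_profile_from_model(normal, dataset),
        entropy_tumor=entropy_profile_from_model(tumor, dataset),
    )


@pytest.fixture(scope="session")
def study_runs():
    """Ten independent default-configuration study replicates.

    Shared across modules: recovery, deviation, entropy and FDR checks all
    read from the same replicates rather than refitting clocks.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [_one_study_run(seed) for seed in range(10)]
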
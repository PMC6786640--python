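"""End-to-end orchestration of the clock analysis.

One call runs the full study workflow on a loaded or simulated cohort:

1. split each group's cohort 2/3 train / 1/3 test,
2. fit the normal clock (controls) and the tumor clock (exposed),
3. assemble the R² matrix — own-train, own-test and cross-applied for each
   clock,
4. score every sample's deviation from both clocks and evaluate the
   per-age 2D predictor (AUC),
5. estimate the global permutation FDR of the clock R² difference,
6. compute entropy-kinetics profiles under both clocks and their contrast,
7. compare clock coefficients and run per-feature group tests.

All randomness fans out from one seed through named stage seeds recorded in
the provenance file, so any stage can be rerun in isolation and a rerun of
the same config writes byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clock import (
    ClockModel,
    FitSettings,
    NORMAL_CLOCK,
    SplitSpec,
    TUMOR_CLOCK,
    fit_clock,
    predict_ages,
    r_squared,
    split_cohort,
)
from .dataset import CONTROL, EXPOSED, LayoutConfig, ProteomicDataset, class_priors, read_dataset
from .deviation import deviation_points, evaluate_2d_predictor
from .entropy import entropy_contrast, entropy_profile_from_model
from .errors import ValidationError
from .fdr import PermutationResult, permutation_fdr
from .features import compare_clocks, per_feature_tests
from .simulate import SyntheticConfig, generate_dataset

logger = logging.getLogger("proteoclock")

_STAGE_NAMES = ("generate", "split_normal", "split_tumor", "cv_normal", "cv_tumor", "fdr")


@dataclass
class RunConfig:
    """Everything needed to reproduce one full analysis run."""

    input_path: str | None = None
    layout: LayoutConfig | None = None
    synthetic: SyntheticConfig | None = None
    seed: int = 0
    train_fraction: float = 2.0 / 3.0
    fit: FitSettings = field(default_factory=FitSettings)
    n_perm: int = 200
    entropy_bins: int = 6
    tested_ages: tuple[int, ...] = (30, 150)
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ValidationError(
                "exactly one of input_path / synthetic must be provided"
            )
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")


@dataclass
class RunReport:
    """All tables produced by one run, plus provenance."""

    r2_matrix: pd.DataFrame
    priors: pd.DataFrame
    auc_by_age: pd.DataFrame
    deviations: pd.DataFrame
    fdr: PermutationResult | None
    entropy_normal: pd.DataFrame
    entropy_tumor: pd.DataFrame
    entropy_contrast: pd.DataFrame
    feature_coefficients: pd.DataFrame
    feature_tests: pd.DataFrame
    normal_clock: ClockModel | None
    tumor_clock: ClockModel | None
    provenance: dict
    partial: list[str] = field(default_factory=list)


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Fan one master seed out into independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGE_NAMES, children)
    }


def _load_input(config: RunConfig, seeds: dict[str, int]) -> ProteomicDataset:
    if config.input_path is not None:
        return read_dataset(config.input_path, config.layout)
    syn = config.synthetic
    # re-seed the generator from the run's master seed fan-out
    syn = SyntheticConfig(**{**syn.__dict__, "seed": seeds["generate"]})
    dataset, _ = generate_dataset(syn)
    return dataset


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute the whole pipeline; write tables if ``config.out_dir`` is set.

    A stage failure marks the report partial and preserves completed
    stages; callers treating the run as a job should exit nonzero when
    ``report.partial`` is not empty.
    """
    config.validate()
    seeds = derive_stage_seeds(config.seed)
    partial: list[str] = []
    t0 = time.time()

    dataset = _load_input(config, seeds)
    logger.info("input: %d samples x %d features (%.1fs)",
                dataset.n_samples, dataset.n_features, time.time() - t0)

    pr = class_priors(dataset)
    priors_df = pd.DataFrame(
        [{"p_normal": pr.p_normal, "p_tumor": pr.p_tumor,
          "n_control": int((dataset.groups == CONTROL).sum()),
          "n_exposed": int((dataset.groups == EXPOSED).sum())}]
    )

    # --- clocks --------------------------------------------------------
    ctl_train, ctl_test = split_cohort(
        dataset, CONTROL, SplitSpec(config.train_fraction, seeds["split_normal"])
    )
    exp_train, exp_test = split_cohort(
        dataset, EXPOSED, SplitSpec(config.train_fraction, seeds["split_tumor"])
    )
    normal = fit_clock(ctl_train, config.fit, label=NORMAL_CLOCK, seed=seeds["cv_normal"])
    tumor = fit_clock(exp_train, config.fit, label=TUMOR_CLOCK, seed=seeds["cv_tumor"])
    logger.info("clocks fitted (%.1fs)", time.time() - t0)

    exp_all = dataset.select_group(EXPOSED)
    ctl_all = dataset.select_group(CONTROL)
    r2 = pd.DataFrame(
        [
            {
                "clock": NORMAL_CLOCK,
                "own_train_r2": normal.training_r2,
                "own_test_r2": r_squared(predict_ages(normal, ctl_test)),
                "cross_group_r2": r_squared(predict_ages(normal, exp_all)),
                "gamma1": normal.gamma1,
                "gamma2": normal.gamma2,
                "n_selected": normal.n_selected,
            },
            {
                "clock": TUMOR_CLOCK,
                "own_train_r2": tumor.training_r2,
                "own_test_r2": r_squared(predict_ages(tumor, exp_test)),
                "cross_group_r2": r_squared(predict_ages(tumor, ctl_all)),
                "gamma1": tumor.gamma1,
                "gamma2": tumor.gamma2,
                "n_selected": tumor.n_selected,
            },
        ]
    )

    # --- deviation + 2D predictor -------------------------------------
    # scored on every sample for the table, but the classifier is judged on
    # held-out samples only: each clock's own training rats sit artificially
    # close to its regression line, which would fake separation
    points = deviation_points(dataset, normal, tumor)
    train_ids = set(normal.training_sample_ids) | set(tumor.training_sample_ids)
    dev_df = pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "group": p.group,
                "age_days": p.age_days,
                "tumor_status": p.tumor_status,
                "d_normal": p.d_normal,
                "d_tumor": p.d_tumor,
                "delta_pr": p.delta_pr,
                "held_out": p.sample_id not in train_ids,
            }
            for p in points
        ]
    )
    test_points = [p for p in points if p.sample_id not in train_ids]
    rocs = evaluate_2d_predictor(test_points)
    auc_df = pd.DataFrame(
        [
            {
                "age_stratum": "/".join(str(a) for a in stratum),
                "auc": r.auc,
                "n_positive": r.n_positive,
                "n_negative": r.n_negative,
            }
            for stratum, r in rocs.items()
        ]
    )

    # --- permutation FDR ----------------------------------------------
    fdr_result: PermutationResult | None = None
    try:
        fdr_result = permutation_fdr(
            dataset,
            n_perm=config.n_perm,
            seed=seeds["fdr"],
            settings=config.fit,
            train_fraction=config.train_fraction,
        )
        logger.info("permutation FDR %.4f over %d permutations (%.1fs)",
                    fdr_result.fdr, config.n_perm, time.time() - t0)
    except ValidationError as exc:
        warnings.warn(f"FDR stage failed: {exc}")
        partial.append("fdr")

    # --- entropy kinetics ----------------------------------------------
    prof_n = entropy_profile_from_model(normal, dataset, config.entropy_bins)
    prof_t = entropy_profile_from_model(tumor, dataset, config.entropy_bins)
    contrast = entropy_contrast(prof_n, prof_t)

    # --- feature report -------------------------------------------------
    coef = compare_clocks(normal, tumor).coefficients
    tests = per_feature_tests(dataset, config.tested_ages).tests

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "train_fraction": config.train_fraction,
        "gamma1_grid": list(config.fit.gamma1_grid),
        "gamma2_grid": list(config.fit.gamma2_grid),
        "cv_folds": config.fit.cv_folds,
        "n_perm": config.n_perm,
        "entropy_bins": config.entropy_bins,
        "tested_ages": list(config.tested_ages),
        "input": config.input_path or "synthetic",
        "n_samples": dataset.n_samples,
        "n_features": dataset.n_features,
    }

    report = RunReport(
        r2_matrix=r2,
        priors=priors_df,
        auc_by_age=auc_df,
        deviations=dev_df,
        fdr=fdr_result,
        entropy_normal=prof_n.to_frame(),
        entropy_tumor=prof_t.to_frame(),
        entropy_contrast=contrast,
        feature_coefficients=coef,
        feature_tests=tests,
        normal_clock=normal,
        tumor_clock=tumor,
        provenance=provenance,
        partial=partial,
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    logger.info("run complete (%.1fs)%s", time.time() - t0,
                " [PARTIAL]" if partial else "")
    return report


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Write every report table as CSV plus a provenance JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "r2_matrix.csv": report.r2_matrix,
        "class_priors.csv": report.priors,
        "auc_by_age.csv": report.auc_by_age,
        "deviations.csv": report.deviations,
        "entropy_normal_clock.csv": report.entropy_normal,
        "entropy_tumor_clock.csv": report.entropy_tumor,
        "entropy_contrast.csv": report.entropy_contrast,
        "feature_coefficients.csv": report.feature_coefficients,
        "feature_tests.csv": report.feature_tests,
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False)
    if report.fdr is not None:
        pd.DataFrame({"null_diff": report.fdr.null_diffs}).to_csv(
            out / "fdr_null_diffs.csv", index=False
        )
        pd.DataFrame(
            [
                {
                    "observed_diff": report.fdr.observed_diff,
                    "fdr": report.fdr.fdr,
                    "n_perm": report.fdr.n_perm,
                }
            ]
        ).to_csv(out / "fdr_summary.csv", index=False)
    if report.normal_clock is not None:
        report.normal_clock.save(out / "normal_clock.json")
    if report.tumor_clock is not None:
        report.tumor_clock.save(out / "tumor_clock.json")
    prov = dict(report.provenance)
    prov["partial_stages"] = report.partial
    (out / "provenance.json").write_text(json.dumps(prov, indent=1))
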
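"""Run the entire analysis in one call and write every report table.

Equivalent to `proteoclock run --out reports/demo`; all randomness fans
out from the single seed, so rerunning reproduces the tables byte for byte.
"""

from proteoclock import FitSettings, RunConfig, SyntheticConfig, run_full_analysis

config = RunConfig(
    synthetic=SyntheticConfig(),
    seed=1,
    n_perm=50,  # study-scale runs use 1000
    fit=FitSettings(gamma1_grid=(5.0, 50.0), gamma2_grid=(1.0, 100.0), cv_folds=3),
    out_dir="reports/demo",
)
report = run_full_analysis(config)

print("R2 panel:")
print(report.r2_matrix[["clock", "own_train_r2", "own_test_r2",
                        "cross_group_r2"]].round(3).to_string(index=False))
print("\nheld-out AUC per age:")
print(report.auc_by_age.round(3).to_string(index=False))
print(f"\npermutation FDR = {report.fdr.fdr:.3f} "
      f"(observed diff {report.fdr.observed_diff:.3f})")
print(f"\ntables written to {config.out_dir}/")

# The R2 panel (own-train / own-test / cross-group for each clock), the
# per-age AUCs, the FDR and the entropy tables together reproduce the
# study-style readout of the analysis on one synthetic cohort.
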
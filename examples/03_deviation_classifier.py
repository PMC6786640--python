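"""Score clock deviation per sample and evaluate the presymptomatic classifier.

Every held-out sample gets two coordinates — distance (in days) to the
normal clock and to the tumor clock — and the scalar score
delta_pr = d_normal - d_tumor.  Larger delta_pr means more tumor-like.
The score is evaluated per sampling age by rank AUC (exposed = positive).
"""

from proteoclock import (
    CONTROL, EXPOSED, NORMAL_CLOCK, TUMOR_CLOCK,
    FitSettings, SplitSpec, SyntheticConfig, deviation_points,
    evaluate_2d_predictor, fit_clock, generate_dataset, split_cohort,
)

dataset, _ = generate_dataset(SyntheticConfig(seed=1))
ctl_train, ctl_test = split_cohort(dataset, CONTROL, SplitSpec(seed=1))
exp_train, exp_test = split_cohort(dataset, EXPOSED, SplitSpec(seed=2))
normal = fit_clock(ctl_train, FitSettings(seed=1), label=NORMAL_CLOCK)
tumor = fit_clock(exp_train, FitSettings(seed=1), label=TUMOR_CLOCK)

# judge the classifier on held-out rats only: training rats sit
# artificially close to their own clock's regression line
held_out = set(ctl_test.sample_ids) | set(exp_test.sample_ids)
points = [p for p in deviation_points(dataset, normal, tumor)
          if p.sample_id in held_out]

sample = points[0]
print(f"sample {sample.sample_id} ({sample.group}, day {sample.age_days}): "
      f"d_normal={sample.d_normal:.1f}d  d_tumor={sample.d_tumor:.1f}d  "
      f"delta_pr={sample.delta_pr:+.1f}d")

print("\nper-age AUC of delta_pr (exposed vs control):")
for stratum, roc in evaluate_2d_predictor(points).items():
    label = "/".join(str(a) for a in stratum)
    print(f"  day {label:>7}: AUC = {roc.auc:.3f} "
          f"({roc.n_positive} exposed vs {roc.n_negative} control)")

# High AUC already at day 30 — weeks before any imaging-visible lesion in
# the timeline the cohort emulates — is the presymptomatic-detection claim
# this score operationalizes.
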
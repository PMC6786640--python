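"""Generate a synthetic two-group CSF cohort and inspect its design.

The generator draws 124 cross-sectional samples (60 control, 64 exposed)
over the sampling grid 30..150 days, with age-trending peaks, a planted
group divergence and an exposed-group noise burst at day 60.
"""

from proteoclock import SyntheticConfig, class_priors, generate_dataset

dataset, truth = generate_dataset(SyntheticConfig(seed=1))

print(f"{dataset.n_samples} samples x {dataset.n_features} features")
print("\ngroup x age design:")
print(dataset.crosstab())

priors = class_priors(dataset)
print(f"\nPr(normal) = {priors.p_normal:.2f}   Pr(tumor) = {priors.p_tumor:.2f}")
print(f"{len(truth.shared_feature_ids)} shared clock features, "
      f"{len(truth.divergent_feature_ids)} divergent, "
      f"{len(truth.background_feature_ids)} background")

# Pr(normal)/Pr(tumor) are the cohort's marginal class frequencies
# (60/124 and 64/124); the divergent features are the ones that will make
# the two groups' clocks disagree downstream.
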
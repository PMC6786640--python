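# Methods

## Data model

The universal input is a cross-sectional cohort: one CSF draw per rat, a
nonnegative intensity per anonymous m/Z peak, and per-sample metadata
(group ∈ {control, exposed}, sampling age in days, tumor status). Samples
are treated as independent; `rat_id` is provenance only. Validation
rejects non-finite or negative intensities, duplicate sample ids and
cohorts of fewer than two samples. The on-disk dialect is CSV with
metadata columns first; a `LayoutConfig` maps arbitrary tabular layouts
(including spreadsheets, whose sheet/column roles are configuration
because no fixed layout can be assumed).

## Clock model

A clock is penalized linear regression of age on standardized intensities:

    L(β) = ‖Y − Xβ‖² + γ₁‖β‖₁ + γ₂‖β‖₂²

* **Standardization.** Per feature, training mean and *population* SD
  (ddof = 0); parameters travel with the model so cross-application is
  well defined. Constant features are dropped with a warning.
* **Loss convention.** The squared error is an unscaled sum; γ₁ and γ₂
  multiply the raw L1 and squared-L2 norms. The scikit-learn elastic-net
  objective `1/(2n)‖y−Xβ‖² + α·l1·‖β‖₁ + α(1−l1)/2·‖β‖²` realizes it
  under `α·l1 = γ₁/(2n)`, `α(1−l1) = γ₂/n`; pure ridge (γ₁ = 0) and the
  unpenalized case dispatch to exact solvers. Under this convention the
  γ₁ = 0 solution is exactly `(XᵀX + γ₂I)⁻¹Xᵀy` on centered data, and on
  an orthogonal design with `XᵀX = cI`, γ₂ = 0, each coefficient is the
  OLS value soft-thresholded at γ₁/(2c) — both are verified against
  independently coded closed forms in the tests.
* **Hyperparameters.** Grid search over γ₁ ∈ {0.5, 5, 50, 500} × γ₂ ∈
  {1, 10, 100}, minimizing mean cross-validated squared prediction error;
  five age-stratified folds by default (folds are dealt round-robin within
  each age stratum, which unlike stock stratified k-fold tolerates the
  design's 5-sample late-age strata). First grid point wins ties, so
  selection is deterministic given the fold seed. No one-standard-error
  rule.
* **Splits.** 2/3 train / 1/3 test, stratified by age with rounding toward
  training (small strata are never emptied of training samples; strata of
  one go wholly to training with a warning). Stratification is used
  because unstratified splits of 5- and 6-sample strata can lose an age
  level entirely; it is switchable.
* **Fit quality.** R² is the squared Pearson correlation between predicted
  and actual age: bounded in [0, 1] even for a badly miscalibrated
  cross-applied clock, which the coefficient of determination is not.
  `method="cod"` provides 1 − SSres/SStot for sensitivity analyses.
  Constant predictions score 0 with a warning.

## Deviation score and 2D classifier

Distance to a clock is the absolute residual in days (signed and squared
variants are options). The classification score is ΔPr = d_normal −
d_tumor, the posterior-difference surrogate: with class priors 0.48/0.52
nearly equal they are deliberately omitted, and proximity to a clock's
regression line stands in for likelihood under that clock. No decision
boundary is trained; an in-sample logistic combination of the two
distances is available as a sensitivity scorer.

Evaluation is per sampling age (120/150 pooled, since by then all exposed
animals carry overt tumors) using the rank (Mann–Whitney) AUC with average
ranks, exposed as positive class. **Held-out evaluation matters:** each
clock's training rats sit artificially close to its own regression line,
so scoring the whole cohort inflates separation even on signal-free data
(null AUC ≈ 0.78 in our measurements). The pipeline therefore judges the
classifier on the union of the two held-out test thirds only; the
per-sample deviation table still covers everyone, flagged `held_out`.

## Permutation FDR

Observed statistic: R²(held-out control third) − R²(all exposed) under a
control-trained clock. Null: group labels randomly reassigned preserving
the 60/64 sizes (keeping the class priors fixed), and the *full* procedure
— fresh split, fresh penalty cross-validation — rerun per permutation, so
the null reflects everything the analyst did. The FDR counts strictly
greater permuted differences (ties have probability ~0 for continuous
statistics); an optional (r+1)/(n+1) correction exists but is off by
default so r exceedances out of n print as exactly r/n. A permutation
whose fit fails is recorded as −∞ — conservative, since it can never beat
the observed value — and still counts in the denominator.

On signal-free cohorts the estimator is *conservative* (FDR values skew
high): the generator assigns labels age-balanced, while permuted labelings
are hypergeometrically unbalanced across ages, truncating the age range of
the 'tumor' arm and deflating its R², so permuted differences tend to
exceed the balanced observed one. This only makes rejections harder.

## Entropy kinetics

The entropy estimator is a **reconstruction, not a reproduction** — no
published definition of the quantity exists to copy. Choice: Shannon
entropy (bits) of clock residuals binned on one equal-width grid spanning
the pooled residual range of all samples under that clock (6 bins by
default). Shared edges make cells directly comparable; entropy is bounded
by log₂(n_bins); a zero pooled range gives all-zero entropies. Residuals
(not ΔPr) enter because the kinetics are tracked per clock separately.
Cells with fewer than 5 samples are flagged low-confidence rather than
suppressed; empty cells are omitted with a warning. The contrast table
reports exposed-minus-control entropy per age under each clock and flags
the own-group-tighter sign pattern. Known bias: small cells underestimate
entropy, and cell size varies 5–23 in the study design, so single-cohort
profiles are noisy; kinetics claims are asserted on means over seeds.

## Feature report

Clock coefficients are aligned over the union of the two models' feature
universes (features a model dropped count as 0) and flagged when selected
by exactly one clock. Group differences per feature use the two-sided
rank-sum test by default (robust for skewed intensities; Welch-free
t-test optional) with Benjamini–Hochberg adjustment across features within
each tested age — 247 simultaneous tests demand multiplicity control.
Peaks stay anonymous throughout; no identification is attempted.

## Synthetic cohort generator

The generator emulates the study design, not the mass spectrometer. Counts
default to the study's group × age table (60 control + 64 exposed = 124;
ages 30–150 days); 247 features. Mean structure per feature:

* 12 **shared clock features**: baseline + slope·(age − 30), identical
  slope in both groups, slopes ~ N(0, 0.35²) intensity-units/day.
* 36 **divergent clock features**: group-specific independent slopes plus
  an exposed-group level shift composed of a deterministic *proteomic age
  shift* — the exposed peak sits where a control's would be
  `age_shift_days = 45` later along its own trend — and an idiosyncratic
  N(0, 10²) component. The age-shift term is what makes the two groups
  separable at the first sampling age: a purely random-sign level shift
  partially cancels through the fitted clock's weight vector and yields
  unstable early-age separation.
* 199 **background features**: baseline + noise.

Baselines ~ U(200, 600); noise is Gaussian with SD 16, scaled by a
(group, age) variance-inflation schedule defaulting to control ≡ 1 and
exposed {30: 1.5, 60: 4.0, 90: 1.0, 120: 2.5, 150: 3.0} — a dispersion
burst at the critical-transition age 60, a quiet window at 90 and renewed
chaos as overt tumors appear. Negative draws truncate at 0 (a log-normal
option exists but is off, keeping the linear model exact for recovery
tests). Everything is deterministic given the seed. The **null generator**
forces identical slopes, zero offsets and a flat variance schedule, so
group labels are exchangeable by construction — the reference for FDR and
AUC calibration.

These defaults were fixed by one calibration sweep so that the generator
exhibits the qualitative structure the analysis assumes — accurate
own-group clocks, degraded cross-application, day-30 separability, and the
day-60 entropy peak with the day-90 dip — and were then frozen. What
passing tests show is that the *pipeline recovers planted structure of
this kind*; they say nothing about real CSF spectra, which carry batch
effects, missingness, peak drift, heavy-tailed intensities and
rat-level correlation that the generator deliberately omits.

## Numerical and reproducibility choices

* Coordinate-descent tolerance 1e-10, max 100 000 iterations; ridge via
  Cholesky; oracle agreement asserted at 1e-6.
* All randomness flows through `numpy.random.default_rng`; the pipeline
  fans one master seed into named stage seeds (recorded in
  `provenance.json`), so stages can be rerun in isolation and a rerun of
  the same config writes byte-identical tables (CSV floats use shortest
  round-trip representation).
* Problem sizes in the test suite: statistical checks run on either the
  full 124 × 247 design (recovery, strong-signal FDR at 200 permutations)
  or a reduced 124 × 40 design with a 2 × 2 penalty grid (null
  calibration at 99 permutations × 20 cohorts, AUC null, monotonicity
  ladders), chosen to keep the whole suite within a few minutes while
  leaving the assertions' Monte-Carlo error small relative to the margins
  tested.

## Known limitations

* Pearson-R² is affine-invariant, so a cross-applied clock that is merely
  *miscalibrated* (right ordering, wrong scale) still scores high;
  cross-group degradation in the generator must come through slope
  cancellation and noise, not calibration error. The `cod` option exposes
  the stricter view.
* The permutation FDR reruns cross-validation ~n_perm times and dominates
  runtime; grids and n_perm are configurable for desk-scale runs.
* Entropy on 5-sample cells is heavily downward-biased; compare only
  like-sized cells or seed-averaged means.
* The 120/150 pooling is applied at evaluation; with only ~4 held-out
  rats there, late-age AUCs are coarse.
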
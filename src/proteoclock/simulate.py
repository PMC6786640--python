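"""Synthetic two-group cross-sectional proteomic cohorts.

The generator emulates the cohort design the pipeline targets: control and
exposed (tumor-destined) rats sampled once each at ages 30..150 days, with a
subset of anonymous intensity features that trend with age.  Three feature
categories are drawn:

* *shared clock features* — identical linear age trend in both groups; they
  let either group's clock tell age.
* *divergent clock features* — group-specific slopes plus a constant
  exposed-group level shift, so each group's clock predicts its own ages
  well but degrades when cross-applied, and the two groups are separable at
  every sampling age (the exposed CSF proteome deviates from the first
  sampling point onward).
* *background features* — baseline plus noise, no age information.

A group x age variance-inflation schedule scales the noise so that residual
dispersion (and hence the entropy of a clock's predictive metric) can peak
at a chosen age, mimicking a critical-transition-like burst of chaotic
dynamics in the exposed group.

All distributional choices are stand-ins: the real CSF intensity-generating
process is not modelled, only the statistical structure the downstream
analysis assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import CONTROL, EXPOSED, ProteomicDataset, SampleRecord
from .errors import ValidationError

#: study-design sample counts: (group, age_days) -> n_samples.
#: Cases are the exposed rats; the design totals 64 exposed + 60 control = 124.
TABLE1_COUNTS: dict[tuple[str, int], int] = {
    (EXPOSED, 30): 13, (CONTROL, 30): 11,
    (EXPOSED, 60): 16, (CONTROL, 60): 16,
    (EXPOSED, 90): 22, (CONTROL, 90): 23,
    (EXPOSED, 120): 6, (CONTROL, 120): 5,
    (EXPOSED, 150): 7, (CONTROL, 150): 5,
}

#: default noise-inflation schedule: the exposed group's dispersion bursts at
#: day 60 (critical transition), relaxes to a quiet window at day 90, then
#: rises again as overt tumors appear.
DEFAULT_VARIANCE_INFLATION: dict[tuple[str, int], float] = {
    (EXPOSED, 30): 1.5,
    (EXPOSED, 60): 4.0,
    (EXPOSED, 90): 1.0,
    (EXPOSED, 120): 2.5,
    (EXPOSED, 150): 3.0,
}


def _exposed_status(age: int) -> str:
    # histology timeline: hyperplasia precedes imaging-visible tumors
    if age < 60:
        return "none"
    if age < 120:
        return "microtumor"
    return "tumor"


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Units: ages in days, intensities in arbitrary units, slopes in intensity
    units per day.
    """

    counts: Mapping[tuple[str, int], int] = field(
        default_factory=lambda: dict(TABLE1_COUNTS)
    )
    n_features: int = 247
    n_shared_clock_features: int = 12
    n_divergent_clock_features: int = 36
    slope_scale: float = 0.35
    offset_scale: float = 10.0
    age_shift_days: float = 45.0
    noise_sd: float = 16.0
    baseline_range: tuple[float, float] = (200.0, 600.0)
    variance_inflation: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_INFLATION)
    )
    age_anchor: float = 30.0
    lognormal: bool = False
    seed: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_features < 1:
            problems.append("n_features must be >= 1")
        if self.n_shared_clock_features < 0 or self.n_divergent_clock_features < 0:
            problems.append("clock feature counts must be >= 0")
        if (
            self.n_shared_clock_features + self.n_divergent_clock_features
            > self.n_features
        ):
            problems.append("clock feature counts exceed n_features")
        if self.slope_scale <= 0:
            problems.append("slope_scale must be > 0")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be > 0")
        if self.offset_scale < 0:
            problems.append("offset_scale must be >= 0")
        if self.age_shift_days < 0:
            problems.append("age_shift_days must be >= 0")
        lo, hi = self.baseline_range
        if not (0 <= lo <= hi):
            problems.append("baseline_range must be 0 <= lo <= hi")
        if any(n < 0 for n in self.counts.values()):
            problems.append("all counts must be >= 0")
        for g in (CONTROL, EXPOSED):
            ages = {a for (grp, a), n in self.counts.items() if grp == g and n > 0}
            if len(ages) < 2:
                problems.append(f"group {g!r} needs >= 2 distinct ages with samples")
        if any(v < 1 for v in self.variance_inflation.values()):
            problems.append("variance_inflation multipliers must be >= 1")
        if problems:
            raise ValidationError("invalid SyntheticConfig: " + "; ".join(problems))

    @property
    def n_samples(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    shared_feature_ids: list[str]
    divergent_feature_ids: list[str]
    background_feature_ids: list[str]
    slopes: dict[str, dict[str, float]]       # feature_id -> {group: slope}
    offsets: dict[str, float]                  # feature_id -> exposed-group shift
    baselines: dict[str, float]
    mean_signal: np.ndarray                    # n_samples x n_features noiseless means


def _feature_ids(n: int) -> list[str]:
    return [f"mz_{i + 1:04d}" for i in range(n)]


def _build_samples(counts: Mapping[tuple[str, int], int]) -> list[SampleRecord]:
    samples = []
    k = 0
    for (group, age) in sorted(counts, key=lambda t: (t[1], t[0])):
        for _ in range(counts[(group, age)]):
            k += 1
            status = _exposed_status(age) if group == EXPOSED else "none"
            samples.append(
                SampleRecord(
                    sample_id=f"s{k:04d}",
                    rat_id=f"rat{k:04d}",
                    group=group,
                    age_days=age,
                    tumor_status=status,
                )
            )
    return samples


def _generate(config: SyntheticConfig, null: bool) -> tuple[ProteomicDataset, GroundTruth]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_features
    n_sh = config.n_shared_clock_features
    n_dv = config.n_divergent_clock_features
    fids = _feature_ids(p)
    shared_ids = fids[:n_sh]
    divergent_ids = fids[n_sh : n_sh + n_dv]
    background_ids = fids[n_sh + n_dv :]

    lo, hi = config.baseline_range
    baselines = rng.uniform(lo, hi, size=p)

    slopes = np.zeros((p, 2))  # columns: control, exposed
    shared_slopes = rng.normal(0.0, config.slope_scale, size=n_sh)
    slopes[:n_sh, 0] = shared_slopes
    slopes[:n_sh, 1] = shared_slopes
    ctl_div = rng.normal(0.0, config.slope_scale, size=n_dv)
    exp_div = rng.normal(0.0, config.slope_scale, size=n_dv)
    slopes[n_sh : n_sh + n_dv, 0] = ctl_div
    slopes[n_sh : n_sh + n_dv, 1] = exp_div if not null else ctl_div

    # exposed-group level shift of divergent peaks: a deterministic
    # "proteomic age shift" along the control trajectory plus an
    # idiosyncratic per-feature component
    offsets = np.zeros(p)
    raw_offsets = rng.normal(0.0, config.offset_scale, size=n_dv)
    if not null:
        offsets[n_sh : n_sh + n_dv] = (
            config.age_shift_days * ctl_div + raw_offsets
        )

    samples = _build_samples(config.counts)
    n = len(samples)
    ages = np.array([s.age_days for s in samples], dtype=float)
    exposed = np.array([s.group == EXPOSED for s in samples])

    mean = np.tile(baselines, (n, 1))
    slope_per_sample = np.where(exposed[:, None], slopes[:, 1], slopes[:, 0])
    mean = mean + slope_per_sample * (ages[:, None] - config.age_anchor)
    mean = mean + np.where(exposed[:, None], offsets, 0.0)

    sd = np.full(n, config.noise_sd)
    if not null:
        for i, s in enumerate(samples):
            infl = config.variance_inflation.get((s.group, s.age_days), 1.0)
            sd[i] = config.noise_sd * np.sqrt(infl)

    eps = rng.normal(0.0, 1.0, size=(n, p)) * sd[:, None]
    if config.lognormal:
        # multiplicative noise with matched coefficient of variation
        X = mean * np.exp(eps / np.maximum(np.abs(mean), 1e-12))
        X = np.maximum(X, 0.0)
    else:
        X = np.maximum(mean + eps, 0.0)

    dataset = ProteomicDataset(intensities=X, feature_ids=fids, samples=samples)
    truth = GroundTruth(
        shared_feature_ids=shared_ids,
        divergent_feature_ids=divergent_ids,
        background_feature_ids=background_ids,
        slopes={
            f: {CONTROL: float(slopes[j, 0]), EXPOSED: float(slopes[j, 1])}
            for j, f in enumerate(fids)
        },
        offsets={f: float(offsets[j]) for j, f in enumerate(fids)},
        baselines={f: float(baselines[j]) for j, f in enumerate(fids)},
        mean_signal=mean,
    )
    return dataset, truth


def generate_dataset(config: SyntheticConfig | None = None) -> tuple[ProteomicDataset, GroundTruth]:
    """Draw a cohort with planted group-specific age structure."""
    return _generate(config or SyntheticConfig(), null=False)


def generate_null_dataset(config: SyntheticConfig | None = None) -> ProteomicDataset:
    """Draw a cohort in which group labels carry no information.

    Slopes, offsets and noise schedules are identical across groups, so the
    labels are exchangeable by construction — the reference case for
    false-discovery calibration.
    """
    dataset, _ = _generate(config or SyntheticConfig(), null=True)
    return dataset
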
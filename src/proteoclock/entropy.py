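"""Entropy kinetics of a clock's predictive metric.

For one fitted clock, every sample yields a residual (predicted minus
actual age).  Binning all residuals under that clock on one shared
equal-width grid and computing the Shannon entropy of the bin occupancy
within each (group, age) cell gives a bounded, comparable measure of how
dispersed — how chaotic — the clock's predictive metric is for that group
at that age.  Tracking the cell entropies across sampling ages is the
*entropy kinetics* of the clock: a group following its own clock stays
tight (low entropy) while the other group's residuals spread out, and a
transient burst of dispersion shows up as an entropy peak at that age.

This estimator is a reconstruction: Shannon entropy of equal-width-binned
residuals with shared edges (default 6 bins), chosen for simplicity,
boundedness (<= log2 n_bins) and cross-cell comparability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clock import ClockModel, predict_ages
from .dataset import CONTROL, EXPOSED, ProteomicDataset
from .errors import ValidationError

#: cells smaller than this are flagged low-confidence rather than suppressed
LOW_CONFIDENCE_N = 5


@dataclass(frozen=True)
class EntropyEntry:
    clock_label: str
    group: str
    age_days: int
    entropy_bits: float
    n_samples: int
    low_confidence: bool


@dataclass
class EntropyProfile:
    """Shannon entropy of binned clock residuals per (group, age) cell."""

    entries: list[EntropyEntry]
    bin_edges: np.ndarray
    n_bins: int
    clock_label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "clock": e.clock_label,
                    "group": e.group,
                    "age_days": e.age_days,
                    "entropy_bits": e.entropy_bits,
                    "n_samples": e.n_samples,
                    "low_confidence": e.low_confidence,
                }
                for e in self.entries
            ]
        )

    def cell(self, group: str, age_days: int) -> EntropyEntry:
        for e in self.entries:
            if e.group == group and e.age_days == age_days:
                return e
        raise ValidationError(f"no entropy cell for ({group}, {age_days})")


def shannon_entropy_bits(counts: Sequence[int] | np.ndarray) -> float:
    """Shannon entropy (bits) of a discrete occupancy vector."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("entropy of an empty cell is undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy_profile(
    residuals: Sequence[float] | np.ndarray,
    groups: Sequence[str],
    ages: Sequence[int],
    n_bins: int = 6,
    clock_label: str = "clock",
) -> EntropyProfile:
    """Entropy per (group, age) cell on a shared equal-width residual grid.

    Bin edges span the pooled residual range of *all* samples under this
    clock so cells are directly comparable.  If every residual is equal the
    grid is degenerate and all entropies are 0.
    """
    residuals = np.asarray(residuals, dtype=float)
    groups = np.asarray(groups, dtype=object)
    ages = np.asarray(ages, dtype=int)
    if not (len(residuals) == len(groups) == len(ages)):
        raise ValidationError("residuals, groups and ages must align")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    lo, hi = float(residuals.min()), float(residuals.max())
    degenerate = hi <= lo
    edges = np.linspace(lo, hi if not degenerate else lo + 1.0, n_bins + 1)

    entries: list[EntropyEntry] = []
    for g in (CONTROL, EXPOSED):
        for a in sorted(set(ages)):
            mask = (groups == g) & (ages == a)
            n = int(mask.sum())
            if n == 0:
                warnings.warn(f"empty cell ({g}, {a}); omitted from profile")
                continue
            if degenerate:
                h = 0.0
            else:
                counts, _ = np.histogram(residuals[mask], bins=edges)
                h = shannon_entropy_bits(counts)
            entries.append(
                EntropyEntry(
                    clock_label=clock_label,
                    group=g,
                    age_days=int(a),
                    entropy_bits=h,
                    n_samples=n,
                    low_confidence=n < LOW_CONFIDENCE_N,
                )
            )
    return EntropyProfile(
        entries=entries, bin_edges=edges, n_bins=n_bins, clock_label=clock_label
    )


def entropy_profile_from_model(
    model: ClockModel, dataset: ProteomicDataset, n_bins: int = 6
) -> EntropyProfile:
    """Convenience wrapper: residuals of one clock applied to a whole cohort."""
    preds = predict_ages(model, dataset)
    residuals = [p.residual for p in preds]
    return entropy_profile(
        residuals,
        dataset.groups,
        dataset.ages.astype(int),
        n_bins=n_bins,
        clock_label=model.label,
    )


def entropy_contrast(
    profile_normal_clock: EntropyProfile, profile_tumor_clock: EntropyProfile
) -> pd.DataFrame:
    """Exposed-minus-control entropy per age under each clock.

    The expected signature of diverging clocks is ``own group tighter``:
    positive contrast under the normal clock (exposed rats are the chaotic
    ones there) and negative under the tumor clock.
    """
    frames = {}
    for name, prof in (
        ("normal_clock", profile_normal_clock),
        ("tumor_clock", profile_tumor_clock),
    ):
        df = prof.to_frame()
        piv = df.pivot_table(index="age_days", columns="group", values="entropy_bits")
        if CONTROL not in piv.columns or EXPOSED not in piv.columns:
            raise ValidationError(f"profile {name} lacks one of the groups")
        frames[name] = piv[EXPOSED] - piv[CONTROL]
    a, b = frames["normal_clock"], frames["tumor_clock"]
    if not a.index.equals(b.index):
        raise ValidationError("profiles cover different ages")
    out = pd.DataFrame(
        {
            "age_days": a.index,
            "contrast_normal_clock": a.to_numpy(),
            "contrast_tumor_clock": b.to_numpy(),
        }
    )
    out["own_group_smaller"] = (out["contrast_normal_clock"] > 0) & (
        out["contrast_tumor_clock"] < 0
    )
    return out.reset_index(drop=True)
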
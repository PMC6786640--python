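"""Clock-coefficient comparison and per-feature group tests.

Two views of which anonymous m/Z peaks drive the clocks: (a) an aligned
table of each feature's coefficient in the normal vs tumor clock, flagging
clock-specific selections; (b) per-feature two-sided tests of control vs
exposed intensity at chosen ages (default rank-sum, robust for skewed
intensities), Benjamini-Hochberg adjusted across features within each age.
Peaks stay anonymous throughout — the features are untargeted peaks with no
protein identity attached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clock import ClockModel
from .dataset import CONTROL, EXPOSED, ProteomicDataset
from .errors import ValidationError

_TEST_METHODS = ("rank_sum", "t_test")


@dataclass
class FeatureComparison:
    """Coefficient table and/or per-age test table over the feature universe."""

    coefficients: pd.DataFrame | None = None
    tests: pd.DataFrame | None = None


def compare_clocks(normal: ClockModel, tumor: ClockModel) -> FeatureComparison:
    """Align the two clocks' coefficients over their shared feature universe.

    Features a model dropped (or never saw) carry coefficient 0 for it.
    Features selected by exactly one clock are flagged ``clock_specific``.
    """
    if not set(normal.feature_ids) & set(tumor.feature_ids):
        raise ValidationError("clocks share no features; comparison undefined")
    universe = list(dict.fromkeys([*normal.feature_ids, *tumor.feature_ids]))
    coef_n = dict(zip(normal.feature_ids, normal.beta))
    coef_t = dict(zip(tumor.feature_ids, tumor.beta))
    rows = []
    for f in universe:
        cn = float(coef_n.get(f, 0.0))
        ct = float(coef_t.get(f, 0.0))
        sel_n, sel_t = cn != 0.0, ct != 0.0
        rows.append(
            {
                "feature_id": f,
                "coef_normal": cn,
                "coef_tumor": ct,
                "selected_normal": sel_n,
                "selected_tumor": sel_t,
                "clock_specific": sel_n != sel_t,
            }
        )
    return FeatureComparison(coefficients=pd.DataFrame(rows))


def per_feature_tests(
    dataset: ProteomicDataset,
    ages: Sequence[int] = (30, 150),
    method: str = "rank_sum",
) -> FeatureComparison:
    """Two-sided control-vs-exposed test per feature at each requested age.

    p-values are Benjamini-Hochberg adjusted across the feature set within
    each age.  Ages with fewer than 3 samples in either group are skipped
    with a warning.
    """
    if method not in _TEST_METHODS:
        raise ValidationError(f"method must be one of {_TEST_METHODS}")
    groups = dataset.groups
    sample_ages = dataset.ages.astype(int)
    frames = []
    for age in ages:
        ctl = (groups == CONTROL) & (sample_ages == age)
        exp = (groups == EXPOSED) & (sample_ages == age)
        if ctl.sum() < 3 or exp.sum() < 3:
            warnings.warn(
                f"age {age}: <3 samples in a group "
                f"({int(ctl.sum())} control, {int(exp.sum())} exposed); skipped"
            )
            continue
        Xc = dataset.intensities[ctl]
        Xe = dataset.intensities[exp]
        pvals = np.empty(dataset.n_features)
        for j in range(dataset.n_features):
            a, b = Xc[:, j], Xe[:, j]
            if method == "rank_sum":
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
            else:
                res = stats.ttest_ind(a, b)
            pvals[j] = res.pvalue
        pvals = np.nan_to_num(pvals, nan=1.0)  # zero-variance ties
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        frames.append(
            pd.DataFrame(
                {
                    "age_days": age,
                    "feature_id": dataset.feature_ids,
                    "p_value": pvals,
                    "q_value": qvals,
                    "n_control": int(ctl.sum()),
                    "n_exposed": int(exp.sum()),
                }
            )
        )
    tests = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["age_days", "feature_id", "p_value", "q_value", "n_control", "n_exposed"]
        )
    )
    return FeatureComparison(tests=tests)
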
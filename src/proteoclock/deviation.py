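"""Clock-deviation coordinates and the presymptomatic 2D predictor.

For a sample x with known age, its *distance* to a clock is the absolute
residual |predicted age - actual age| in days: how far the observation sits
from that clock's regression line at its age.  With two fitted clocks the
pair (distance to normal clock, distance to tumor clock) places each sample
on a 2D plot, and the scalar score

    delta_pr = dis(x to normal) - dis(x to tumor)

ranks samples by tumor-likeness: an observation close to the tumor clock's
line and far from the normal clock's scores high.  The score is a
posterior-difference surrogate — under Bayes' rule with near-equal class
priors, Pr(tumor|x) - Pr(normal|x) tracks Pr(x|tumor) - Pr(x|normal), and
proximity to a clock's regression line stands in for likelihood under that
clock.  Class priors are deliberately omitted from the score.

Per sampling age (late ages pooled), the score is evaluated against the
known group labels by the rank (Mann-Whitney) AUC with half-credit for
ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .clock import ClockModel, predict_ages
from .dataset import EXPOSED, ProteomicDataset
from .errors import ValidationError

#: evaluation strata of the study design; days 120 and 150 are pooled
#: because by then all exposed animals carry overt tumors
DEFAULT_AGE_STRATA: tuple[tuple[int, ...], ...] = ((30,), (60,), (90,), (120, 150))

_DISTANCE_MODES = ("abs", "signed", "squared")


@dataclass(frozen=True)
class DeviationPoint:
    """One sample's coordinates relative to the two clocks."""

    sample_id: str
    d_normal: float
    d_tumor: float
    age_days: int
    group: str
    tumor_status: str = "unknown"

    @property
    def delta_pr(self) -> float:
        """Tumor-likeness score: distance to normal minus distance to tumor."""
        return self.d_normal - self.d_tumor


@dataclass
class RocResult:
    """AUC of the score for exposed (positive) vs control within one stratum."""

    auc: float
    n_positive: int
    n_negative: int
    stratum: tuple[int, ...] = ()
    thresholds: np.ndarray = field(default_factory=lambda: np.array([]))
    tpr: np.ndarray = field(default_factory=lambda: np.array([]))
    fpr: np.ndarray = field(default_factory=lambda: np.array([]))


def clock_distances(
    model: ClockModel, dataset: ProteomicDataset, mode: str = "abs"
) -> np.ndarray:
    """Distance of every sample to one clock's regression line (days)."""
    if mode not in _DISTANCE_MODES:
        raise ValidationError(f"distance mode must be one of {_DISTANCE_MODES}")
    preds = predict_ages(model, dataset)
    resid = np.array([p.residual for p in preds])
    if mode == "abs":
        return np.abs(resid)
    if mode == "squared":
        return resid**2
    return resid


def clock_distance(
    model: ClockModel, dataset: ProteomicDataset, sample_id: str, mode: str = "abs"
) -> float:
    """Distance of one named sample to a clock."""
    ids = dataset.sample_ids
    if sample_id not in ids:
        raise ValidationError(f"unknown sample_id {sample_id!r}")
    return float(clock_distances(model, dataset, mode)[ids.index(sample_id)])


def deviation_points(
    dataset: ProteomicDataset,
    normal: ClockModel,
    tumor: ClockModel,
    mode: str = "abs",
) -> list[DeviationPoint]:
    """Per-sample 2D deviation coordinates under both clocks."""
    d_n = clock_distances(normal, dataset, mode)
    d_t = clock_distances(tumor, dataset, mode)
    return [
        DeviationPoint(
            sample_id=s.sample_id,
            d_normal=float(dn),
            d_tumor=float(dt),
            age_days=s.age_days,
            group=s.group,
            tumor_status=s.tumor_status,
        )
        for s, dn, dt in zip(dataset.samples, d_n, d_t)
    ]


def rank_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC with average ranks (half-credit for ties)."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs at least one sample of each class")
    ranks = stats.rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def logistic_2d_scores(
    points: Sequence[DeviationPoint], seed: int = 0
) -> np.ndarray:
    """Alternative scorer: logistic combination of (d_normal, d_tumor).

    Trained on the supplied points' own labels — an in-sample discriminant,
    useful as a sensitivity check on the fixed delta_pr score.
    """
    from sklearn.linear_model import LogisticRegression

    X = np.array([[p.d_normal, p.d_tumor] for p in points])
    y = np.array([p.group == EXPOSED for p in points], dtype=int)
    if y.min() == y.max():
        raise ValidationError("logistic scorer needs both classes present")
    est = LogisticRegression(random_state=seed, max_iter=1000)
    est.fit(X, y)
    return est.predict_proba(X)[:, 1]


def _roc_points(scores: np.ndarray, positive: np.ndarray):
    order = np.argsort(-scores, kind="stable")
    s, p = scores[order], positive[order]
    thresholds, tpr, fpr = [], [], []
    n_pos, n_neg = p.sum(), (~p).sum()
    tp = fp = 0
    i = 0
    while i < len(s):
        thr = s[i]
        while i < len(s) and s[i] == thr:
            tp += p[i]
            fp += not p[i]
            i += 1
        thresholds.append(thr)
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
    return np.array(thresholds), np.array(tpr), np.array(fpr)


def evaluate_2d_predictor(
    points: Sequence[DeviationPoint],
    age_strata: Sequence[Sequence[int]] | None = None,
    scorer: str = "delta_pr",
    seed: int = 0,
) -> dict[tuple[int, ...], RocResult]:
    """Per-age-stratum AUC of the tumor-likeness score.

    Positive class is the exposed (tumor-destined) group.  Strata holding a
    single class are skipped with a warning.
    """
    if age_strata is None:
        present = sorted({p.age_days for p in points})
        age_strata = [
            tuple(s for s in stratum if s in present)
            for stratum in DEFAULT_AGE_STRATA
        ]
        age_strata = [s for s in age_strata if s]
        extra = [a for a in present if not any(a in s for s in DEFAULT_AGE_STRATA)]
        age_strata += [(a,) for a in extra]
    if scorer == "delta_pr":
        all_scores = np.array([p.delta_pr for p in points])
    elif scorer == "logistic":
        all_scores = logistic_2d_scores(points, seed=seed)
    else:
        raise ValidationError(f"unknown scorer {scorer!r}")
    positive_all = np.array([p.group == EXPOSED for p in points])
    ages = np.array([p.age_days for p in points])

    results: dict[tuple[int, ...], RocResult] = {}
    for stratum in age_strata:
        stratum = tuple(stratum)
        mask = np.isin(ages, stratum)
        if not mask.any():
            continue
        pos = positive_all[mask]
        if pos.all() or not pos.any():
            warnings.warn(f"stratum {stratum} holds a single class; skipped")
            continue
        scores = all_scores[mask]
        thr, tpr, fpr = _roc_points(scores, pos)
        results[stratum] = RocResult(
            auc=rank_auc(scores, pos),
            n_positive=int(pos.sum()),
            n_negative=int((~pos).sum()),
            stratum=stratum,
            thresholds=thr,
            tpr=tpr,
            fpr=fpr,
        )
    return results
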
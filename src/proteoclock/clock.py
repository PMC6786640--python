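"""Elastic-net age clocks: fitting, prediction and fit-quality scoring.

A *clock* is a penalized linear regression of chronological age (sampling
day) on standardized peak intensities,

    L(beta) = ||Y - X beta||^2 + gamma1 * ||beta||_1 + gamma2 * ||beta||_2^2,

with an unpenalized intercept, fitted separately to the control cohort (the
*normal clock*) and the exposed cohort (the *tumor clock*).  The L1 weight
``gamma1`` limits how many peaks are used; the L2 weight ``gamma2`` keeps
groups of correlated peaks in play.  Both are chosen by age-stratified
k-fold cross-validation on a grid.

Loss convention (recorded in model provenance): the squared-error term is
an *unscaled* sum over training samples, X is standardized per feature to
zero mean and unit (population) standard deviation on the training set, and
gamma1/gamma2 multiply the raw L1 / squared-L2 norms of beta.  With
``gamma1 = 0`` the solution is exactly the ridge closed form
``(X'X + gamma2 I)^-1 X' y`` on centered data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import ElasticNet, LinearRegression, Ridge

from .dataset import ProteomicDataset, normalize_group
from .errors import ValidationError

NORMAL_CLOCK = "normal_clock"
TUMOR_CLOCK = "tumor_clock"

LOSS_CONVENTION = (
    "L(beta) = ||y - X beta||^2 + gamma1*||beta||_1 + gamma2*||beta||_2^2; "
    "X standardized (train mean 0, population sd 1); intercept unpenalized"
)


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split specification (default 2/3 train)."""

    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    stratify_by_age: bool = True

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class FitSettings:
    """Hyperparameter search settings shared by fitting entry points."""

    gamma1_grid: tuple[float, ...] = (0.5, 5.0, 50.0, 500.0)
    gamma2_grid: tuple[float, ...] = (1.0, 10.0, 100.0)
    cv_folds: int = 5
    seed: int = 0


@dataclass
class ClockModel:
    """A fitted clock: coefficients, penalties and training provenance."""

    beta: np.ndarray
    intercept: float
    gamma1: float
    gamma2: float
    feature_ids: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    training_sample_ids: list[str]
    training_r2: float
    label: str = NORMAL_CLOCK
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        if not (
            len(self.beta)
            == len(self.feature_ids)
            == len(self.feature_means)
            == len(self.feature_sds)
        ):
            raise ValidationError("beta, feature_ids and standardization lengths differ")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValidationError("penalty weights must be >= 0")
        if np.any(self.feature_sds <= 0):
            raise ValidationError("standardization sds must be > 0 for retained features")
        if self.label not in (NORMAL_CLOCK, TUMOR_CLOCK):
            raise ValidationError(f"unknown clock label {self.label!r}")

    @property
    def n_selected(self) -> int:
        return int(np.sum(self.beta != 0.0))

    # -- text serialization (exact round-trip) -------------------------
    def to_json(self) -> str:
        payload = {
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "gamma1": self.gamma1,
            "gamma2": self.gamma2,
            "feature_ids": self.feature_ids,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "training_sample_ids": self.training_sample_ids,
            "training_r2": self.training_r2,
            "label": self.label,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ClockModel":
        d = json.loads(text)
        return cls(
            beta=np.array(d["beta"], dtype=float),
            intercept=float(d["intercept"]),
            gamma1=float(d["gamma1"]),
            gamma2=float(d["gamma2"]),
            feature_ids=list(d["feature_ids"]),
            feature_means=np.array(d["feature_means"], dtype=float),
            feature_sds=np.array(d["feature_sds"], dtype=float),
            training_sample_ids=list(d["training_sample_ids"]),
            training_r2=float(d["training_r2"]),
            label=d["label"],
            provenance=dict(d.get("provenance", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ClockModel":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class ClockPrediction:
    """Predicted vs actual age for one sample under one clock."""

    sample_id: str
    actual_age: float
    predicted_age: float

    @property
    def residual(self) -> float:
        return self.predicted_age - self.actual_age


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------

def split_cohort(
    dataset: ProteomicDataset, group: str, spec: SplitSpec | None = None
) -> tuple[ProteomicDataset, ProteomicDataset]:
    """Randomly split one group's cohort into train/test, stratified by age.

    Each age stratum contributes approximately ``train_fraction`` of its
    samples to training (rounded toward training, so small strata are never
    emptied of training samples).  Strata with fewer than 2 samples go
    wholly to training with a warning.
    """
    spec = spec or SplitSpec()
    cohort = dataset.select_group(normalize_group(group))
    if cohort.n_samples < 6:
        raise ValidationError(
            f"cohort {group!r} has {cohort.n_samples} samples; need >= 6 to split"
        )
    rng = np.random.default_rng(spec.seed)
    ages = cohort.ages
    train_idx: list[int] = []
    test_idx: list[int] = []
    if spec.stratify_by_age:
        strata = [np.flatnonzero(ages == a) for a in np.unique(ages)]
    else:
        strata = [np.arange(cohort.n_samples)]
    for idx in strata:
        idx = rng.permutation(idx)
        if len(idx) < 2:
            warnings.warn(
                f"age stratum with {len(idx)} sample(s) assigned wholly to training"
            )
            train_idx.extend(idx)
            continue
        n_train = int(np.ceil(spec.train_fraction * len(idx)))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    if not test_idx:
        # every stratum rounded wholly into training; demote one sample
        warnings.warn("rounding left the test set empty; demoting one training sample")
        test_idx.append(train_idx.pop())
    train_idx = sorted(train_idx)
    test_idx = sorted(test_idx)
    return cohort.subset(train_idx), cohort.subset(test_idx)


# ----------------------------------------------------------------------
# solving the penalized least-squares problem
# ----------------------------------------------------------------------

def solve_elastic_net(
    X: np.ndarray, y: np.ndarray, gamma1: float, gamma2: float
) -> tuple[np.ndarray, float]:
    """Minimize the clock loss on an already-standardized design matrix.

    Returns ``(beta, intercept)``.  The scikit-learn elastic-net objective
    ``1/(2n)||y-Xb||^2 + a*l1*||b||_1 + a*(1-l1)/2*||b||^2`` equals our loss
    up to the factor 2n under ``a*l1 = gamma1/(2n)`` and
    ``a*(1-l1) = gamma2/n``; pure-ridge and unpenalized cases dispatch to
    their exact solvers.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if gamma1 < 0 or gamma2 < 0:
        raise ValidationError("penalty weights must be >= 0")
    if gamma1 == 0 and gamma2 == 0:
        est = LinearRegression()
    elif gamma1 == 0:
        est = Ridge(alpha=gamma2, solver="cholesky")
    else:
        alpha = (gamma1 / 2.0 + gamma2) / n
        l1_ratio = (gamma1 / 2.0) / (gamma1 / 2.0 + gamma2)
        est = ElasticNet(
            alpha=alpha, l1_ratio=l1_ratio, max_iter=100_000, tol=1e-10
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return np.asarray(est.coef_, dtype=float), float(est.intercept_)


def elastic_net_loss(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, intercept: float,
    gamma1: float, gamma2: float,
) -> float:
    """Evaluate the clock loss at a candidate solution (for diagnostics)."""
    resid = y - (X @ beta + intercept)
    return float(
        resid @ resid + gamma1 * np.abs(beta).sum() + gamma2 * beta @ beta
    )


def _stratified_folds(
    ages: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deal samples into folds round-robin within each age stratum.

    Unlike StratifiedKFold this tolerates strata smaller than the fold
    count, which the small late-age strata of the study design require.
    """
    assignment = np.empty(len(ages), dtype=int)
    offset = 0
    for a in np.unique(ages):
        idx = rng.permutation(np.flatnonzero(ages == a))
        for k, i in enumerate(idx):
            assignment[i] = (offset + k) % n_folds
        offset += len(idx)
    folds = [np.flatnonzero(assignment == f) for f in range(n_folds)]
    return [f for f in folds if len(f) > 0]


def fit_clock(
    train: ProteomicDataset,
    settings: FitSettings | None = None,
    label: str = NORMAL_CLOCK,
    *,
    gamma1_grid: Sequence[float] | None = None,
    gamma2_grid: Sequence[float] | None = None,
    cv_folds: int | None = None,
    seed: int | None = None,
) -> ClockModel:
    """Fit a clock to a training cohort with grid-search cross-validation.

    ``(gamma1, gamma2)`` minimizing the mean cross-validated squared
    prediction error are selected (first grid point wins ties, gamma1-major
    order); folds are age-stratified and deterministic given ``seed``.
    Constant features are dropped with a warning.
    """
    s = settings or FitSettings()
    g1_grid = tuple(gamma1_grid) if gamma1_grid is not None else s.gamma1_grid
    g2_grid = tuple(gamma2_grid) if gamma2_grid is not None else s.gamma2_grid
    folds_n = cv_folds if cv_folds is not None else s.cv_folds
    seed = seed if seed is not None else s.seed
    if not g1_grid or not g2_grid:
        raise ValidationError("penalty grids must be nonempty")

    y = train.ages
    if len(np.unique(y)) < 2:
        raise ValidationError("training cohort has a single age; clock undefined")
    if train.n_samples < folds_n:
        raise ValidationError(
            f"{train.n_samples} training samples < {folds_n} CV folds"
        )

    X_raw = train.intensities
    sds_all = X_raw.std(axis=0)
    keep = sds_all > 0
    if not np.all(keep):
        dropped = [f for f, k in zip(train.feature_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} constant feature(s): {dropped[:5]}...")
    feature_ids = [f for f, k in zip(train.feature_ids, keep) if k]
    X_raw = X_raw[:, keep]
    means = X_raw.mean(axis=0)
    sds = X_raw.std(axis=0)
    X = (X_raw - means) / sds

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, folds_n, rng)
    best = None
    cv_table = []
    for g1 in g1_grid:
        for g2 in g2_grid:
            sq_errors = []
            for val_idx in folds:
                tr_mask = np.ones(len(y), dtype=bool)
                tr_mask[val_idx] = False
                Xtr_raw, ytr = X_raw[tr_mask], y[tr_mask]
                m = Xtr_raw.mean(axis=0)
                sd = Xtr_raw.std(axis=0)
                sd = np.where(sd > 0, sd, 1.0)  # fold-constant features: no info
                beta, b0 = solve_elastic_net((Xtr_raw - m) / sd, ytr, g1, g2)
                pred = ((X_raw[val_idx] - m) / sd) @ beta + b0
                sq_errors.extend((pred - y[val_idx]) ** 2)
            mse = float(np.mean(sq_errors))
            cv_table.append({"gamma1": g1, "gamma2": g2, "cv_mse": mse})
            if best is None or mse < best[0]:
                best = (mse, g1, g2)
    _, gamma1, gamma2 = best

    beta, intercept = solve_elastic_net(X, y, gamma1, gamma2)
    model = ClockModel(
        beta=beta,
        intercept=intercept,
        gamma1=float(gamma1),
        gamma2=float(gamma2),
        feature_ids=feature_ids,
        feature_means=means,
        feature_sds=sds,
        training_sample_ids=train.sample_ids,
        training_r2=np.nan,
        label=label,
        provenance={
            "loss_convention": LOSS_CONVENTION,
            "gamma1_grid": list(g1_grid),
            "gamma2_grid": list(g2_grid),
            "cv_folds": folds_n,
            "cv_seed": seed,
            "cv_mse": best[0],
            "n_train": train.n_samples,
        },
    )
    model.training_r2 = r_squared(predict_ages(model, train))
    return model


def predict_ages(model: ClockModel, dataset: ProteomicDataset) -> list[ClockPrediction]:
    """Apply a clock to any dataset carrying (a superset of) its features.

    Standardization uses the model's stored training parameters, so
    cross-application (normal clock on exposed rats and vice versa) is
    well-defined.
    """
    pos = {f: j for j, f in enumerate(dataset.feature_ids)}
    missing = [f for f in model.feature_ids if f not in pos]
    if missing:
        raise ValidationError(f"dataset lacks model feature(s): {missing[:5]}")
    cols = [pos[f] for f in model.feature_ids]
    X = (dataset.intensities[:, cols] - model.feature_means) / model.feature_sds
    pred = X @ model.beta + model.intercept
    return [
        ClockPrediction(sample_id=s.sample_id, actual_age=float(s.age_days),
                        predicted_age=float(p))
        for s, p in zip(dataset.samples, pred)
    ]


def r_squared(predictions: Sequence[ClockPrediction], method: str = "pearson") -> float:
    """Fit quality of a set of predictions.

    Default is the squared Pearson correlation between predicted and actual
    ages — bounded in [0, 1] even for a miscalibrated cross-applied clock.
    ``method='cod'`` gives the coefficient of determination
    ``1 - SS_res/SS_tot`` instead (can be negative).
    """
    if len(predictions) < 3:
        raise ValidationError("need >= 3 predictions to score")
    actual = np.array([p.actual_age for p in predictions])
    pred = np.array([p.predicted_age for p in predictions])
    if np.allclose(actual, actual[0]):
        raise ValidationError("all actual ages equal; fit quality undefined")
    if method == "cod":
        ss_res = np.sum((actual - pred) ** 2)
        ss_tot = np.sum((actual - actual.mean()) ** 2)
        return float(1.0 - ss_res / ss_tot)
    if method != "pearson":
        raise ValidationError(f"unknown r_squared method {method!r}")
    if np.allclose(pred, pred[0]):
        warnings.warn("constant predictions; returning r_squared = 0")
        return 0.0
    r = stats.pearsonr(actual, pred).statistic
    return float(r * r)
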
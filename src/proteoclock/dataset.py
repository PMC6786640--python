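"""Dataset model and tabular I/O for two-group proteomic cohorts.

The universal input of the pipeline is a samples x features matrix of
nonnegative peak intensities (anonymous m/Z features) with per-sample
metadata: rat id, group (control vs exposed), sampling age in days and
tumor status.  Samples are treated as cross-sectional and independent (one
CSF draw per rat); ``rat_id`` is retained for provenance only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

CONTROL = "control"
EXPOSED = "exposed"
GROUPS = (CONTROL, EXPOSED)

TUMOR_STATUSES = ("none", "microtumor", "tumor", "unknown")

#: aliases accepted on input and normalized to the canonical group labels
_GROUP_ALIASES = {
    "control": CONTROL,
    "ctrl": CONTROL,
    "normal": CONTROL,
    "saline": CONTROL,
    "exposed": EXPOSED,
    "case": EXPOSED,
    "enu": EXPOSED,
    "tumor": EXPOSED,
}


def normalize_group(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _GROUP_ALIASES:
        raise ValidationError(
            f"unrecognized group label {label!r}; expected one of {sorted(set(_GROUP_ALIASES))}"
        )
    return _GROUP_ALIASES[key]


@dataclass(frozen=True)
class SampleRecord:
    """One CSF draw from one rat."""

    sample_id: str
    rat_id: str
    group: str
    age_days: int
    tumor_status: str = "unknown"

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.tumor_status not in TUMOR_STATUSES:
            raise ValidationError(
                f"tumor_status must be one of {TUMOR_STATUSES}, got {self.tumor_status!r}"
            )
        if int(self.age_days) <= 0:
            raise ValidationError(f"age_days must be positive, got {self.age_days}")
        object.__setattr__(self, "age_days", int(self.age_days))


@dataclass
class ProteomicDataset:
    """Validated intensity matrix plus aligned per-sample metadata.

    Row ``i`` of ``intensities`` is the profile of ``samples[i]``.
    """

    intensities: np.ndarray
    feature_ids: list[str]
    samples: list[SampleRecord]

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        X = self.intensities
        if X.ndim != 2:
            raise ValidationError(f"intensities must be 2-D, got shape {X.shape}")
        n, p = X.shape
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValidationError("need at least 1 feature")
        if len(self.samples) != n:
            raise ValidationError(
                f"{len(self.samples)} sample records for {n} intensity rows"
            )
        if len(self.feature_ids) != p:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {p} intensity columns"
            )
        if len(set(self.feature_ids)) != p:
            raise ValidationError("feature_ids are not unique")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != n:
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id(s): {dupes}")
        if not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))[0]
            raise ValidationError(
                f"non-finite intensity at sample {ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )
        if np.any(X < 0):
            bad = np.argwhere(X < 0)[0]
            raise ValidationError(
                f"negative intensity at sample {ids[bad[0]]!r}, "
                f"feature {self.feature_ids[bad[1]]!r}"
            )

    # -- convenience views ---------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age_days for s in self.samples], dtype=float)

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.samples], dtype=object)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "ProteomicDataset":
        idx = np.asarray(indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ProteomicDataset(
            intensities=self.intensities[idx].copy(),
            feature_ids=list(self.feature_ids),
            samples=[self.samples[i] for i in idx],
        )

    def select_group(self, group: str) -> "ProteomicDataset":
        group = normalize_group(group)
        mask = self.groups == group
        if mask.sum() == 0:
            raise ValidationError(f"no samples in group {group!r}")
        return self.subset(mask)

    def relabel(self, new_groups: Sequence[str]) -> "ProteomicDataset":
        """Return a copy with reassigned group labels (used by the permutation null)."""
        if len(new_groups) != self.n_samples:
            raise ValidationError("one new label per sample required")
        samples = [
            replace(s, group=normalize_group(g)) for s, g in zip(self.samples, new_groups)
        ]
        return ProteomicDataset(self.intensities.copy(), list(self.feature_ids), samples)

    def to_frame(self) -> pd.DataFrame:
        """Default on-disk dialect: metadata columns first, then one column per feature."""
        meta = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "rat_id": [s.rat_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "age_days": [s.age_days for s in self.samples],
                "tumor_status": [s.tumor_status for s in self.samples],
            }
        )
        feat = pd.DataFrame(self.intensities, columns=self.feature_ids)
        return pd.concat([meta, feat.set_index(meta.index)], axis=1)

    def crosstab(self) -> pd.DataFrame:
        """Group x age sample counts (the cohort-design table)."""
        df = pd.DataFrame({"group": self.groups, "age_days": self.ages.astype(int)})
        return pd.crosstab(df["group"], df["age_days"])


@dataclass(frozen=True)
class ClassPriors:
    """Marginal class probabilities Pr(normal), Pr(tumor) from cohort counts."""

    p_normal: float
    p_tumor: float

    def __post_init__(self):
        for p in (self.p_normal, self.p_tumor):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"prior {p} outside [0, 1]")
        if abs(self.p_normal + self.p_tumor - 1.0) > 1e-9:
            raise ValidationError("priors must sum to 1")


@dataclass
class LayoutConfig:
    """Maps an arbitrary tabular layout onto the dataset model.

    ``samples_as='columns'`` transposes the table first (features as rows).
    ``sheet`` selects a worksheet when reading a spreadsheet.  Metadata
    columns not listed among the roles are treated as feature columns unless
    ``feature_columns`` narrows them explicitly.
    """

    sample_id_column: str = "sample_id"
    group_column: str = "group"
    age_column: str = "age_days"
    rat_id_column: str | None = "rat_id"
    tumor_status_column: str | None = "tumor_status"
    samples_as: str = "rows"
    sheet: str | int | None = None
    feature_columns: list[str] | None = None
    log1p: bool = False

    def __post_init__(self):
        if self.samples_as not in ("rows", "columns"):
            raise ConfigurationError("samples_as must be 'rows' or 'columns'")


DEFAULT_LAYOUT = LayoutConfig()


def _load_table(path: str | Path, layout: LayoutConfig) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=layout.sheet or 0, dtype=object)
    else:
        df = pd.read_csv(path, dtype=object)
    if layout.samples_as == "columns":
        df = df.set_index(df.columns[0]).T.reset_index(names=layout.sample_id_column)
    return df


def read_dataset(path: str | Path, layout: LayoutConfig | None = None) -> ProteomicDataset:
    """Read a dataset from a delimited file or spreadsheet.

    The default layout is the package's own dialect (comma-separated,
    samples as rows, metadata columns first); a :class:`LayoutConfig`
    adapts other layouts such as supplementary-table spreadsheets.
    """
    layout = layout or DEFAULT_LAYOUT
    df = _load_table(path, layout)

    required = {
        "sample id": layout.sample_id_column,
        "group": layout.group_column,
        "age": layout.age_column,
    }
    for role, col in required.items():
        if col not in df.columns:
            raise ConfigurationError(
                f"layout names {col!r} as the {role} column but the file has no such "
                f"column (columns: {list(df.columns)[:8]}...)"
            )

    meta_cols = [layout.sample_id_column, layout.group_column, layout.age_column]
    for opt in (layout.rat_id_column, layout.tumor_status_column):
        if opt is not None and opt in df.columns:
            meta_cols.append(opt)

    if layout.feature_columns is not None:
        feat_cols = list(layout.feature_columns)
        missing = [c for c in feat_cols if c not in df.columns]
        if missing:
            raise ConfigurationError(f"feature columns absent from file: {missing}")
    else:
        feat_cols = [c for c in df.columns if c not in meta_cols]
    if not feat_cols:
        raise ConfigurationError("no feature columns identified by the layout")

    samples = []
    for i, row in df.iterrows():
        sid = str(row[layout.sample_id_column])
        try:
            age = int(float(row[layout.age_column]))
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"age {row[layout.age_column]!r} of sample {sid!r} is not an integer"
            ) from exc
        rat = (
            str(row[layout.rat_id_column])
            if layout.rat_id_column in df.columns
            else sid
        )
        status = (
            str(row[layout.tumor_status_column])
            if layout.tumor_status_column in df.columns
            else "unknown"
        )
        samples.append(
            SampleRecord(
                sample_id=sid,
                rat_id=rat,
                group=normalize_group(row[layout.group_column]),
                age_days=age,
                tumor_status=status,
            )
        )

    raw = df[feat_cols]
    X = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(feat_cols):
        values = raw[col].to_numpy()
        try:
            # astype(float) parses exactly (unlike pandas' fast to_numeric path)
            parsed = values.astype(float)
        except (TypeError, ValueError):
            parsed = None
        if parsed is None or np.isnan(parsed).any():
            for i, v in enumerate(values):
                try:
                    ok = not np.isnan(float(v))
                except (TypeError, ValueError):
                    ok = False
                if not ok:
                    raise ParseError(
                        f"non-numeric or missing intensity {v!r} at sample "
                        f"{samples[i].sample_id!r}, feature {col!r}"
                    )
            raise ParseError(f"could not parse feature column {col!r}")
        X[:, j] = parsed
    if layout.log1p:
        X = np.log1p(X)

    return ProteomicDataset(intensities=X, feature_ids=[str(c) for c in feat_cols], samples=samples)


def write_dataset(dataset: ProteomicDataset, path: str | Path) -> None:
    """Write a dataset in the default comma-separated dialect (re-readable)."""
    dataset.validate()
    df = dataset.to_frame()
    # shortest round-trip float representation guarantees exact re-read
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def class_priors(dataset: ProteomicDataset) -> ClassPriors:
    """Pr(normal) = #control / (#control + #case), Pr(tumor) the complement."""
    groups = dataset.groups
    n_control = int(np.sum(groups == CONTROL))
    n_case = int(np.sum(groups == EXPOSED))
    if n_control == 0 or n_case == 0:
        raise ValidationError("class priors need at least one sample of each group")
    total = n_control + n_case
    return ClassPriors(p_normal=n_control / total, p_tumor=n_case / total)
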
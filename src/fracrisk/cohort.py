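"""Patient-level cohort table: schema, CSV I/O, and the stratified
independent-training-and-testing (ITT) split.

The canonical schema has 20 candidate predictors — two demographics, eight
comorbidity flags, and ten corticosteroid dose/duration variables (OCS =
oral/intravenous, ICS = inhaled) — plus a binary outcome column ``fracture``
(1 = hip or vertebral fracture; the minority class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical predictor names, in fixed report order.
FEATURE_NAMES: tuple[str, ...] = (
    "Sex",
    "Age",
    "Asthma",
    "COPD",
    "Bronchiectasis",
    "DM",
    "Cancer",
    "Liver_cirrhosis",
    "ESRD",
    "Osteoporosis",
    "OCS_followup_days",
    "OCS_exposed_days",
    "ICS_followup_days",
    "ICS_exposed_days",
    "OCS_dose",
    "ICS_dose",
    "OCS_follow_daily_dose",
    "OCS_exposed_daily_dose",
    "ICS_follow_daily_dose",
    "ICS_exposed_daily_dose",
)

#: Binary predictors: sex (1 = male) and the eight comorbidity flags.
BINARY_FEATURES: tuple[str, ...] = FEATURE_NAMES[0:1] + FEATURE_NAMES[2:10]

#: Non-negative continuous predictors (doses, durations, daily doses).
CONTINUOUS_FEATURES: tuple[str, ...] = ("Age",) + FEATURE_NAMES[10:]

LABEL_COLUMN = "fracture"

MINIMUM_AGE = 20.0


class CohortSchemaError(ValueError):
    """Raised when a table violates the cohort schema."""


@dataclass
class CohortTable:
    """A feature matrix plus a binary fracture label per record.

    ``features`` is a DataFrame whose column order is the feature order;
    ``labels`` is an int array aligned with its rows (1 = fracture, the
    minority class).  Toy tables used for algorithm-level work may carry an
    arbitrary feature set; the canonical 20-column schema is enforced at the
    I/O boundary and by the generator.
    """

    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or len(self.labels) != len(self.features):
            raise CohortSchemaError(
                f"labels length {self.labels.shape} does not match "
                f"{len(self.features)} records"
            )
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise CohortSchemaError(f"labels must be 0/1; found {sorted(bad)}")
        self.features = self.features.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n(self) -> int:
        return len(self.labels)

    def class_counts(self) -> tuple[int, int]:
        """(majority count M, minority count m) for labels (0, 1)."""
        m = int(self.labels.sum())
        return self.n - m, m

    def class_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def subset(self, indices: Iterable[int]) -> "CohortTable":
        idx = np.asarray(list(indices), dtype=np.int64)
        return CohortTable(self.features.iloc[idx].reset_index(drop=True),
                           self.labels[idx])

    def matrix(self, columns: Sequence[str] | None = None) -> np.ndarray:
        cols = list(columns) if columns is not None else self.feature_names
        missing = [c for c in cols if c not in self.features.columns]
        if missing:
            raise CohortSchemaError(f"missing feature column(s): {missing}")
        return self.features[cols].to_numpy(dtype=np.float64)

    def to_frame(self) -> pd.DataFrame:
        frame = self.features.copy()
        frame[LABEL_COLUMN] = self.labels
        return frame

    def equals(self, other: "CohortTable") -> bool:
        return (np.array_equal(self.labels, other.labels)
                and self.features.columns.equals(other.features.columns)
                and np.allclose(self.features.to_numpy(dtype=float),
                                other.features.to_numpy(dtype=float),
                                rtol=1e-12, atol=0.0))

    # -- schema validation ----------------------------------------------
    def validate_schema(self, strict: bool = True) -> None:
        """Check the canonical 20-column schema and value domains.

        ``strict`` additionally rejects unknown extra columns.
        """
        cols = list(self.features.columns)
        missing = [c for c in FEATURE_NAMES if c not in cols]
        if missing:
            raise CohortSchemaError(f"missing feature column(s): {missing}")
        if strict:
            extra = [c for c in cols if c not in FEATURE_NAMES]
            if extra:
                raise CohortSchemaError(f"unknown column(s): {extra}")
        for col in BINARY_FEATURES:
            vals = self.features[col].to_numpy()
            bad = np.setdiff1d(np.unique(vals), [0, 1])
            if bad.size:
                raise CohortSchemaError(
                    f"column {col!r} must be 0/1; found {bad.tolist()}")
        for col in CONTINUOUS_FEATURES:
            vals = self.features[col].to_numpy(dtype=float)
            if np.isnan(vals).any():
                row = int(np.flatnonzero(np.isnan(vals))[0])
                raise CohortSchemaError(f"missing value in {col!r} at row {row}")
            if (vals < 0).any():
                row = int(np.flatnonzero(vals < 0)[0])
                raise CohortSchemaError(
                    f"negative value in {col!r} at row {row}")
        if self.n and (self.features["Age"].to_numpy(dtype=float) < MINIMUM_AGE).any():
            row = int(np.flatnonzero(
                self.features["Age"].to_numpy(dtype=float) < MINIMUM_AGE)[0])
            raise CohortSchemaError(
                f"Age below {MINIMUM_AGE:g} at row {row}; the cohort covers "
                "adults aged 20 and older")


def load_cohort(path: str | Path, strict: bool = True) -> CohortTable:
    """Read a cohort CSV (canonical schema, header row, label ``fracture``).

    Rows keep file order.  Errors name the offending column and row.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if LABEL_COLUMN not in frame.columns:
        raise CohortSchemaError(
            f"{path.name}: missing label column {LABEL_COLUMN!r}")
    for col in (LABEL_COLUMN,) + FEATURE_NAMES:
        if col not in frame.columns:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise CohortSchemaError(
                f"{path.name}: non-numeric value {frame[col][row]!r} in "
                f"column {col!r} at row {row}")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise CohortSchemaError(
                f"{path.name}: missing value in column {col!r} at row {row}")
        frame[col] = coerced
    labels = frame[LABEL_COLUMN].to_numpy()
    table = CohortTable(frame.drop(columns=[LABEL_COLUMN]), labels)
    table.validate_schema(strict=strict)
    return table


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort as UTF-8 CSV with a header row.

    Continuous values are written with enough digits to round-trip to 12
    significant figures.
    """
    table.to_frame().to_csv(path, index=False, float_format="%.12g")


@dataclass
class SplitResult:
    """Outcome of the stratified ITT split."""

    train: CohortTable
    test: CohortTable
    seed: int
    train_indices: np.ndarray = field(repr=False, default=None)
    test_indices: np.ndarray = field(repr=False, default=None)


def itt_split(cohort: CohortTable, train_fraction: float = 0.5,
              seed: int = 0) -> SplitResult:
    """Stratified independent-training-and-testing split.

    Each class contributes ``floor(n_class * train_fraction)`` records to the
    training half, drawn without replacement under ``seed``; the remainder
    (including the extra record of an odd class) goes to testing.  Row order
    within each half preserves input order.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_major, n_minor = cohort.class_counts()
    if n_major == 0 or n_minor == 0:
        raise ValueError("both classes must be present to split")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    for label in (0, 1):
        idx = cohort.class_indices(label)
        k = int(np.floor(len(idx) * train_fraction))
        train_idx.append(rng.choice(idx, size=k, replace=False))
    train = np.sort(np.concatenate(train_idx))
    mask = np.zeros(cohort.n, dtype=bool)
    mask[train] = True
    test = np.flatnonzero(~mask)
    return SplitResult(train=cohort.subset(train), test=cohort.subset(test),
                       seed=seed, train_indices=train, test_indices=test)
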
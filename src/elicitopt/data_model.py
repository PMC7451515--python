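"""Domain types and table I/O for factorial elicitation experiments.

An elicitation experiment applies a fungal elicitor (cell extract CE,
culture filtrate CF, or cell wall CW) at a given concentration on a given
culture day, optionally with methyl-beta-cyclodextrin (MBCD), and measures
paclitaxel in the medium at a later harvest day.  One row of the table is
one flask-level observation.  Models are fit per elicitor type on the four
numeric inputs (elicitor concentration, MBCD concentration, adding day,
harvest day) against paclitaxel concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ELICITOR_TYPES = ("CE", "CF", "CW")

#: canonical column order of the CSV interchange format
CSV_COLUMNS = (
    "elicitor_type",
    "elicitor_conc",
    "mbcd_conc",
    "adding_day",
    "harvest_day",
    "block_id",
    "paclitaxel",
)

#: design-matrix column order, fixed across the whole package
INPUT_COLUMNS = ("elicitor_conc", "mbcd_conc", "adding_day", "harvest_day")


class SchemaError(ValueError):
    """Input file does not have the expected columns."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class ElicitationRecord:
    """One observation of the factorial elicitation experiment.

    ``elicitor_conc`` is in % (v/v); zero encodes the vehicle control of the
    corresponding elicitor type.  ``mbcd_conc`` is in mM.  Days are culture
    days (day 0 = subculture); ``harvest_day`` may be fractional.
    ``paclitaxel`` is the measured response in micrograms per litre.
    """

    elicitor_type: str
    elicitor_conc: float
    mbcd_conc: float
    adding_day: float
    harvest_day: float
    block_id: str
    paclitaxel: float

    def __post_init__(self) -> None:
        if self.elicitor_type not in ELICITOR_TYPES:
            raise ValidationError(
                f"elicitor_type must be one of {ELICITOR_TYPES}, "
                f"got {self.elicitor_type!r}"
            )
        for name in ("elicitor_conc", "mbcd_conc", "adding_day",
                     "harvest_day", "paclitaxel"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
        for name in ("elicitor_conc", "mbcd_conc", "paclitaxel"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{name} must be non-negative, got {getattr(self, name)}"
                )
        if self.adding_day <= 0:
            raise ValidationError(
                f"adding_day must be positive, got {self.adding_day}"
            )
        if not self.harvest_day > self.adding_day:
            raise ValidationError(
                f"harvest_day ({self.harvest_day}) must be after "
                f"adding_day ({self.adding_day})"
            )


@dataclass
class ExperimentTable:
    """Ordered collection of records plus free-form metadata."""

    records: list[ElicitationRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("ExperimentTable must contain at least one record")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {col: getattr(r, col) for col in CSV_COLUMNS} for r in self.records
        ])

    def equals(self, other: "ExperimentTable", tol: float = 1e-9) -> bool:
        """Field-by-field equality, real-valued fields within ``tol``."""
        if len(self) != len(other):
            return False
        for a, b in zip(self.records, other.records):
            if a.elicitor_type != b.elicitor_type or a.block_id != b.block_id:
                return False
            for name in ("elicitor_conc", "mbcd_conc", "adding_day",
                         "harvest_day", "paclitaxel"):
                if abs(getattr(a, name) - getattr(b, name)) > tol:
                    return False
        return True


@dataclass(frozen=True)
class DataSplit:
    """A reproducible train/test partition of table row indices."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    seed: int
    fraction: float

    def __post_init__(self) -> None:
        train, test = set(self.train_indices), set(self.test_indices)
        if train & test:
            raise ValidationError("train and test indices overlap")
        n = len(train) + len(test)
        if train | test != set(range(n)):
            raise ValidationError("train and test indices do not cover 0..n-1")


@dataclass
class DesignMatrix:
    """Numeric inputs and response for one elicitor's model.

    Columns of ``X`` are fixed as (elicitor_conc, mbcd_conc, adding_day,
    harvest_day); ``input_ranges`` holds the per-column (min, max) actually
    observed, which downstream models use for scaling and search bounds.
    """

    X: np.ndarray
    y: np.ndarray
    column_names: tuple[str, ...]
    input_ranges: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.y.ndim != 1:
            raise ValidationError("X must be 2-D and y 1-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("X and y row counts differ")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValidationError("design matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def read_experiment_csv(path) -> ExperimentTable:
    """Read an experiment table from CSV, validating every record.

    The header must name the seven canonical fields (case-insensitive, any
    order).  Raises :class:`SchemaError` for a missing column and
    :class:`ValidationError` (with the offending row index) for bad values.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(ElicitationRecord(
                elicitor_type=str(row["elicitor_type"]).strip(),
                elicitor_conc=float(row["elicitor_conc"]),
                mbcd_conc=float(row["mbcd_conc"]),
                adding_day=float(row["adding_day"]),
                harvest_day=float(row["harvest_day"]),
                block_id=str(row["block_id"]).strip(),
                paclitaxel=float(row["paclitaxel"]),
            ))
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return ExperimentTable(records=records, metadata={"source": str(path)})


def write_experiment_csv(table: ExperimentTable, path) -> None:
    """Write a table as CSV with the canonical column order."""
    table.to_frame().to_csv(path, index=False, columns=list(CSV_COLUMNS))


def split_train_test(table: ExperimentTable, fraction: float = 0.75,
                     seed: int = 0) -> DataSplit:
    """Randomly partition the table rows into training and testing subsets.

    ``fraction`` is the training share.  The training count is
    ``round(fraction * n)`` with ties to nearest even; the permutation is a
    uniform shuffle (no stratification).  Identical seeds give identical
    splits.
    """
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n_train = int(np.round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)  # both subsets non-empty
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return DataSplit(
        train_indices=tuple(int(i) for i in np.sort(perm[:n_train])),
        test_indices=tuple(int(i) for i in np.sort(perm[n_train:])),
        seed=seed,
        fraction=fraction,
    )


def to_design_matrix(table: ExperimentTable, elicitor: str,
                     indices=None) -> DesignMatrix:
    """Extract the single-elicitor design matrix for the given row indices.

    Rows whose ``elicitor_type`` differs from ``elicitor`` are dropped;
    within the selection the original table order is preserved so that X and
    y stay row-aligned with the source records.
    """
    if elicitor not in ELICITOR_TYPES:
        raise ValueError(f"unknown elicitor {elicitor!r}")
    if indices is None:
        indices = range(len(table))
    rows = [table.records[i] for i in indices
            if table.records[i].elicitor_type == elicitor]
    if not rows:
        raise ValueError(f"no records of elicitor {elicitor} in selection")
    X = np.array([[getattr(r, c) for c in INPUT_COLUMNS] for r in rows])
    y = np.array([r.paclitaxel for r in rows])
    ranges = tuple((float(X[:, j].min()), float(X[:, j].max()))
                   for j in range(X.shape[1]))
    return DesignMatrix(X=X, y=y, column_names=INPUT_COLUMNS,
                        input_ranges=ranges)
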
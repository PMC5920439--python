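"""Domain types, CSV I/O and the two deterministic labeling rules.

A subject carries three physical parameters — age (years), weight (kg),
height (m) — and four tibial rotation angles in degrees: right/left tibial
external/internal rotation (RTER, RTIR, LTER, LTIR).

Two rule systems partition the cohort:

* **Rule clusters** (C1/C2/C3) from the physical parameters: subjects older
  than 30 years form cluster 1; the rest split on body weight at 60 kg.
* **Rotation types** (1/2/3) per angle: at most 20 degrees is pathological
  (type 1), between 20 and 65 degrees is normal (type 2), above 65 degrees
  is pathological again (type 3).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

log = logging.getLogger(__name__)

ROTATION_COLUMNS = ("rter", "rtir", "lter", "ltir")
CSV_COLUMNS = ("id", "age", "weight", "height") + ROTATION_COLUMNS


class ValidationError(ValueError):
    """A subject field or a whole file violates a domain invariant."""


class RotationType(enum.IntEnum):
    """Pathology class of a single rotation angle."""

    TYPE1 = 1  # <= 20 degrees, pathological
    TYPE2 = 2  # (20, 65] degrees, normal
    TYPE3 = 3  # > 65 degrees, pathological


class RuleCluster(enum.IntEnum):
    """Rule-based cohort cluster from the physical parameters."""

    C1 = 1  # age > 30
    C2 = 2  # age <= 30, weight <= 60 kg
    C3 = 3  # age <= 30, weight > 60 kg


@dataclass(frozen=True)
class Subject:
    """One individual: identifier, physical parameters, four rotation angles.

    Parameters
    ----------
    id : str
        Opaque unique identifier.
    age, weight, height : float
        Strictly positive; years, kilograms, meters.
    rter, rtir, lter, ltir : float
        Non-negative rotation angles in degrees.
    """

    id: str
    age: float
    weight: float
    height: float
    rter: float
    rtir: float
    lter: float
    ltir: float

    def __post_init__(self) -> None:
        for name in ("age", "weight", "height"):
            if not getattr(self, name) > 0:
                raise ValidationError(
                    f"subject {self.id!r}: {name} must be strictly positive, "
                    f"got {getattr(self, name)}"
                )
        for name in ROTATION_COLUMNS:
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"subject {self.id!r}: {name} must be >= 0, "
                    f"got {getattr(self, name)}"
                )

    def rotation(self, name: str) -> float:
        """Return one of the four rotation angles by column name."""
        name = name.lower()
        if name not in ROTATION_COLUMNS:
            raise KeyError(f"unknown rotation {name!r}; expected one of {ROTATION_COLUMNS}")
        return getattr(self, name)


@dataclass
class Dataset:
    """Ordered collection of subjects with unique ids."""

    subjects: list[Subject] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes[:5]}")

    @property
    def n(self) -> int:
        return len(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[Subject]:
        return iter(self.subjects)

    def __getitem__(self, i: int) -> Subject:
        return self.subjects[i]

    def to_frame(self) -> pd.DataFrame:
        """Subjects as a DataFrame with the canonical 8 columns."""
        return pd.DataFrame(
            [[getattr(s, c) for c in CSV_COLUMNS] for s in self.subjects],
            columns=list(CSV_COLUMNS),
        )

    def physical_matrix(self):
        """(n, 3) float array of age, weight, height — the clustering features."""
        import numpy as np

        return np.array([[s.age, s.weight, s.height] for s in self.subjects], dtype=float)

    def rotation_values(self, name: str):
        """(n,) float array of one rotation angle across all subjects."""
        import numpy as np

        return np.array([s.rotation(name) for s in self.subjects], dtype=float)

    def rule_clusters(self):
        """(n,) int array of rule-cluster labels (values 1..3)."""
        import numpy as np

        return np.array(
            [int(assign_rule_cluster(s.age, s.weight, s.height)) for s in self.subjects]
        )

    def rotation_types(self, name: str):
        """(n,) int array of pathology types (values 1..3) for one rotation."""
        import numpy as np

        return np.array([int(classify_rotation_type(s.rotation(name))) for s in self.subjects])


def classify_rotation_type(angle: float) -> RotationType:
    """Classify one rotation angle into its pathology type.

    Type 1 for angles in [0, 20], type 2 for (20, 65], type 3 above 65
    degrees. Angles must be non-negative.
    """
    if angle < 0:
        raise ValidationError(f"rotation angle must be >= 0, got {angle}")
    if angle <= 20:
        return RotationType.TYPE1
    if angle <= 65:
        return RotationType.TYPE2
    return RotationType.TYPE3


def assign_rule_cluster(age: float, weight: float, height: float) -> RuleCluster:
    """Assign a subject to its rule-based cluster.

    Age above 30 years puts the subject in cluster 1; otherwise weight at
    most 60 kg gives cluster 2 and heavier subjects cluster 3. Height is
    accepted for interface symmetry but does not enter the rule: in the
    study population the weight and height thresholds (60 kg, 1.70 m)
    select nearly the same subjects, so weight alone decides.
    """
    if age <= 0 or weight <= 0 or height <= 0:
        raise ValidationError(
            f"age, weight, height must be positive, got ({age}, {weight}, {height})"
        )
    if age > 30:
        return RuleCluster.C1
    if weight <= 60:
        return RuleCluster.C2
    return RuleCluster.C3


def _validate_frame(df: pd.DataFrame, source: str) -> Dataset:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing required column(s) {missing}")
    subjects: list[Subject] = []
    heights = pd.to_numeric(df["height"], errors="coerce")
    # files sometimes carry height in cm; detect by the column median
    cm_heights = heights.median() > 3
    if cm_heights:
        log.warning("%s: height column median %.1f > 3, interpreting as centimeters", source, heights.median())
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        vals = {}
        for col in CSV_COLUMNS[1:]:
            raw = getattr(row, col)
            try:
                vals[col] = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{source}: row {row_no}, column {col!r}: non-numeric value {raw!r}"
                ) from None
        if cm_heights:
            vals["height"] = vals["height"] / 100.0
        try:
            subjects.append(Subject(id=str(row.id), **vals))
        except ValidationError as exc:
            raise ValidationError(f"{source}: row {row_no}: {exc}") from None
    try:
        return Dataset(subjects)
    except ValidationError as exc:
        raise ValidationError(f"{source}: {exc}") from None


def read_dataset(path: str | Path) -> Dataset:
    """Read a cohort CSV (header ``id,age,weight,height,rter,rtir,lter,ltir``).

    Every row is validated into a :class:`Subject`; row order is preserved.
    Heights whose column median exceeds 3 are taken to be centimeters and
    converted to meters with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str})
    return _validate_frame(df, str(path))


def write_dataset(dataset: Dataset, path: str | Path) -> Path:
    """Write a cohort to CSV so that :func:`read_dataset` round-trips it."""
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    return path


def dataset_from_records(records: Iterable[dict]) -> Dataset:
    """Build a Dataset from dicts keyed by the canonical column names."""
    return Dataset([Subject(**{k: r[k] for k in CSV_COLUMNS}) for r in records])
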
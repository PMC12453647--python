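"""Cohort data model: feature schema, per-patient records, and the cohort container.

A cohort is a collection of per-patient hourly tables in the layout of the
public sepsis-prediction datasets: one row per patient-hour, a patient
identifier, an in-stay hour counter (ICULOS), vital-sign / laboratory /
demographic feature columns, and a per-timestep binary ``SepsisLabel`` that
is 0 before sepsis onset and 1 from onset to discharge.

Values are stored densely as floats together with a boolean ``observed_mask``;
an entry whose mask is ``False`` was never measured (labs in particular are
very sparsely observed) and its stored magnitude is meaningless until
imputation.  Categorical features (e.g. gender) are stored as the index of
the value in the schema's declared category order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError, ValidationError

VITAL = "vital"
LAB = "lab"
DEMOGRAPHIC = "demographic"

_GROUPS = (VITAL, LAB, DEMOGRAPHIC)


@dataclass(frozen=True)
class FeatureSchema:
    """Declares the feature columns of a cohort table.

    Parameters
    ----------
    feature_names
        Ordered feature identifiers (unique; excludes id/time/label columns).
    groups
        Mapping feature -> one of ``{"vital", "lab", "demographic"}``.
    categorical
        Mapping from categorical feature name to its declared category order,
        e.g. ``{"Gender": ("Male", "Female")}``.  Order is significant: it
        fixes both label codes and one-hot column order.
    """

    feature_names: tuple[str, ...]
    groups: dict[str, str]
    categorical: dict[str, tuple[str, ...]] = field(default_factory=dict)
    label_column: str = "SepsisLabel"
    id_column: str = "Patient_ID"
    time_column: str = "ICULOS"

    def __post_init__(self) -> None:
        names = self.feature_names
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        for name in names:
            group = self.groups.get(name)
            if group not in _GROUPS:
                raise SchemaError(
                    f"feature {name!r} has invalid group {group!r}; "
                    f"expected one of {_GROUPS}"
                )
        for name, cats in self.categorical.items():
            if name not in names:
                raise SchemaError(f"categorical feature {name!r} not in feature list")
            if len(cats) < 2:
                raise SchemaError(
                    f"categorical feature {name!r} must declare >= 2 categories"
                )
        reserved = {self.label_column, self.id_column, self.time_column}
        overlap = reserved & set(names)
        if overlap:
            raise SchemaError(f"reserved columns used as features: {sorted(overlap)}")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def index_of(self, name: str) -> int:
        return self.feature_names.index(name)

    def is_categorical(self, name: str) -> bool:
        return name in self.categorical

    def numeric_features(self) -> list[str]:
        return [f for f in self.feature_names if f not in self.categorical]

    def columns(self) -> list[str]:
        """All columns of a serialized table, in canonical order."""
        return [self.id_column, self.time_column, *self.feature_names, self.label_column]


@dataclass
class PatientRecord:
    """Time-indexed feature matrix for a single patient stay."""

    patient_id: str
    times: np.ndarray          # (T,) in-stay hours, strictly increasing
    values: np.ndarray         # (T, F) float
    observed_mask: np.ndarray  # (T, F) bool, True = measured
    labels: np.ndarray         # (T,) in {0, 1}

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != self.observed_mask.shape:
            raise ValidationError(
                f"patient {self.patient_id}: values shape {self.values.shape} "
                f"!= mask shape {self.observed_mask.shape}"
            )
        if len(self.times) != self.values.shape[0]:
            raise ValidationError(
                f"patient {self.patient_id}: {len(self.times)} times but "
                f"{self.values.shape[0]} value rows"
            )
        if len(self.labels) != len(self.times):
            raise ValidationError(
                f"patient {self.patient_id}: label length {len(self.labels)} "
                f"!= timestep count {len(self.times)}"
            )
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"patient {self.patient_id}: times are not strictly increasing"
            )
        bad = ~np.isin(self.labels, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"patient {self.patient_id}: non-binary label "
                f"{self.labels[row]!r} at row {row}"
            )

    @property
    def n_timesteps(self) -> int:
        return len(self.times)


@dataclass
class Cohort:
    """A feature schema plus the per-patient records that conform to it."""

    schema: FeatureSchema
    records: list[PatientRecord]

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient ids in cohort")
        for r in self.records:
            if r.values.shape[1] != self.schema.n_features:
                raise ValidationError(
                    f"patient {r.patient_id}: {r.values.shape[1]} feature "
                    f"columns, schema declares {self.schema.n_features}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def n_timesteps(self) -> int:
        return int(sum(r.n_timesteps for r in self.records))

    @property
    def n_positive(self) -> int:
        return int(sum(int(r.labels.sum()) for r in self.records))

    def prevalence(self) -> float:
        """Fraction of patient-hours labelled septic."""
        total = self.n_timesteps
        return self.n_positive / total if total else 0.0

    def subset(self, patient_ids) -> "Cohort":
        wanted = set(patient_ids)
        return Cohort(self.schema, [r for r in self.records if r.patient_id in wanted])
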
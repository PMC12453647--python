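"""Imputation, scaling, categorical encoding, and outlier handling.

All statistics are learned on the training split only and frozen in a
:class:`FittedPreprocessor`; applying it to validation/test data reuses the
training statistics, honouring the patient-wise no-leakage principle the
splitting module enforces.

Pipeline order (applied by :func:`transform`): impute -> outlier policy ->
scale, with categorical features encoded (one-hot by default) at the end.
Time-varying features (vitals, labs) are imputed by carrying the previous
observation forward, the next observation backward for leading gaps, and the
training mean for patients with no observation at all; static demographics
use the training mean (numeric) or mode (categorical).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .cohort import Cohort, FeatureSchema
from .errors import EncodingError, ImputationError

__all__ = [
    "PreprocessConfig",
    "FittedPreprocessor",
    "NumericPatient",
    "NumericCohort",
    "impute_mean",
    "impute_time_series",
    "minmax_scale",
    "zscore_standardize",
    "one_hot_encode",
    "label_encode",
    "outlier_transform",
    "fit",
    "transform",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing behaviour.

    ``imputation`` routes feature groups to an imputation mode: time-varying
    groups default to forward/backward fill, demographics to the mean.
    ``std_convention`` selects the population (/N) or sample (/(N-1)) form of
    the standard deviation used for both z-scoring and outlier z-values.
    """

    imputation: dict = field(
        default_factory=lambda: {
            "vital": "forward_fill",
            "lab": "forward_fill",
            "demographic": "mean",
        }
    )
    scaling: str = "zscore"              # "minmax" | "zscore"
    outlier_threshold: float = 3.0
    outlier_policy: str = "cap"          # "cap" | "remove" | "flag"
    std_convention: str = "population"   # "population" | "sample"
    categorical_encoding: str = "one_hot"  # "one_hot" | "label"

    def __post_init__(self) -> None:
        if self.outlier_threshold <= 0:
            raise ValueError("outlier z-threshold must be > 0")
        if self.scaling not in ("minmax", "zscore"):
            raise ValueError(f"unknown scaling mode {self.scaling!r}")
        if self.outlier_policy not in ("cap", "remove", "flag"):
            raise ValueError(f"unknown outlier policy {self.outlier_policy!r}")
        if self.std_convention not in ("population", "sample"):
            raise ValueError(f"unknown std convention {self.std_convention!r}")
        if self.categorical_encoding not in ("one_hot", "label"):
            raise ValueError(f"unknown encoding {self.categorical_encoding!r}")


# --- column-level operations -------------------------------------------------


def impute_mean(column_values, observed_mask, feature_name: str = "<column>"):
    """Replace missing entries by the mean of the observed entries."""
    values = np.asarray(column_values, dtype=float).copy()
    mask = np.asarray(observed_mask, dtype=bool)
    if not mask.any():
        raise ImputationError(f"feature {feature_name!r}: no observed values")
    values[~mask] = values[mask].mean()
    return values


def impute_time_series(column_values, observed_mask, feature_name: str = "<column>"):
    """Carry the previous observation forward; back-fill leading gaps.

    Interior and trailing gaps take the last observed value before them;
    a leading run of missing entries takes the first observed value.
    """
    values = np.asarray(column_values, dtype=float).copy()
    mask = np.asarray(observed_mask, dtype=bool)
    if not mask.any():
        raise ImputationError(f"feature {feature_name!r}: no observed values")
    idx = np.where(mask, np.arange(len(values)), -1)
    idx = np.maximum.accumulate(idx)
    first = int(np.flatnonzero(mask)[0])
    idx[idx < 0] = first  # leading gap -> next observed value
    return values[idx]


def minmax_scale(column_values, vmin: float, vmax: float):
    """Map to (x - min) / (max - min); a constant feature maps to 0."""
    values = np.asarray(column_values, dtype=float)
    if vmax == vmin:
        return np.zeros_like(values)
    return (values - vmin) / (vmax - vmin)


def zscore_standardize(column_values, mean: float, std: float):
    """Map to (x - mu) / sigma; a constant feature (sigma = 0) maps to 0."""
    values = np.asarray(column_values, dtype=float)
    if std == 0:
        return np.zeros_like(values)
    return (values - mean) / std


def one_hot_encode(category_value, declared_order, strict: bool = True):
    """Unit vector with a 1 at the category's declared index.

    In lenient mode an unseen category encodes as the all-zeros vector.
    """
    vec = np.zeros(len(declared_order), dtype=float)
    if category_value in declared_order:
        vec[declared_order.index(category_value)] = 1.0
    elif strict:
        raise EncodingError(
            f"category {category_value!r} not in declared order {declared_order}"
        )
    return vec


def label_encode(category_value, declared_order, strict: bool = True) -> int:
    """Integer code of the category in the declared order."""
    if category_value in declared_order:
        return declared_order.index(category_value)
    if strict:
        raise EncodingError(
            f"category {category_value!r} not in declared order {declared_order}"
        )
    return -1


def outlier_transform(
    column_values, mean: float, std: float, threshold: float = 3.0, policy: str = "cap"
):
    """Flag entries with |z| > threshold and apply the configured policy.

    Returns ``(values, flags)`` where flags marks the outliers.  ``cap``
    replaces them by mean +/- threshold*std (sign-matching); ``remove``
    replaces them by NaN (to be re-imputed); ``flag`` leaves values intact.
    """
    values = np.asarray(column_values, dtype=float).copy()
    if std == 0:
        return values, np.zeros(values.shape, dtype=bool)
    z = (values - mean) / std
    flags = np.abs(z) > threshold
    if policy == "cap":
        values[flags] = mean + np.sign(z[flags]) * threshold * std
    elif policy == "remove":
        values[flags] = np.nan
    elif policy != "flag":
        raise ValueError(f"unknown outlier policy {policy!r}")
    return values, flags


# --- fitted pipeline ---------------------------------------------------------


@dataclass
class NumericPatient:
    """Fully numeric, fully observed per-patient matrix after transform."""

    patient_id: str
    times: np.ndarray
    values: np.ndarray  # (T, F_out) no missing entries
    labels: np.ndarray


@dataclass
class NumericCohort:
    feature_names: list[str]
    patients: list[NumericPatient]

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_timesteps(self) -> int:
        return int(sum(p.values.shape[0] for p in self.patients))


@dataclass
class FittedPreprocessor:
    """Frozen training-split statistics for every feature.

    ``raw_stats`` holds the mean/std of observed raw training values (used
    for outlier z-values and mean imputation).  ``scale_stats`` holds the
    mean/std/min/max of the imputed-and-outlier-handled training matrix, so
    the scaling contract (z-scored training output has mean 0 / sd 1; min-max
    output lies in [0, 1]) holds exactly on the training split.
    """

    schema: FeatureSchema
    config: PreprocessConfig
    raw_stats: dict          # feature -> {mean, std}
    scale_stats: dict        # feature -> {mean, std, min, max}
    category_maps: dict      # feature -> {category_name: index}
    modes: dict              # categorical feature -> modal category index

    def output_feature_names(self) -> list[str]:
        names: list[str] = []
        for f in self.schema.feature_names:
            if self.schema.is_categorical(f) and self.config.categorical_encoding == "one_hot":
                names.extend(f"{f}={c}" for c in self.schema.categorical[f])
            else:
                names.append(f)
        return names

    # plain-text round-trip for exact reuse across runs
    def save(self, path) -> None:
        payload = {
            "config": {
                "imputation": self.config.imputation,
                "scaling": self.config.scaling,
                "outlier_threshold": self.config.outlier_threshold,
                "outlier_policy": self.config.outlier_policy,
                "std_convention": self.config.std_convention,
                "categorical_encoding": self.config.categorical_encoding,
            },
            "raw_stats": self.raw_stats,
            "scale_stats": self.scale_stats,
            "category_maps": self.category_maps,
            "modes": self.modes,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path, schema: FeatureSchema) -> "FittedPreprocessor":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            schema=schema,
            config=PreprocessConfig(**payload["config"]),
            raw_stats=payload["raw_stats"],
            scale_stats=payload["scale_stats"],
            category_maps=payload["category_maps"],
            modes=payload["modes"],
        )


def _std(values: np.ndarray, convention: str) -> float:
    ddof = 1 if convention == "sample" and len(values) > 1 else 0
    return float(np.std(values, ddof=ddof))


def _impute_record(rec_values, rec_mask, schema, config, raw_stats, modes):
    """Fill one patient's matrix; returns (T, F) with no missing entries."""
    out = rec_values.copy()
    for j, name in enumerate(schema.feature_names):
        col = rec_values[:, j]
        mask = rec_mask[:, j]
        if schema.is_categorical(name):
            out[:, j] = np.where(mask, col, modes[name])
            continue
        mode = config.imputation.get(schema.groups[name], "mean")
        if not mask.any():
            out[:, j] = raw_stats[name]["mean"]
        elif mode == "forward_fill":
            out[:, j] = impute_time_series(col, mask, name)
        else:
            out[:, j] = impute_mean(col, mask, name)
    return out


def fit(cohort_train: Cohort, config: PreprocessConfig | None = None) -> FittedPreprocessor:
    """Learn per-feature statistics from the training split only."""
    config = config or PreprocessConfig()
    schema = cohort_train.schema

    raw_stats: dict = {}
    category_maps: dict = {}
    modes: dict = {}
    for j, name in enumerate(schema.feature_names):
        observed = np.concatenate(
            [r.values[r.observed_mask[:, j], j] for r in cohort_train.records]
        ) if cohort_train.records else np.array([])
        if schema.is_categorical(name):
            order = schema.categorical[name]
            category_maps[name] = {c: i for i, c in enumerate(order)}
            if observed.size:
                codes, counts = np.unique(observed.astype(int), return_counts=True)
                modes[name] = int(codes[np.argmax(counts)])
            else:
                modes[name] = 0
            continue
        if observed.size == 0:
            raise ImputationError(
                f"feature {name!r}: no observed value anywhere in the training split"
            )
        raw_stats[name] = {
            "mean": float(observed.mean()),
            "std": _std(observed, config.std_convention),
        }

    # scaling statistics come from the imputed + outlier-handled training
    # matrix so the training-split moment/range contract holds exactly
    pooled: dict[str, list] = {name: [] for name in schema.numeric_features()}
    for rec in cohort_train.records:
        filled = _impute_record(
            rec.values, rec.observed_mask, schema, config, raw_stats, modes
        )
        for name in schema.numeric_features():
            j = schema.index_of(name)
            col, _ = outlier_transform(
                filled[:, j],
                raw_stats[name]["mean"],
                raw_stats[name]["std"],
                config.outlier_threshold,
                "cap" if config.outlier_policy == "remove" else config.outlier_policy,
            )
            pooled[name].append(col)

    scale_stats: dict = {}
    for name, cols in pooled.items():
        col = np.concatenate(cols) if cols else np.array([0.0])
        scale_stats[name] = {
            "mean": float(col.mean()),
            "std": _std(col, config.std_convention),
            "min": float(col.min()),
            "max": float(col.max()),
        }
    return FittedPreprocessor(
        schema=schema,
        config=config,
        raw_stats=raw_stats,
        scale_stats=scale_stats,
        category_maps=category_maps,
        modes=modes,
    )


def transform(cohort: Cohort, fitted: FittedPreprocessor) -> NumericCohort:
    """Apply the fitted pipeline: impute -> outlier policy -> scale -> encode.

    Deterministic; the output has no missing entries.  Under the ``remove``
    policy, removed outliers are re-imputed with the training mean before
    scaling.
    """
    schema = fitted.schema
    config = fitted.config
    out_names = fitted.output_feature_names()
    patients: list[NumericPatient] = []
    for rec in cohort.records:
        filled = _impute_record(
            rec.values, rec.observed_mask, schema, config, fitted.raw_stats, fitted.modes
        )
        columns: list[np.ndarray] = []
        for name in schema.feature_names:
            j = schema.index_of(name)
            if schema.is_categorical(name):
                order = schema.categorical[name]
                codes = filled[:, j].astype(int)
                if config.categorical_encoding == "one_hot":
                    block = np.zeros((len(codes), len(order)))
                    block[np.arange(len(codes)), codes] = 1.0
                    columns.append(block)
                else:
                    columns.append(codes.astype(float)[:, None])
                continue
            stats = fitted.raw_stats[name]
            col, _ = outlier_transform(
                filled[:, j],
                stats["mean"],
                stats["std"],
                config.outlier_threshold,
                config.outlier_policy,
            )
            if config.outlier_policy == "remove":
                col = np.where(np.isnan(col), stats["mean"], col)
            sstats = fitted.scale_stats[name]
            if config.scaling == "minmax":
                col = minmax_scale(col, sstats["min"], sstats["max"])
            else:
                col = zscore_standardize(col, sstats["mean"], sstats["std"])
            columns.append(col[:, None])
        patients.append(
            NumericPatient(
                patient_id=rec.patient_id,
                times=rec.times.copy(),
                values=np.hstack(columns),
                labels=rec.labels.copy(),
            )
        )
    return NumericCohort(feature_names=out_names, patients=patients)
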
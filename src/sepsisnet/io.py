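"""Reading and writing cohort tables, and the run-configuration file.

Tables are plain delimited text (comma by default, pipe supported — the
PhysioNet-style exports of the same data circulate as ``.psv``) with a single
header row and one row per patient-hour.  Cells matching a missing token
(default: empty string, ``NaN``, ``NA``) are recorded as unobserved in the
mask; their stored magnitude is 0 and is never used downstream.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, FeatureSchema, PatientRecord
from .errors import ConfigError, SchemaError, ValidationError

DEFAULT_MISSING_TOKENS = ("", "NaN", "NA")


def _parse_feature_column(raw: pd.Series, name: str, schema: FeatureSchema):
    """Return (values, observed) float/bool arrays for one feature column."""
    observed = raw.notna().to_numpy()
    values = np.zeros(len(raw), dtype=float)
    if schema.is_categorical(name):
        order = schema.categorical[name]
        for i, cell in enumerate(raw):
            if not observed[i]:
                continue
            cell = str(cell).strip()
            if cell in order:
                values[i] = order.index(cell)
                continue
            try:
                code = float(cell)
            except ValueError:
                raise ValidationError(
                    f"column {name!r}, row {i}: {cell!r} is neither a "
                    f"declared category of {order} nor a numeric code"
                ) from None
            if not (code.is_integer() and 0 <= code < len(order)):
                raise ValidationError(
                    f"column {name!r}, row {i}: code {cell!r} outside the "
                    f"declared {len(order)} categories"
                )
            values[i] = code
    else:
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = observed & numeric.isna().to_numpy()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"column {name!r}, row {row}: non-numeric value {raw.iloc[row]!r}"
            )
        values[observed] = numeric.to_numpy(dtype=float)[observed]
    return values, observed


def read_cohort(
    path,
    schema: FeatureSchema,
    delimiter: str = ",",
    missing_tokens=DEFAULT_MISSING_TOKENS,
) -> Cohort:
    """Parse a per-patient-hour table into a :class:`Cohort`.

    One :class:`PatientRecord` is built per distinct id, rows sorted by the
    in-stay hour.  Duplicate (id, time) rows keep the first occurrence and
    emit a warning.
    """
    df = pd.read_csv(
        path,
        sep=delimiter,
        na_values=list(missing_tokens),
        keep_default_na=False,
        dtype=str,
        skipinitialspace=True,
    )
    missing_cols = [c for c in schema.columns() if c not in df.columns]
    if missing_cols:
        raise SchemaError(
            f"required column(s) missing from {path}: {missing_cols} "
            f"(found {list(df.columns)})"
        )

    ids = df[schema.id_column].astype(str)
    times = pd.to_numeric(df[schema.time_column], errors="coerce")
    if times.isna().any():
        row = int(times.isna().idxmax())
        raise ValidationError(f"row {row}: unparseable time value")
    labels_raw = pd.to_numeric(df[schema.label_column], errors="coerce")
    bad_label = labels_raw.isna() | ~labels_raw.isin((0, 1))
    if bad_label.any():
        row = int(bad_label.idxmax())
        raise ValidationError(
            f"row {row}: label {df[schema.label_column].iloc[row]!r} is not binary"
        )

    value_cols = {}
    for name in schema.feature_names:
        value_cols[name] = _parse_feature_column(df[name], name, schema)

    records = []
    for pid in ids.unique():
        sel = np.flatnonzero((ids == pid).to_numpy())
        order = sel[np.argsort(times.to_numpy()[sel], kind="stable")]
        t = times.to_numpy()[order]
        keep = np.ones(len(order), dtype=bool)
        if len(t) > 1:
            dup = np.diff(t) == 0
            if dup.any():
                warnings.warn(
                    f"patient {pid}: duplicate time rows dropped (kept first)",
                    stacklevel=2,
                )
                keep[1:][dup] = False
        order = order[keep]
        values = np.column_stack([value_cols[n][0][order] for n in schema.feature_names])
        mask = np.column_stack([value_cols[n][1][order] for n in schema.feature_names])
        records.append(
            PatientRecord(
                patient_id=str(pid),
                times=times.to_numpy()[order],
                values=values,
                observed_mask=mask,
                labels=labels_raw.to_numpy()[order].astype(int),
            )
        )
    return Cohort(schema, records)


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write a cohort as a single delimited table (inverse of read_cohort).

    Unobserved cells are written as empty strings; categorical cells are
    written as their category names.
    """
    schema = cohort.schema
    rows = []
    for rec in cohort.records:
        for t in range(rec.n_timesteps):
            row = {
                schema.id_column: rec.patient_id,
                schema.time_column: _fmt_time(rec.times[t]),
                schema.label_column: int(rec.labels[t]),
            }
            for j, name in enumerate(schema.feature_names):
                if not rec.observed_mask[t, j]:
                    row[name] = ""
                elif schema.is_categorical(name):
                    row[name] = schema.categorical[name][int(rec.values[t, j])]
                else:
                    row[name] = repr(float(rec.values[t, j]))
            rows.append(row)
    df = pd.DataFrame(rows, columns=schema.columns())
    df.to_csv(path, sep=delimiter, index=False)


def _fmt_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else repr(float(t))


# --- run configuration -------------------------------------------------------

#: Documented configuration keys, their target bundle, and a validator.
_KNOWN_KEYS: dict[str, tuple[str, str]] = {
    # training
    "learning_rate": ("train", "learning_rate"),
    "batch_size": ("train", "batch_size"),
    "dropout": ("train", "dropout"),
    "max_epochs": ("train", "max_epochs"),
    "patience": ("train", "patience"),
    "threshold": ("train", "threshold"),
    "seed": ("train", "seed"),
    # model architecture
    "window_length": ("model", "window_length"),
    "entry_filters": ("model", "entry_filters"),
    "branch_filters": ("model", "branch_filters"),
    "branch_kernels": ("model", "branch_kernels"),
    "spatial_kernel": ("model", "spatial_kernel"),
    "channel_bottleneck": ("model", "channel_bottleneck"),
    "hdcb_filters": ("model", "hdcb_filters"),
    "hdcb_dilations": ("model", "hdcb_dilations"),
    "hdcb_fusion": ("model", "hdcb_fusion"),
    "fusion_filters": ("model", "fusion_filters"),
    "rpcc_filters": ("model", "rpcc_filters"),
    "rpcc_blocks": ("model", "rpcc_blocks"),
    "dense_units": ("model", "dense_units"),
    "bn_form": ("model", "bn_form"),
    # preprocessing
    "scaling": ("preprocess", "scaling"),
    "outlier_threshold": ("preprocess", "outlier_threshold"),
    "outlier_policy": ("preprocess", "outlier_policy"),
    "std_convention": ("preprocess", "std_convention"),
    "categorical_encoding": ("preprocess", "categorical_encoding"),
    # io
    "delimiter": ("io", "delimiter"),
}


def load_config(path) -> dict:
    """Load a flat ``key: value`` configuration file.

    Returns a dict with sub-dicts ``train``, ``model``, ``preprocess``,
    ``io`` holding only the keys the file overrides; downstream dataclasses
    fill in the published defaults (learning rate 0.001, batch size 128,
    dropout 0.5, 100-epoch cap, ...).  Unknown keys and out-of-range values
    raise :class:`ConfigError` naming the offending key.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a flat key: value mapping")
    out: dict[str, dict] = {"train": {}, "model": {}, "preprocess": {}, "io": {}}
    for key, value in raw.items():
        if key not in _KNOWN_KEYS:
            raise ConfigError(f"unknown configuration key {key!r}")
        section, fieldname = _KNOWN_KEYS[key]
        _validate_config_value(key, value)
        if isinstance(value, list):
            value = tuple(value)
        out[section][fieldname] = value
    return out


def _validate_config_value(key: str, value) -> None:
    if key == "dropout" and not (0 <= value < 1):
        raise ConfigError(f"dropout must be in [0, 1), got {value}")
    if key == "learning_rate" and not value > 0:
        raise ConfigError(f"learning_rate must be positive, got {value}")
    if key in ("batch_size", "max_epochs", "patience", "window_length") and (
        not isinstance(value, int) or value < 1
    ):
        raise ConfigError(f"{key} must be a positive integer, got {value}")
    if key == "outlier_threshold" and not value > 0:
        raise ConfigError(f"outlier_threshold must be > 0, got {value}")
    if key == "hdcb_fusion" and value not in ("concat", "sum"):
        raise ConfigError(f"hdcb_fusion must be 'concat' or 'sum', got {value!r}")
    if key == "scaling" and value not in ("minmax", "zscore"):
        raise ConfigError(f"scaling must be 'minmax' or 'zscore', got {value!r}")
    if key == "outlier_policy" and value not in ("cap", "remove", "flag"):
        raise ConfigError(f"outlier_policy must be cap/remove/flag, got {value!r}")
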
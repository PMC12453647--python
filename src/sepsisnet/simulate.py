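"""Synthetic ICU sepsis cohorts in the public dataset's per-patient-hour layout.

The generator emulates the structural properties of the real cohorts used for
early sepsis warning — hourly vitals with temporal autocorrelation, sparsely
observed labs, static demographics, heavy class imbalance (~1.8% of
patient-hours positive), and a per-patient onset after which the label stays
1 — without attempting to reproduce the real data's marginal distributions.

Vitals and labs follow a stationary AR(1) process around a physiologic
baseline, x_t = mu + rho (x_{t-1} - mu) + e_t with e_t scaled so the marginal
standard deviation matches the configured per-feature sd.  Septic patients
receive an onset hour uniform in the second half of the stay and a linear
pre-onset drift (tachycardia, fever, tachypnoea, falling MAP, rising WBC and
lactate) that is sustained after onset — the planted signal the classifier
is expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import DEMOGRAPHIC, LAB, VITAL, Cohort, FeatureSchema, PatientRecord

#: Record / patient / positive counts of the reference cohort the generator
#: is shaped after (used by :func:`simulate_paper_scale`).
REFERENCE_RECORDS = 1_552_210
REFERENCE_PATIENTS = 40_336
REFERENCE_POSITIVES = 27_916

_DEFAULT_BASELINES = {
    # feature: (mean, sd) — textbook adult ICU magnitudes
    "HR": (85.0, 10.0),
    "O2Sat": (97.0, 1.5),
    "Temp": (36.8, 0.4),
    "SBP": (120.0, 12.0),
    "MAP": (82.0, 8.0),
    "DBP": (65.0, 8.0),
    "Resp": (18.0, 3.0),
    "WBC": (8.0, 2.0),
    "Lactate": (1.2, 0.4),
    "Creatinine": (1.0, 0.3),
    "Platelets": (250.0, 50.0),
}

_DEFAULT_DRIFT = {
    # total shift reached at onset, ramped linearly over the drift window
    "HR": 20.0,
    "Temp": 1.2,
    "Resp": 8.0,
    "MAP": -15.0,
    "WBC": 6.0,
    "Lactate": 2.5,
}


def default_schema() -> FeatureSchema:
    """Schema of the simulated cohort: 7 vitals, 4 labs, age and gender."""
    vitals = ["HR", "O2Sat", "Temp", "SBP", "MAP", "DBP", "Resp"]
    labs = ["WBC", "Lactate", "Creatinine", "Platelets"]
    demo = ["Age", "Gender"]
    groups = {f: VITAL for f in vitals}
    groups.update({f: LAB for f in labs})
    groups.update({f: DEMOGRAPHIC for f in demo})
    return FeatureSchema(
        feature_names=tuple(vitals + labs + demo),
        groups=groups,
        categorical={"Gender": ("Male", "Female")},
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort.

    ``sepsis_probability`` (patient-level) defaults to the value that makes
    the expected patient-hour prevalence equal ``target_prevalence``
    (~27,916/1,552,210 = 1.8%), computed analytically from the stay-length
    and onset distributions by :func:`calibrate_sepsis_probability`.
    """

    n_patients: int = 1000
    stay_hours: tuple[int, int] = (8, 60)       # integer uniform, inclusive
    target_prevalence: float = REFERENCE_POSITIVES / REFERENCE_RECORDS
    sepsis_probability: float | None = None     # None -> calibrated
    rho: float = 0.9                            # AR(1) coefficient for vitals/labs
    baselines: dict = field(default_factory=lambda: dict(_DEFAULT_BASELINES))
    drift: dict = field(default_factory=lambda: dict(_DEFAULT_DRIFT))
    drift_window: int = 12                      # hours of pre-onset ramp
    lab_missing_rate: float = 0.85
    vital_missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.stay_hours
        if lo < 2 or hi < lo:
            raise ValueError("stay lengths must be >= 2 with lo <= hi")
        if not (0 <= self.rho < 1):
            raise ValueError("AR(1) coefficient rho must lie in [0, 1)")
        for name, p in (
            ("target_prevalence", self.target_prevalence),
            ("lab_missing_rate", self.lab_missing_rate),
            ("vital_missing_rate", self.vital_missing_rate),
        ):
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.sepsis_probability is not None and not (
            0 <= self.sepsis_probability <= 1
        ):
            raise ValueError("sepsis_probability must lie in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    def resolved_sepsis_probability(self) -> float:
        if self.sepsis_probability is not None:
            return self.sepsis_probability
        return calibrate_sepsis_probability(self.stay_hours, self.target_prevalence)


def calibrate_sepsis_probability(stay_hours: tuple[int, int], target: float) -> float:
    """Patient-level sepsis probability yielding the target hour prevalence.

    With stay length L uniform on [lo, hi] and onset uniform on the integer
    hours of the second half of the stay, the expected number of positive
    hours per septic patient is E[L - onset]; dividing the target hour
    prevalence by E[positives] / E[L] gives the patient-level probability.
    """
    lengths = np.arange(stay_hours[0], stay_hours[1] + 1)
    exp_pos = np.array([(L - np.arange(L // 2, L)).mean() for L in lengths])
    fraction = exp_pos.sum() / lengths.sum()
    return float(min(1.0, target / fraction))


def _ar1(rng, mu, sd, rho, length):
    """Stationary AR(1) path with marginal mean mu and sd sd."""
    x = np.empty(length)
    x[0] = rng.normal(mu, sd)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    noise = rng.normal(0.0, innov_sd, size=length - 1)
    for t in range(1, length):
        x[t] = mu + rho * (x[t - 1] - mu) + noise[t - 1]
    return x


def simulate_cohort(config: SimConfig | None = None) -> Cohort:
    """Draw a fully reproducible synthetic cohort from the configuration."""
    config = config or SimConfig()
    schema = default_schema()
    rng = np.random.default_rng(config.seed)
    p_sepsis = config.resolved_sepsis_probability()
    records = []
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        L = int(rng.integers(config.stay_hours[0], config.stay_hours[1] + 1))
        septic = rng.random() < p_sepsis
        onset = int(rng.integers(L // 2, L)) if septic else None

        values = np.zeros((L, schema.n_features))
        mask = np.ones((L, schema.n_features), dtype=bool)
        hours = np.arange(L, dtype=float)
        for j, name in enumerate(schema.feature_names):
            group = schema.groups[name]
            if name == "Age":
                values[:, j] = float(np.clip(rng.normal(62, 15), 18, 100))
                continue
            if name == "Gender":
                values[:, j] = float(rng.integers(0, 2))
                continue
            mu, sd = config.baselines[name]
            x = _ar1(rng, mu, sd, config.rho, L)
            if septic:
                mag = config.drift.get(name, 0.0)
                if mag:
                    ramp = np.clip(
                        1.0 - (onset - hours) / max(config.drift_window, 1), 0.0, 1.0
                    )
                    x = x + mag * ramp
            values[:, j] = x
            miss = (
                config.vital_missing_rate if group == VITAL else config.lab_missing_rate
            )
            mask[:, j] = rng.random(L) >= miss

        labels = np.zeros(L, dtype=int)
        if septic:
            labels[onset:] = 1
        records.append(
            PatientRecord(
                patient_id=pid,
                times=hours,
                values=values,
                observed_mask=mask,
                labels=labels,
            )
        )
    return Cohort(schema, records)


def simulate_paper_scale(scale_fraction: float, seed: int = 0):
    """Cohort shaped like the reference one, scaled down by ``scale_fraction``.

    At ``scale_fraction = 1`` the expected record count is ~1,552,210 from
    40,336 patients with ~27,916 positive hours.  Returns ``(cohort, report)``
    where the report compares expected and realized counts.
    """
    if not (0 < scale_fraction <= 1):
        raise ValueError("scale_fraction must lie in (0, 1]")
    n_patients = max(1, round(scale_fraction * REFERENCE_PATIENTS))
    # stay uniform on [17, 60]: mean 38.5 ~ 1,552,210 / 40,336 hours/patient
    config = SimConfig(n_patients=n_patients, stay_hours=(17, 60), seed=seed)
    cohort = simulate_cohort(config)
    report = {
        "n_patients": n_patients,
        "expected_records": scale_fraction * REFERENCE_RECORDS,
        "realized_records": cohort.n_timesteps,
        "expected_positives": scale_fraction * REFERENCE_POSITIVES,
        "realized_positives": cohort.n_positive,
    }
    return cohort, report


def separability_report(cohort: Cohort, window: int = 12) -> dict[str, float]:
    """Standardized mean difference of each numeric feature, septic pre-onset
    window vs matched windows from non-septic patients.

    Used to assert that the planted physiological drift actually exists in a
    generated cohort (all ~0 when drift magnitudes are zero).
    """
    schema = cohort.schema
    septic_rows = []
    control_rows = []
    for rec in cohort.records:
        pos = np.flatnonzero(rec.labels)
        if pos.size:
            onset = int(pos[0])
            lo = max(0, onset - window)
            septic_rows.append(rec.values[lo : onset + 1])
        else:
            take = min(window + 1, rec.n_timesteps)
            start = (rec.n_timesteps - take) // 2
            control_rows.append(rec.values[start : start + take])
    out: dict[str, float] = {}
    if not septic_rows or not control_rows:
        return {f: 0.0 for f in schema.numeric_features()}
    sep = np.vstack(septic_rows)
    con = np.vstack(control_rows)
    for name in schema.numeric_features():
        j = schema.index_of(name)
        pooled_sd = np.sqrt((sep[:, j].var() + con[:, j].var()) / 2.0)
        out[name] = (
            float((sep[:, j].mean() - con[:, j].mean()) / pooled_sd)
            if pooled_sd > 0
            else 0.0
        )
    return out
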
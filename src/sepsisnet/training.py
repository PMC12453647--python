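"""Patient-wise splitting, the training loop, cross-validation and ablations.

Splits are always patient-wise: every record of a patient lands in exactly
one partition, so no patient identity leaks between train, validation and
test.  Training uses Adam with binary cross-entropy on the sigmoid output,
early stopping on validation loss with best-weight restoration, and the
published defaults (learning rate 0.001, batch size 128, dropout 0.5, at
most 100 epochs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .cohort import Cohort
from .metrics import MetricsReport, compute_metrics, confusion_counts, roc_auc
from .model import ModelConfig, SepsisNet, WindowDataset, build_model, tensorize_windows
from .nn.autodiff import bce_with_logits
from .nn.layers import Adam
from .preprocessing import NumericCohort, PreprocessConfig, fit as fit_preprocessor, transform

__all__ = [
    "TrainConfig",
    "SplitAssignment",
    "compute_split_sizes",
    "patient_wise_split",
    "split_kfold",
    "prepare_windows",
    "train",
    "evaluate",
    "kfold_cv",
    "run_ablation",
    "ABLATION_VARIANTS",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 128
    dropout: float = 0.5
    max_epochs: int = 100
    patience: int = 10
    threshold: float = 0.5
    pos_weight: float = 1.0          # optional positive-class weighting (off)
    max_train_batches: int | None = None  # per-epoch cap for desk-scale runs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("batch size, epochs and patience must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class SplitAssignment:
    """Partition label per patient plus the fractions and seed that made it."""

    assignment: dict[str, str]  # patient id -> "train" | "val" | "test"
    fractions: tuple[float, ...]
    seed: int

    def patients(self, partition: str) -> list[str]:
        return [pid for pid, part in self.assignment.items() if part == partition]


def compute_split_sizes(total_records: int, fractions) -> tuple[int, ...]:
    """Round each partition to the nearest record count; the remainder is
    assigned to the first (training) partition so the counts sum exactly."""
    sizes = [round(f * total_records) for f in fractions]
    sizes[0] += total_records - sum(sizes)
    return tuple(int(s) for s in sizes)


_PARTS = ("train", "val", "test")


def patient_wise_split(
    cohort: Cohort, fractions=(0.8, 0.1, 0.1), seed: int = 0
) -> SplitAssignment:
    """Assign whole patients to partitions, targeting record fractions.

    Patients are shuffled by the seed and assigned greedily to the partition
    with the largest remaining record deficit, which keeps realized record
    fractions within ~2 percentage points of the targets.
    """
    if len(fractions) != 3 or not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must be three values summing to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort.records))
    targets = np.array(fractions, dtype=float) * cohort.n_timesteps
    filled = np.zeros(3)
    assignment: dict[str, str] = {}
    for idx in order:
        rec = cohort.records[idx]
        deficit = targets - filled
        part = int(np.argmax(deficit))
        assignment[rec.patient_id] = _PARTS[part]
        filled[part] += rec.n_timesteps
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)


def split_kfold(cohort: Cohort, k: int, seed: int = 0) -> list[list[str]]:
    """Patient-wise folds, near-equal in patient count and stratified by
    patient-level sepsis occurrence.  Returns k lists of patient ids."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    septic = [r.patient_id for r in cohort.records if r.labels.any()]
    healthy = [r.patient_id for r in cohort.records if not r.labels.any()]
    folds: list[list[str]] = [[] for _ in range(k)]
    cursor = 0  # carried across strata so fold sizes stay near-equal
    for group in (septic, healthy):
        order = rng.permutation(len(group))
        for idx in order:
            folds[cursor % k].append(group[idx])
            cursor += 1
    return folds


def prepare_windows(cohort: NumericCohort, model_config: ModelConfig) -> WindowDataset:
    """Tensorize an already-preprocessed cohort with the configured window."""
    return tensorize_windows(cohort, model_config.window_length)


def _epoch_batches(n: int, batch_size: int, rng, max_batches=None):
    order = rng.permutation(n)
    batches = [order[i : i + batch_size] for i in range(0, n, batch_size)]
    if max_batches is not None and len(batches) > max_batches:
        batches = batches[:max_batches]
    return batches


def _dataset_loss(
    model: SepsisNet, data: WindowDataset, config: TrainConfig, max_batches=None
):
    """Evaluation-mode loss and accuracy over a dataset (optionally estimated
    on the first ``max_batches`` batches when a per-epoch cap is set)."""
    limit = (
        len(data)
        if max_batches is None
        else min(len(data), max_batches * config.batch_size)
    )
    model.eval()
    losses = []
    correct = 0
    for i in range(0, limit, config.batch_size):
        xb = data.X[i : i + config.batch_size]
        yb = data.y[i : i + config.batch_size]
        logits = model.forward_logits(xb)
        loss = bce_with_logits(logits, yb, pos_weight=config.pos_weight)
        losses.append(loss.item() * len(yb))
        probs = expit(logits.data.reshape(-1))
        correct += int(np.sum((probs >= config.threshold) == (yb == 1)))
    model.train()
    n = limit
    return sum(losses) / n, correct / n


def train(
    model: SepsisNet,
    train_data: WindowDataset,
    val_data: WindowDataset,
    config: TrainConfig | None = None,
):
    """Train with Adam + early stopping; returns (model, history).

    History holds per-epoch train/val loss and accuracy (aligned lengths =
    epochs actually run).  Early stopping triggers after ``patience`` epochs
    without validation-loss improvement and restores the best weights.
    """
    config = config or TrainConfig()
    if len(train_data) == 0:
        raise ValueError("training partition is empty")
    if len(val_data) == 0:
        raise ValueError("validation partition is empty")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    best_val = np.inf
    best_state = model.state_dict()
    epochs_since_best = 0

    model.train()
    for _ in range(config.max_epochs):
        for batch_idx in _epoch_batches(
            len(train_data), config.batch_size, rng, config.max_train_batches
        ):
            xb = train_data.X[batch_idx]
            yb = train_data.y[batch_idx]
            model.zero_grad()
            loss = bce_with_logits(
                model.forward_logits(xb), yb, pos_weight=config.pos_weight
            )
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite training loss ({loss.item()}); aborting — "
                    f"check the learning rate ({config.learning_rate})"
                )
            loss.backward()
            optimizer.step()

        train_loss, train_acc = _dataset_loss(
            model, train_data, config, config.max_train_batches
        )
        val_loss, val_acc = _dataset_loss(model, val_data, config)
        history["train_loss"].append(train_loss)
        history["train_acc"].append(train_acc)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)

        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break

    model.load_state_dict(best_state)
    model.eval()
    return model, history


def evaluate(
    model: SepsisNet, data: WindowDataset, config: TrainConfig | None = None
) -> MetricsReport:
    """Probabilities -> confusion counts + AUC -> full metric panel."""
    config = config or TrainConfig()
    probs = model.predict_proba(data.X, batch_size=config.batch_size)
    counts = confusion_counts(probs, data.y, config.threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-class folds report NaN AUC
        auc = roc_auc(probs, data.y)
    return compute_metrics(counts, auc)


def _fit_transform(train_cohort: Cohort, eval_cohort: Cohort, pre_config):
    fitted = fit_preprocessor(train_cohort, pre_config)
    return transform(train_cohort, fitted), transform(eval_cohort, fitted), fitted


def kfold_cv(
    cohort: Cohort,
    k: int = 6,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    pre_config: PreprocessConfig | None = None,
    seed: int = 0,
):
    """Patient-wise k-fold cross-validation.

    Each fold serves as validation exactly once; preprocessing is refitted
    on each fold's training patients.  Returns ``(reports, summary)`` where
    summary maps metric -> (mean, population sd) in percent.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    folds = split_kfold(cohort, k, seed)
    reports: list[MetricsReport] = []
    for i, fold_ids in enumerate(folds):
        val_cohort = cohort.subset(fold_ids)
        train_ids = [pid for j, fold in enumerate(folds) if j != i for pid in fold]
        train_cohort = cohort.subset(train_ids)
        train_num, val_num, _ = _fit_transform(train_cohort, val_cohort, pre_config)
        train_data = prepare_windows(train_num, model_config)
        val_data = prepare_windows(val_num, model_config)
        model = build_model(replace(model_config, seed=model_config.seed + i))
        model, _ = train(model, train_data, val_data, train_config)
        reports.append(evaluate(model, val_data, train_config))
    summary = summarize_reports(reports)
    return reports, summary


def summarize_reports(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Mean and population standard deviation per metric across folds."""
    out: dict[str, tuple[float, float]] = {}
    for key in ("accuracy", "precision", "recall", "f1", "specificity", "fpr",
                "fnr", "auc"):
        values = np.array([getattr(r, key) for r in reports], dtype=float)
        valid = values[~np.isnan(values)]
        if valid.size:
            out[key] = (float(valid.mean()), float(valid.std()))
        else:
            out[key] = (float("nan"), float("nan"))
    return out


ABLATION_VARIANTS = (
    "full",
    "without_SCAN",
    "without_HDCB",
    "without_RPCC",
    "without_ECLF",
)

_VARIANT_TO_BLOCK = {
    "without_SCAN": "scan",
    "without_HDCB": "hdcb",
    "without_RPCC": "rpcc",
    "without_ECLF": "eclf",
}


def ablation_config(model_config: ModelConfig, variant: str) -> ModelConfig:
    """Model configuration for an ablation variant (identity bypass with a
    1x1 channel adapter in place of the removed block)."""
    if variant == "full":
        return model_config
    if variant not in _VARIANT_TO_BLOCK:
        raise ValueError(f"unknown ablation variant {variant!r}")
    return replace(model_config, disabled_blocks=(_VARIANT_TO_BLOCK[variant],))


def run_ablation(
    cohort: Cohort,
    variants=ABLATION_VARIANTS,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    pre_config: PreprocessConfig | None = None,
    seed: int = 0,
) -> dict[str, MetricsReport]:
    """Train and evaluate every variant under identical data, seeds and
    budget; returns variant -> MetricsReport (validation partition)."""
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    split = patient_wise_split(cohort, seed=seed)
    train_cohort = cohort.subset(split.patients("train"))
    val_cohort = cohort.subset(split.patients("val"))
    train_num, val_num, _ = _fit_transform(train_cohort, val_cohort, pre_config)
    train_data = prepare_windows(train_num, model_config)
    val_data = prepare_windows(val_num, model_config)
    results: dict[str, MetricsReport] = {}
    for variant in variants:
        model = build_model(ablation_config(model_config, variant))
        model, _ = train(model, train_data, val_data, train_config)
        results[variant] = evaluate(model, val_data, train_config)
    return results
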
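# Methods

## Problem and data model

The package classifies each recorded patient-hour of an ICU stay as septic
or not. Input tables have one row per patient-hour: a patient id, an
in-stay hour counter (ICULOS), vital signs (HR, O2Sat, Temp, SBP, MAP,
DBP, Resp, ...), laboratory values (WBC, lactate, creatinine, platelets,
...), demographics (age, gender), and a binary `SepsisLabel` that switches
to 1 at onset and stays 1 to discharge. Internally a cohort is a set of
`PatientRecord`s — a dense float matrix plus a boolean observation mask —
because most lab cells are simply never measured and imputation must be an
explicit, fitted step rather than a property of the file format.

## Preprocessing

All statistics are learned from the **training split only** and frozen in a
`FittedPreprocessor`; validation and test data are transformed with the
training statistics. This is the same no-leakage principle as the
patient-wise split: a model must not see even the marginal distribution of
held-out patients.

Order of operations: **impute → outlier policy → scale**, with categorical
features encoded at the end. The order is a package decision (the
operations are individually standard but their composition is not forced by
anything): imputing first makes the outlier pass total, and scaling last
makes the scaled moment contract exact.

* Imputation routes by feature group: time-varying features (vitals, labs)
  carry the previous observation forward and back-fill leading gaps, with
  the training mean as fallback for a patient with no observation at all;
  static demographics use the training mean (numeric) or mode (categorical).
* Outliers are scored by Z_i = (x_i − μ_x)/σ_x with μ, σ from observed raw
  training values; |Z| > 3 is flagged. The default policy caps at
  μ ± 3σ (sign-matching); `remove` (re-imputed with the training mean) and
  `flag` are available. Capping can only shrink |Z|, which is asserted as a
  property test.
* Scaling is z-score by default (min-max available). The scaling statistics
  are computed from the imputed-and-capped training matrix, so the z-scored
  training output has mean 0 and sd 1 exactly, and min-max training output
  lies in [0, 1] exactly; held-out data may fall outside these ranges.
  The standard deviation is the population form (÷N) by default, matching
  the batch-normalization convention used in the network; the sample form
  is a config toggle.
* One-hot columns follow the schema's declared category order (e.g.
  [Male, Female, Other] → unit vectors in that order), not alphabetical
  order, and are not rescaled.

## Synthetic cohorts

The generator reproduces the *structure* of the public sepsis tables, not
their marginal distributions:

* Stay lengths are integer uniform 8–60 h (17–60 h for the
  reference-shaped cohort, whose mean stay of 38.5 h reproduces the
  published count of ~1.55M records from 40,336 patients).
* Vitals and labs follow a stationary AR(1) process
  x_t = μ + ρ(x_{t−1} − μ) + ε_t with ρ = 0.9 and innovation variance
  chosen so the marginal sd matches the configured per-feature sd. The
  baselines (HR 85±10 bpm, Temp 36.8±0.4 °C, MAP 82±8 mmHg, Resp 18±3
  /min, WBC 8±2 ×10⁹/L, Lactate 1.2±0.4 mmol/L, ...) are textbook adult
  ICU magnitudes; they are package choices, documented as such.
* Septic patients (onset uniform over the second half of the stay) receive
  a linear pre-onset drift over a 12 h window, sustained after onset:
  HR +20, Temp +1.2, Resp +8, MAP −15, WBC +6, Lactate +2.5. These
  magnitudes make the task clearly learnable (standardized mean differences
  ~0.8–1.9) without being degenerate.
* The patient-level sepsis probability is calibrated **analytically** from
  the stay-length and onset distributions so expected patient-hour
  prevalence equals the target 27,916/1,552,210 ≈ 1.8%; at 5,000 patients
  the realized prevalence lands within ±0.5 pp.
* Labs are observed with probability 0.15, vitals 0.95, demographics always.

What passing tests on this cohort do **not** show: robustness to the real
data's non-Gaussian marginals, inter-feature correlation structure,
informative missingness (labs ordered *because* the patient deteriorates),
or distribution shift between sites. The generator is a test harness, not a
claim about physiology.

## Network

Each sample is the window of the T most recent preprocessed hourly rows
ending at a patient-hour, shaped T×F×1 (T = 8 by default), zero-padded at
the top early in the stay, labelled by the final hour. Treating the
time-feature plane as a 2-D map is the package's tensorization choice — it
is what makes 2-D convolutions, 2×2 pooling and 7×7 attention kernels
meaningful on tabular clinical data — and it is deliberately configurable,
since per-row reshaping is an equally defensible reading.

Pipeline (all convolutions stride 1, shape-preserving zero padding except
the single ECLF pool):

1. **ECLF** — entry 3×3 conv (64 filters, dilation 1) → batch norm → ReLU,
   then three parallel branches with kernel sizes 3/5/7 (64 filters each)
   whose outputs are concatenated (192 channels), activated, normalized,
   and 2×2 max-pooled (floor division on odd dims).
2. **SCAN** — spatial attention A = σ(Conv₇ₓ₇(Conv₁ₓ₁(X))) with the 1×1
   conv reducing channels to max(C/8, 1) and the 7×7 conv producing a
   single-channel map, multiplied into X with channel broadcast; then
   channel attention from global average pooling through a 64-unit
   bottleneck (FC → ReLU → FC → σ), multiplied with spatial broadcast.
   Both weight sets are strictly in (0, 1), so attention only attenuates.
3. **HDCB** — three parallel 3×3/64-filter convolutions at dilation rates
   1, 2, 3; fusion by concatenation + 1×1 convolution to 128 channels
   (default) or by summation (equal channel counts required), then batch
   norm and ReLU.
4. **RPCC** — N = 2 residual blocks X_k = X_{k−1} + F_k(X_{k−1}) with
   F = Conv 3×3 → BN → ReLU → Conv 3×3 (128 filters); a 1×1 projection
   aligns the skip path when the incoming channel count differs.
5. Global average pooling → dense 512 → ReLU → dropout 0.5 → dense 256 →
   ReLU → dropout 0.5 → one sigmoid unit.

Batch normalization defaults to the form x̂ = (x − μ_B)/(σ_B + ε) — the
standard deviation plus the stabilizer in the denominator — with the
conventional √(var + ε) form available as a toggle; the two agree to ~1e−3
whenever σ_B ≫ ε. Weights are He-initialized (fan-in-scaled Gaussian) from
an explicit seed; evaluation-mode forward is a pure function of weights and
input (running batch-norm statistics, no dropout).

The loss is binary cross-entropy on the sigmoid output, computed stably
from logits, with an optional positive-class weight that is off by default.
Training uses Adam (lr 0.001), batch size 128, dropout 0.5, at most 100
epochs, early stopping on validation loss with patience 10 and best-weight
restoration; the decision threshold is 0.5. All of these are configurable.

### Autodiff engine

No deep-learning framework is part of the dependency set; the network runs
on a small reverse-mode autodiff engine over NumPy arrays
(`sepsisnet.nn.autodiff`) with exactly the operations the model needs.
Convolution accumulates one BLAS matmul per kernel tap rather than
materializing an im2col buffer — at these map sizes memory traffic, not
arithmetic, dominates. Gradients of every operation are checked against
central finite differences in the test suite. The sigmoid clamps its output
to the open interval (0, 1) at machine precision so the attention and
probability contracts survive saturated logits.

## AVOA

The vulture optimizer evolves a population of candidate positions in a
box (minimization convention): each iteration evaluates every candidate,
tracks the best-so-far, then moves each candidate either by a uniform
random step (probability = exploration radius; step bounded by
step_size × range per dimension) or by a pull of strength
exploitation_factor toward the best; with probability reproduction_rate a
candidate is replaced by breeding_factor × the midpoint of itself and a
random partner; optionally one Gaussian local-search trial per candidate is
accepted only if it improves fitness. Positions are clipped to bounds after
every move. The reproduction loop iterates over the whole population (the
only reading consistent with its per-candidate body). Non-finite fitness
values are penalized with +∞ and a warning. Per-dimension log10 scaling
supports rate-like parameters; the tuning driver searches learning rate in
[1e−4, 1e−1] (log axis) and dropout in [0.1, 0.7], scoring each candidate
by validation loss after a short training run. Deliberately out of scope:
the satiation-rate/Lévy-flight machinery of the fuller published AVOA
variants.

Defaults (population 30, 50 iterations, step 0.1, exploration 0.3,
exploitation 0.7, reproduction 0.2, breeding 1.0, local-search scale 0.01 ×
range) reliably drive the 2-D sphere below 1e−2.

## Evaluation protocol

* Splits are patient-wise (80/10/10 by record count, greedy assignment
  after a seeded shuffle; realized fractions within ~2 pp). Partition
  counts from a total use round-to-nearest with the remainder to train,
  which reproduces the published 1,241,768 / 155,221 / 155,221 from
  1,552,210.
* Metrics are reported in percent at full precision; identities
  specificity + FPR = 100, recall + FNR = 100 and F1 = harmonic mean of
  precision and recall hold at machine precision. Zero-denominator ratios
  are NaN with a warning, never silently 0. AUC is the Mann–Whitney rank
  statistic (ties count half), verified against an O(n²) pairwise oracle.
* Cross-validation folds are patient-wise and stratified by patient-level
  sepsis occurrence.
* Ablation replaces a named block with an identity bypass (a 1×1 channel
  adapter only where the downstream channel contract requires it), keeping
  data, seeds and training budget identical across variants.

## Problem sizes

The published cohort is ~1.55M patient-hours; the package's tests and the
acceptance script run at desk scale as a deliberate choice: synthetic
cohorts of 500–5,000 patients (~17k–170k hours), the `.compact()`
architecture (8-filter entry/branches, 16-filter fusion and residual
chain, 32/16 dense head, ~17.5k parameters) for training runs, a per-epoch
cap of 100 batches, and ≤4 training epochs. The planted signal is strong
enough that validation AUC exceeds 0.95 within these budgets; the
full-width architecture (~1.5M parameters) is exercised structurally
(shapes, parameter accounting, forward contracts) rather than trained in
the test suite.

## Known limitations

* The published headline numbers of the system this package re-implements
  were obtained on the real Kaggle cohort; reproducing them requires that
  external download and a full-scale training run, both outside the test
  suite. Point `sepsisnet train --data` at a local copy for that.
* Reported precision/F1 at 1.8% prevalence are sensitive to the 0.5
  threshold; the AUC is the stable headline number at desk scale.
* The comparison baselines (logistic regression, SVM, random forest, plain
  CNN) and explainability tooling are out of scope.
* CPU-only by design; no GPU kernels.
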
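"""The sepsis-detection network: four composable convolutional blocks.

Input is a sliding time window of preprocessed hourly rows, shaped
``T x F x 1`` (window length x features x one channel), one sample per
patient-hour.  The forward pipeline is

    ECLF -> SCAN -> HDCB -> RPCC -> global average pool -> dense head

* **ECLF** (enhanced convolutional learning framework): an entry 3x3
  convolution, batch norm and ReLU, then three parallel convolution branches
  with increasing kernel sizes whose outputs are concatenated along
  channels, activated, normalized, and 2x2 max-pooled.
* **SCAN** (spatio-channel attention network): a single-channel spatial
  attention map (1x1 channel-reducing conv followed by a 7x7 conv and
  sigmoid) multiplied into the features, then channel attention (global
  average pool through a two-layer bottleneck, sigmoid) — both weight sets
  lie strictly in (0, 1), so attention can only attenuate.
* **HDCB** (hierarchical dilated convolutional block): three parallel 3x3
  convolutions at dilation rates 1, 2, 3, fused by concatenation and a 1x1
  convolution (or by summation), then batch norm and ReLU.
* **RPCC** (residual path convolutional chain): N residual blocks
  ``X_k = X_{k-1} + F_k(X_{k-1})`` with ``F = Conv -> BN -> ReLU -> Conv``
  and a 1x1 projection on the skip path when channel counts differ.

Batch normalization follows the printed form (X - mu_B) / (sigma_B + eps)
by default, with the conventional sqrt(var + eps) form available.

The module also exposes pure-NumPy reference semantics for the two
primitives the architecture is defined by — :func:`dilated_conv` (the
nested-sum dilated convolution) and :func:`batch_norm` — which the layers
are tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nn.autodiff import Tensor, concatenate, maxpool2x2
from .nn.layers import (
    DTYPE,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Identity,
    Module,
    ReLU,
    Sequential,
)
from .preprocessing import NumericCohort

__all__ = [
    "ModelConfig",
    "BatchNormParams",
    "WindowDataset",
    "tensorize_windows",
    "dilated_conv",
    "batch_norm",
    "ECLF",
    "SCAN",
    "HDCB",
    "RPCC",
    "SepsisNet",
    "build_model",
    "forward",
    "count_parameters",
]

BLOCK_NAMES = ("eclf", "scan", "hdcb", "rpcc")


@dataclass(frozen=True)
class ModelConfig:
    """Every architectural hyperparameter, with the published defaults."""

    n_features: int = 14
    window_length: int = 8          # T: hours of history per sample
    entry_filters: int = 64
    branch_filters: int = 64
    branch_kernels: tuple[int, int, int] = (3, 5, 7)
    spatial_kernel: int = 7
    channel_bottleneck: int = 64
    hdcb_filters: int = 64
    hdcb_dilations: tuple[int, ...] = (1, 2, 3)
    hdcb_fusion: str = "concat"     # "concat" (+ 1x1 conv) | "sum"
    fusion_filters: int = 128
    rpcc_filters: int = 128
    rpcc_blocks: int = 2
    dense_units: tuple[int, ...] = (512, 256)
    dropout: float = 0.5
    bn_form: str = "paper"          # "paper" | "variance"
    bn_eps: float = 1e-5
    seed: int = 0
    disabled_blocks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window length T must be >= 2 (pooling needs extent)")
        for name in (
            "n_features",
            "entry_filters",
            "branch_filters",
            "hdcb_filters",
            "fusion_filters",
            "rpcc_filters",
            "rpcc_blocks",
            "channel_bottleneck",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.hdcb_fusion not in ("concat", "sum"):
            raise ValueError("hdcb_fusion must be 'concat' or 'sum'")
        unknown = set(self.disabled_blocks) - set(BLOCK_NAMES)
        if unknown:
            raise ValueError(f"unknown blocks to disable: {sorted(unknown)}")

    def compact(self, **overrides) -> "ModelConfig":
        """A narrow variant of the same architecture for desk-scale runs."""
        base = dict(
            entry_filters=8,
            branch_filters=8,
            channel_bottleneck=8,
            hdcb_filters=8,
            fusion_filters=16,
            rpcc_filters=16,
            rpcc_blocks=1,
            dense_units=(32, 16),
        )
        base.update(overrides)
        return replace(self, **base)


# --- reference functional semantics ------------------------------------------


def dilated_conv(x, kernel, dilation: int = 1, padding: str = "valid"):
    """Dilated convolution exactly as the architecture defines it:

        Y[i, j, k] = sum_{m,n} X[i + m*d, j + n*d, k] * W[m, n, k]

    applied per channel k of an ``H x W x C`` map with a ``K x K x C``
    kernel.  ``valid`` (default) anchors the kernel at the top-left;
    ``same`` zero-pads so the output keeps the spatial shape.
    """
    x = np.asarray(x, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, :, None]
        kernel = kernel[:, :, None] if kernel.ndim == 2 else kernel
    H, W, C = x.shape
    kh, kw, kc = kernel.shape
    if kc != C:
        raise ValueError(f"kernel has {kc} channels, input has {C}")
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    if padding == "same":
        ph, pw = (kh - 1) * dilation // 2, (kw - 1) * dilation // 2
        x = np.pad(x, ((ph, ph), (pw, pw), (0, 0)))
        Hout, Wout = H, W
    elif padding == "valid":
        Hout = H - (kh - 1) * dilation
        Wout = W - (kw - 1) * dilation
        if Hout < 1 or Wout < 1:
            raise ValueError(
                f"dilated kernel ({kh}x{kw}, d={dilation}) larger than input {H}x{W}"
            )
    else:
        raise ValueError(f"unknown padding {padding!r}")
    out = np.zeros((Hout, Wout, C))
    for m in range(kh):
        for n in range(kw):
            out += x[m * dilation : m * dilation + Hout,
                     n * dilation : n * dilation + Wout, :] * kernel[m, n, :]
    return out[:, :, 0] if squeeze else out


@dataclass
class BatchNormParams:
    """Learnable scale/shift plus the normalization-form toggle."""

    gamma: float | np.ndarray = 1.0
    beta: float | np.ndarray = 0.0
    eps: float = 1e-5
    form: str = "paper"  # "paper": (sigma + eps) denominator; "variance": sqrt(var + eps)

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.form not in ("paper", "variance"):
            raise ValueError(f"unknown form {self.form!r}")


def batch_norm(x, params: BatchNormParams | None = None):
    """Reference batch normalization over the full batch (all axes but last).

    Paper form: gamma * (X - mu_B) / (sigma_B + eps) + beta.
    """
    params = params or BatchNormParams()
    x = np.asarray(x, dtype=float)
    axes = tuple(range(x.ndim - 1)) or None
    mu = x.mean(axis=axes, keepdims=True)
    sigma = x.std(axis=axes, keepdims=True)
    if params.form == "paper":
        xhat = (x - mu) / (sigma + params.eps)
    else:
        xhat = (x - mu) / np.sqrt(sigma**2 + params.eps)
    return params.gamma * xhat + params.beta


# --- windowing ----------------------------------------------------------------


@dataclass
class WindowDataset:
    """One sample per patient-hour: the T most recent rows ending there."""

    X: np.ndarray            # (N, T, F, 1) float32
    y: np.ndarray            # (N,) int
    patient_ids: np.ndarray  # (N,) provenance for patient-wise splitting
    times: np.ndarray        # (N,) window-end hour

    def __len__(self) -> int:
        return len(self.y)


def tensorize_windows(cohort: NumericCohort, window_length: int = 8) -> WindowDataset:
    """Slice each patient's numeric matrix into sliding windows.

    The window for hour t covers rows t-T+1 .. t, zero-padded at the top for
    the first hours of the stay; the label is the SepsisLabel at hour t.
    """
    if window_length < 2:
        raise ValueError("window length T must be >= 2")
    T = window_length
    xs, ys, pids, ts = [], [], [], []
    for patient in cohort.patients:
        V = patient.values
        n, F = V.shape
        padded = np.vstack([np.zeros((T - 1, F)), V])
        for t in range(n):
            xs.append(padded[t : t + T])
            ys.append(patient.labels[t])
            pids.append(patient.patient_id)
            ts.append(patient.times[t])
    X = np.asarray(xs, dtype=DTYPE)[..., None]
    return WindowDataset(
        X=X,
        y=np.asarray(ys, dtype=int),
        patient_ids=np.asarray(pids),
        times=np.asarray(ts, dtype=float),
    )


# --- blocks -------------------------------------------------------------------


def _bn(channels: int, config: ModelConfig) -> BatchNorm:
    return BatchNorm(channels, eps=config.bn_eps, form=config.bn_form)


class ECLF(Module):
    """Entry conv -> BN -> ReLU -> three multi-kernel branches -> concat ->
    ReLU -> BN -> 2x2 max-pool.  Output channels: 3 x branch_filters."""

    def __init__(self, in_channels: int, config: ModelConfig, rng):
        super().__init__()
        self.entry = Conv2D(in_channels, config.entry_filters, 3, rng, dilation=1)
        self.entry_bn = _bn(config.entry_filters, config)
        self.branches = [
            Conv2D(config.entry_filters, config.branch_filters, k, rng)
            for k in config.branch_kernels
        ]
        self.out_bn = _bn(config.branch_filters * len(config.branch_kernels), config)
        self.out_channels = config.branch_filters * len(config.branch_kernels)

    def forward(self, x):
        x = self.entry_bn(self.entry(x)).relu()
        fused = concatenate([branch(x) for branch in self.branches], axis=-1)
        return maxpool2x2(self.out_bn(fused.relu()))


class SpatialAttention(Module):
    """Single-channel (0,1) map: sigmoid(Conv_7x7(Conv_1x1(X)))."""

    def __init__(self, channels: int, config: ModelConfig, rng):
        super().__init__()
        reduced = max(channels // 8, 1)
        self.reduce = Conv2D(channels, reduced, 1, rng)
        self.spatial = Conv2D(reduced, 1, config.spatial_kernel, rng)
        self.last_map: np.ndarray | None = None

    def forward(self, x):
        attention = self.spatial(self.reduce(x)).sigmoid()
        self.last_map = attention.data
        return x * attention  # broadcast across channels


class ChannelAttention(Module):
    """Per-channel (0,1) weights from a pooled descriptor through a two-layer
    bottleneck: sigmoid(FC2(ReLU(FC1(GAP(X)))))."""

    def __init__(self, channels: int, config: ModelConfig, rng):
        super().__init__()
        self.fc1 = Dense(channels, config.channel_bottleneck, rng)
        self.fc2 = Dense(config.channel_bottleneck, channels, rng)
        self.last_weights: np.ndarray | None = None

    def forward(self, x):
        pooled = x.mean(axis=(1, 2))                     # (B, C)
        weights = self.fc2(self.fc1(pooled).relu()).sigmoid()
        self.last_weights = weights.data
        B, C = weights.shape
        return x * weights.reshape(B, 1, 1, C)


class SCAN(Module):
    """Spatial then channel attention, applied sequentially; shape-preserving."""

    def __init__(self, channels: int, config: ModelConfig, rng):
        super().__init__()
        self.spatial = SpatialAttention(channels, config, rng)
        self.channel = ChannelAttention(channels, config, rng)
        self.out_channels = channels

    def forward(self, x):
        return self.channel(self.spatial(x))


class HDCB(Module):
    """Parallel 3x3 convs at dilations (1, 2, 3); concat + 1x1 fusion (or
    sum), then BN and ReLU."""

    def __init__(self, in_channels: int, config: ModelConfig, rng):
        super().__init__()
        self.branches = [
            Conv2D(in_channels, config.hdcb_filters, 3, rng, dilation=d)
            for d in config.hdcb_dilations
        ]
        self.fusion = config.hdcb_fusion
        if self.fusion == "concat":
            self.project = Conv2D(
                config.hdcb_filters * len(config.hdcb_dilations),
                config.fusion_filters,
                1,
                rng,
            )
            self.out_channels = config.fusion_filters
        else:
            self.project = None
            self.out_channels = config.hdcb_filters
        self.bn = _bn(self.out_channels, config)

    def forward(self, x):
        outs = [branch(x) for branch in self.branches]
        if self.fusion == "concat":
            fused = self.project(concatenate(outs, axis=-1))
        else:
            fused = outs[0]
            for o in outs[1:]:
                fused = fused + o
        return self.bn(fused).relu()


class ResidualBlock(Module):
    """X + F(X) with F = Conv -> BN -> ReLU -> Conv (``fn`` is swappable)."""

    def __init__(self, channels: int, config: ModelConfig, rng):
        super().__init__()
        self.fn = Sequential(
            Conv2D(channels, channels, 3, rng),
            _bn(channels, config),
            ReLU(),
            Conv2D(channels, channels, 3, rng),
        )

    def forward(self, x):
        return x + self.fn(x)


class RPCC(Module):
    """Chain of residual blocks; 1x1 projection aligns the skip path when
    the incoming channel count differs from the block width."""

    def __init__(self, in_channels: int, config: ModelConfig, rng):
        super().__init__()
        width = config.rpcc_filters
        self.project = (
            Conv2D(in_channels, width, 1, rng) if in_channels != width else Identity()
        )
        self.blocks = [
            ResidualBlock(width, config, rng) for _ in range(config.rpcc_blocks)
        ]
        self.out_channels = width

    def forward(self, x):
        x = self.project(x)
        for block in self.blocks:
            x = block(x)
        return x


class Bypass(Module):
    """Ablation stand-in for a removed block: a 1x1 channel adapter (pure
    identity when the channel counts already agree)."""

    def __init__(self, in_channels: int, out_channels: int, rng):
        super().__init__()
        self.adapter = (
            Conv2D(in_channels, out_channels, 1, rng)
            if in_channels != out_channels
            else Identity()
        )
        self.out_channels = out_channels

    def forward(self, x):
        return self.adapter(x)


class SepsisNet(Module):
    """The full pipeline; probability of sepsis at the window's final hour."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        disabled = set(config.disabled_blocks)
        channels = 1
        eclf_out = config.branch_filters * len(config.branch_kernels)
        self.eclf = (
            ECLF(channels, config, rng)
            if "eclf" not in disabled
            else Bypass(channels, eclf_out, rng)
        )
        channels = self.eclf.out_channels if hasattr(self.eclf, "out_channels") else eclf_out
        self.scan = (
            SCAN(channels, config, rng)
            if "scan" not in disabled
            else Bypass(channels, channels, rng)
        )
        hdcb_out = (
            config.fusion_filters
            if config.hdcb_fusion == "concat"
            else config.hdcb_filters
        )
        self.hdcb = (
            HDCB(channels, config, rng)
            if "hdcb" not in disabled
            else Bypass(channels, hdcb_out, rng)
        )
        channels = self.hdcb.out_channels
        self.rpcc = (
            RPCC(channels, config, rng)
            if "rpcc" not in disabled
            else Bypass(channels, config.rpcc_filters, rng)
        )
        channels = self.rpcc.out_channels

        head: list[Module] = []
        in_units = channels
        for units in config.dense_units:
            head.append(Dense(in_units, units, rng))
            in_units = units
        self.head = head
        self.dropouts = [
            Dropout(config.dropout, np.random.default_rng(config.seed + 1 + i))
            for i in range(len(config.dense_units))
        ]
        self.output = Dense(in_units, 1, rng)

    def _check_batch(self, x: np.ndarray) -> None:
        expected = (self.config.window_length, self.config.n_features, 1)
        if x.ndim != 4 or x.shape[1:] != expected:
            raise ValueError(
                f"batch shape {x.shape} incompatible with configured "
                f"window {expected}"
            )

    def forward_logits(self, x) -> Tensor:
        if isinstance(x, np.ndarray):
            self._check_batch(x)
            x = Tensor(x.astype(DTYPE, copy=False))
        h = self.rpcc(self.hdcb(self.scan(self.eclf(x))))
        h = h.mean(axis=(1, 2))  # global average pool -> (B, C)
        for dense, drop in zip(self.head, self.dropouts):
            h = drop(dense(h).relu())
        return self.output(h)

    def forward(self, x) -> Tensor:
        return self.forward_logits(x).sigmoid()

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode probabilities for an array of samples."""
        was_training = self.training
        self.eval()
        try:
            out = [
                self.forward(x[i : i + batch_size]).data.reshape(-1)
                for i in range(0, len(x), batch_size)
            ]
        finally:
            if was_training:
                self.train()
        return np.concatenate(out) if out else np.zeros(0)


def build_model(config: ModelConfig) -> SepsisNet:
    return SepsisNet(config)


def forward(model: SepsisNet, batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode forward pass returning probabilities in (0, 1)."""
    return model.predict_proba(batch)


def count_parameters(model: Module) -> int:
    return model.count_parameters()
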
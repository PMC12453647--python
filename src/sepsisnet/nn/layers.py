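"""Layers and optimizer built on the autodiff engine.

Weight initialization is fan-in-scaled Gaussian (He) drawn from an explicit
``numpy.random.Generator`` so every model build is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self) -> None:
        self.training = True

    def __call__(self, x):
        return self.forward(x)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> None:
        self.training = True
        for _, child in self._children():
            child.train()

    def eval(self) -> None:
        self.training = False
        for _, child in self._children():
            child.eval()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, child in self._children():
            for key, buf in child._buffers().items():
                state[f"{name}.{key}"] = buf.copy()
        state.update({k: v.copy() for k, v in self._buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = self._named_buffers()
        for key, value in state.items():
            if key in params:
                params[key].data = np.asarray(value, dtype=DTYPE).reshape(
                    params[key].data.shape
                )
            elif key in buffers:
                owner, attr = buffers[key]
                setattr(owner, attr, np.asarray(value, dtype=DTYPE))
            else:
                raise KeyError(f"unknown state entry {key!r}")

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def _named_buffers(self, prefix: str = ""):
        out = {}
        for key in self._buffers():
            out[f"{prefix}{key}"] = (self, key)
        for name, child in self._children():
            out.update(child._named_buffers(prefix=f"{prefix}{name}."))
        return out

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.steps = list(modules)

    def forward(self, x):
        for step in self.steps:
            x = step(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Conv2D(Module):
    """Stride-1 (optionally dilated) convolution, NHWC, He-initialized."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        dilation: int = 1,
        padding: str = "same",
        bias: bool = True,
    ):
        super().__init__()
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        fan_in = kernel * kernel * in_channels
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(kernel, kernel, in_channels, out_channels))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.dilation = dilation
        self.padding = padding

    def forward(self, x):
        return conv2d(
            x, self.weight, self.bias, dilation=self.dilation, padding=self.padding
        )


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x):
        return x @ self.weight + self.bias


class BatchNorm(Module):
    """Per-channel batch normalization over (batch, height, width).

    ``form="paper"`` normalizes by (sigma_B + eps) — the standard deviation
    plus the stabilizer, as the architecture prints it; ``form="variance"``
    uses the conventional sqrt(var + eps).  In evaluation mode running
    statistics (exponential moving averages) replace batch statistics.
    """

    def __init__(
        self,
        channels: int,
        eps: float = 1e-5,
        form: str = "paper",
        momentum: float = 0.1,
    ):
        super().__init__()
        if eps <= 0:
            raise ValueError("eps must be > 0")
        if form not in ("paper", "variance"):
            raise ValueError(f"unknown batch-norm form {form!r}")
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.form = form
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_std = np.ones(channels, dtype=DTYPE)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_std": self.running_std}

    def forward(self, x):
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            diff = x - mu
            var = (diff * diff).mean(axis=axes, keepdims=True)
            if self.form == "paper":
                denom = var.sqrt() + self.eps
            else:
                denom = (var + self.eps).sqrt()
            m = self.momentum
            self.running_mean = (
                (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            ).astype(DTYPE)
            self.running_std = (
                (1 - m) * self.running_std + m * np.sqrt(var.data.reshape(-1))
            ).astype(DTYPE)
            xhat = diff / denom
        else:
            mu = self.running_mean.reshape((1,) * (x.ndim - 1) + (-1,))
            std = self.running_std.reshape((1,) * (x.ndim - 1) + (-1,))
            if self.form == "paper":
                denom = std + self.eps
            else:
                denom = np.sqrt(std**2 + self.eps)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / denom)
        return self.gamma * xhat + self.beta


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x):
        if not self.training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * Tensor(mask)


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
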
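"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operation that
produced it; calling :meth:`Tensor.backward` on a scalar loss walks the
graph in reverse topological order and accumulates gradients into every
tensor created with ``requires_grad=True``.

The operation set is exactly what the sepsis network needs: broadcasting
arithmetic, matmul, ReLU/sigmoid/sqrt, axis reductions, reshape and channel
concatenation, dilated 2-D convolution (NHWC, im2col + BLAS matmul), 2x2
max-pooling, and a numerically stable binary cross-entropy on logits.
Gradients of every op are verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concatenate",
    "conv2d",
    "maxpool2x2",
    "bce_with_logits",
]


def _as_tensor(x, dtype=None) -> "Tensor":
    """Wrap a constant; scalars adopt ``dtype`` so float32 graphs stay float32."""
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and (arr.ndim == 0 or arr.dtype != dtype):
        if arr.dtype.kind in "fib":
            arr = arr.astype(dtype)
    elif arr.dtype.kind in "ib":
        arr = arr.astype(float)
    return Tensor(arr)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over the axes that broadcasting expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # --- graph construction helpers -----------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # --- basic properties ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # --- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        a, b = self, other

        def backward(grad):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(grad):
            a._accumulate(-grad)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        a, b = self, other

        def backward(grad):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other, self.data.dtype)
        a, b = self, other

        def backward(grad):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(
                    _unbroadcast(-grad * a.data / (b.data**2), b.data.shape)
                )

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __matmul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        a, b = self, other

        def backward(grad):
            if a.requires_grad:
                a._accumulate(grad @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ grad)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # --- elementwise nonlinearities ------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(grad):
            a._accumulate(grad * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = _sigmoid(a.data)

        def backward(grad):
            a._accumulate(grad * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(grad):
            a._accumulate(grad * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (a,), backward)

    # --- reductions and shape ops --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(grad):
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        a = self
        count = a.data.size if axis is None else np.prod(
            [a.data.shape[ax] for ax in np.atleast_1d(axis)]
        )

        def backward(grad):
            g = grad / count
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(a.data.mean(axis=axis, keepdims=keepdims), (a,), backward)

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(grad):
            a._accumulate(grad.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    dtype = x.dtype if x.dtype.kind == "f" else np.dtype(float)
    out = np.empty_like(x, dtype=dtype)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    # keep the open interval (0, 1) even where the exponential saturates
    tiny = np.finfo(dtype).tiny
    eps = np.finfo(dtype).eps
    return np.clip(out, tiny, 1.0 - eps)


def concatenate(tensors, axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis (channel fusion in the network)."""
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        pieces = np.split(grad, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    dilation: int = 1,
    padding: str = "same",
) -> Tensor:
    """Dilated 2-D convolution, NHWC layout, stride 1.

    ``x`` is (B, H, W, Cin), ``w`` is (kh, kw, Cin, Cout).  ``same`` padding
    keeps the spatial shape (odd kernels); ``valid`` applies no padding and
    the kernel taps land at x[i + m*d, j + n*d] exactly as in the dilated
    convolution sum the architecture is defined by.
    """
    x = _as_tensor(x)
    w = _as_tensor(w)
    B, H, W, Cin = x.data.shape
    kh, kw, wcin, Cout = w.data.shape
    if wcin != Cin:
        raise ValueError(f"kernel expects {wcin} input channels, got {Cin}")
    if padding == "same":
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("same padding requires odd kernel sizes")
        ph, pw = (kh - 1) * dilation // 2, (kw - 1) * dilation // 2
        Hout, Wout = H, W
    elif padding == "valid":
        ph = pw = 0
        Hout = H - (kh - 1) * dilation
        Wout = W - (kw - 1) * dilation
        if Hout < 1 or Wout < 1:
            raise ValueError(
                f"dilated kernel ({kh}x{kw}, d={dilation}) larger than input {H}x{W}"
            )
    else:
        raise ValueError(f"unknown padding mode {padding!r}")

    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0))) if (ph or pw) else x.data

    def tap(m: int, n: int) -> np.ndarray:
        """The input slice seen by kernel element (m, n), as (B*Hout*Wout, Cin)."""
        return xp[
            :, m * dilation : m * dilation + Hout, n * dilation : n * dilation + Wout, :
        ].reshape(B * Hout * Wout, Cin)

    # accumulate one small matmul per kernel tap; avoids materializing the
    # full im2col buffer, which dominates memory traffic at these map sizes
    out_flat = np.zeros((B * Hout * Wout, Cout), dtype=x.data.dtype)
    for m in range(kh):
        for n in range(kw):
            out_flat += tap(m, n) @ w.data[m, n]
    out_data = out_flat.reshape(B, Hout, Wout, Cout)
    if b is not None:
        out_data = out_data + b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        gflat = grad.reshape(B * Hout * Wout, Cout)
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for m in range(kh):
                for n in range(kw):
                    dw[m, n] = tap(m, n).T @ gflat
            w._accumulate(dw)
        if b is not None and b.requires_grad:
            b._accumulate(grad.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            dxp = np.zeros_like(xp) if (ph or pw) else np.zeros_like(x.data)
            for m in range(kh):
                for n in range(kw):
                    dxp[
                        :,
                        m * dilation : m * dilation + Hout,
                        n * dilation : n * dilation + Wout,
                        :,
                    ] += (gflat @ w.data[m, n].T).reshape(B, Hout, Wout, Cin)
            if ph or pw:
                dxp = dxp[:, ph : ph + H, pw : pw + W, :]
            x._accumulate(dxp)

    return Tensor._make(out_data, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max-pooling with stride 2; odd trailing rows/columns are dropped
    (floor division of the spatial dims)."""
    x = _as_tensor(x)
    B, H, W, C = x.data.shape
    H2, W2 = H // 2, W // 2
    if H2 < 1 or W2 < 1:
        raise ValueError(f"input {H}x{W} too small for 2x2 pooling")
    crop = x.data[:, : 2 * H2, : 2 * W2, :]
    win = crop.reshape(B, H2, 2, W2, 2, C).transpose(0, 1, 3, 2, 4, 5)
    win = win.reshape(B, H2, W2, 4, C)
    arg = win.argmax(axis=3)
    out_data = np.take_along_axis(win, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(grad):
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, arg[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        dcrop = (
            dwin.reshape(B, H2, W2, 2, 2, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, 2 * H2, 2 * W2, C)
        )
        dx = np.zeros_like(x.data)
        dx[:, : 2 * H2, : 2 * W2, :] = dcrop
        x._accumulate(dx)

    return Tensor._make(out_data, (x,), backward)


def bce_with_logits(logits: Tensor, targets, pos_weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy computed stably from logits.

    ``targets`` is a plain 0/1 array; ``pos_weight`` > 1 up-weights the
    positive class (off by default)."""
    logits = _as_tensor(logits)
    z = logits.data.reshape(-1)
    y = np.asarray(targets, dtype=z.dtype).reshape(-1)
    if z.shape != y.shape:
        raise ValueError(f"logits {z.shape} vs targets {y.shape}")
    weights = np.where(y == 1, pos_weight, 1.0)
    # log(1 + e^-|z|) + max(z, 0) - z*y  is the stable per-sample loss
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = float((weights * per).mean())
    p = _sigmoid(z)

    def backward(grad):
        g = grad * weights * (p - y) / z.size
        logits._accumulate(g.reshape(logits.data.shape))

    return Tensor._make(np.asarray(loss, dtype=z.dtype), (logits,), backward)
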
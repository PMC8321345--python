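"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The segmentation networks in this package are small enough to train on a CPU,
so the whole neural-network stack is built on a compact dynamic tape: every
operation returns a :class:`Tensor` that remembers its parents and a closure
propagating the upstream gradient.  Only the operations the UNet variants need
are implemented (convolution, batch normalization, ReLU, max pooling, bilinear
upsampling, concatenation, the focal objective and a weighted map sum).

Arrays are ``float32`` and follow the NCHW layout used throughout the models.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A NumPy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep UNet tapes overflow recursion limits
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _needs_graph(*tensors: Tensor) -> bool:
    return _GRAD_ENABLED and any(t.requires_grad or t._parents for t in tensors)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data
    if not _needs_graph(a, b):
        return Tensor(out_data)

    def backward(grad):
        _accum(a, _unbroadcast(grad, a.data.shape))
        _accum(b, _unbroadcast(grad, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)
    if not _needs_graph(x):
        return Tensor(out_data)
    mask = x.data > 0

    def backward(grad):
        _accum(x, grad * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not _needs_graph(*tensors):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(grad):
        for t, g in zip(tensors, np.split(grad, splits, axis=axis)):
            _accum(t, g)

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (n, c, oh, ow, kh, kw) -> (n, oh*ow, c*kh*kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
    d = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation; weight shape (F, C, kh, kw)."""
    f, c, kh, kw = weight.data.shape
    n = x.data.shape[0]
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(f, -1)
    out = cols @ wmat.T  # (n, oh*ow, f)
    if bias is not None:
        out += bias.data
    out_data = out.transpose(0, 2, 1).reshape(n, f, oh, ow)
    parents = (x, weight) if bias is None else (x, weight, bias)
    if not _needs_graph(*parents):
        return Tensor(out_data)

    def backward(grad):
        g = grad.reshape(n, f, oh * ow).transpose(0, 2, 1)  # (n, oh*ow, f)
        if weight.requires_grad or weight._parents:
            dw = np.einsum("npf,npk->fk", g, cols, optimize=True)
            _accum(weight, dw.reshape(weight.data.shape))
        if bias is not None and (bias.requires_grad or bias._parents):
            _accum(bias, g.sum(axis=(0, 1)))
        if x.requires_grad or x._parents:
            dcols = g @ wmat  # (n, oh*ow, c*kh*kw)
            _accum(x, _col2im(dcols, x.data.shape, kh, kw, stride, pad))

    return Tensor(out_data, parents=parents, backward=backward)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel normalization; updates running stats in place when training."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    if not _needs_graph(x, gamma, beta):
        return Tensor(out_data)

    def backward(grad):
        if gamma.requires_grad or gamma._parents:
            _accum(gamma, (grad * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad or beta._parents:
            _accum(beta, grad.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gx = grad * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                s1 = gx.sum(axis=(0, 2, 3))[None, :, None, None]
                s2 = (gx * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
                dx = (gx - s1 / m - xhat * s2 / m) * inv_std[None, :, None, None]
            else:
                dx = gx * inv_std[None, :, None, None]
            _accum(x, dx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


# ---------------------------------------------------------------------------
# max pooling (ResNet stem)
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    n_, c_, oh, ow = win.shape[:4]
    flat = win.reshape(n, c, oh, ow, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    if not _needs_graph(x):
        return Tensor(out_data)

    def backward(grad):
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        ki, kj = np.unravel_index(idx, (kernel, kernel))
        oi, oj = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
        rows = oi[None, None] * stride + ki
        cols_ = oj[None, None] * stride + kj
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, ci, rows, cols_), grad)
        _accum(x, dxp[:, :, pad : pad + h, pad : pad + w])

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# bilinear upsampling
# ---------------------------------------------------------------------------

def _linear_coeffs(n_in: int, n_out: int):
    """Source indices and weights for 1-D bilinear resizing (half-pixel centers)."""
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.floor(src).astype(np.int64)
    frac = (src - i0).astype(np.float32)
    i0 = np.clip(i0, 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    # when src < 0 the clipped pair collapses; zero the fractional weight there
    frac = np.where(src < 0, 0.0, frac).astype(np.float32)
    return i0, i1, frac


def upsample_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize to ``out_hw`` with the half-pixel (align_corners=False) convention."""
    n, c, h, w = x.data.shape
    oh, ow = out_hw
    r0, r1, fr = _linear_coeffs(h, oh)
    c0, c1, fc = _linear_coeffs(w, ow)
    xr = x.data[:, :, r0, :] * (1.0 - fr)[None, None, :, None] + x.data[:, :, r1, :] * fr[None, None, :, None]
    out_data = xr[:, :, :, c0] * (1.0 - fc)[None, None, None, :] + xr[:, :, :, c1] * fc[None, None, None, :]
    if not _needs_graph(x):
        return Tensor(out_data)

    def backward(grad):
        gxr = np.zeros((n, c, oh, w), dtype=np.float32)
        np.add.at(gxr, (slice(None), slice(None), slice(None), c0), grad * (1.0 - fc)[None, None, None, :])
        np.add.at(gxr, (slice(None), slice(None), slice(None), c1), grad * fc[None, None, None, :])
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        np.add.at(dx, (slice(None), slice(None), r0, slice(None)), gxr * (1.0 - fr)[None, None, :, None])
        np.add.at(dx, (slice(None), slice(None), r1, slice(None)), gxr * fr[None, None, :, None])
        _accum(x, dx)

    return Tensor(out_data, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# objectives and map merging
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    zs = z - z.max(axis=axis, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=axis, keepdims=True)


def focal_from_logits(logits: Tensor, target_onehot: np.ndarray, gamma: float, eps: float = 1e-7) -> Tensor:
    """Mean focal loss -(1-p_t)^gamma * log(p_t) computed from class logits.

    ``target_onehot`` must be one-hot along axis 1 and is treated as a constant.
    """
    t = np.asarray(target_onehot, dtype=np.float32)
    if t.shape != logits.data.shape:
        raise ValueError(f"target shape {t.shape} != logits shape {logits.data.shape}")
    p = softmax(logits.data, axis=1)
    pt = (p * t).sum(axis=1)
    ptc = np.clip(pt, eps, 1.0)
    one_minus = np.clip(1.0 - pt, 0.0, 1.0)
    losses = -(one_minus ** gamma) * np.log(ptc)
    out_data = np.float32(losses.mean())
    if not _needs_graph(logits):
        return Tensor(out_data)
    count = losses.size

    def backward(grad):
        # d/du[-(1-u)^g log u]; log term uses the clipped probability
        if gamma == 0.0:
            dldu = -1.0 / ptc
        else:
            dldu = gamma * (one_minus ** (gamma - 1.0)) * np.log(ptc) - (one_minus ** gamma) / ptc
        coeff = (float(grad) / count) * dldu * pt  # (N,H,W)
        dz = coeff[:, None] * (t - p)
        _accum(logits, dz.astype(np.float32))

    return Tensor(out_data, parents=(logits,), backward=backward)


def weighted_map_sum(maps: list[Tensor], weights: Tensor) -> Tensor:
    """sum_l w[l] * maps[l]; used by the linear-merge head."""
    k = len(maps)
    if weights.data.shape != (k,):
        raise ValueError(f"expected {k} weights, got shape {weights.data.shape}")
    out_data = sum(weights.data[i] * maps[i].data for i in range(k))
    parents = tuple(maps) + (weights,)
    if not _needs_graph(*parents):
        return Tensor(out_data)

    def backward(grad):
        if weights.requires_grad or weights._parents:
            dw = np.array([(maps[i].data * grad).sum() for i in range(k)], dtype=np.float32)
            _accum(weights, dw)
        for i, m in enumerate(maps):
            if m.requires_grad or m._parents:
                _accum(m, weights.data[i] * grad)

    return Tensor(out_data, parents=parents, backward=backward)
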
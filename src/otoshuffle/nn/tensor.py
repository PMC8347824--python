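"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a ``float32`` ndarray and records the operations
applied to it; calling :meth:`Tensor.backward` on a scalar result walks the
recorded graph in reverse topological order and accumulates ``.grad`` on
every node reached.  Gradients are accumulated on *all* intermediate nodes,
not only leaves — Grad-CAM reads the gradient of an internal feature map
directly off the graph.

Only the operations needed by the residual classifiers live here: dense and
convolutional primitives (via im2col), batch normalisation, pooling, the
space-to-depth / depth-to-space pair, nearest-neighbour upsampling, and a
fused softmax cross-entropy loss.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "linear",
    "conv2d",
    "batch_norm2d",
    "max_pool2d",
    "global_avg_pool",
    "spatial_mean",
    "spatial_max",
    "channel_mean",
    "channel_max",
    "concat_channels",
    "flatten",
    "space_to_depth",
    "depth_to_space",
    "upsample_nearest2x",
    "softmax_cross_entropy",
]


def _as_f32(a) -> np.ndarray:
    a = np.asarray(a, dtype=np.float32)
    if a.ndim and not a.flags["C_CONTIGUOUS"]:
        a = np.ascontiguousarray(a)
    return a


class Tensor:
    """An ndarray with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(()))

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    # -- autodiff -------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node.

        ``grad`` defaults to 1 for scalar outputs; a non-scalar root needs
        an explicit seed gradient of matching shape.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(_as_f32(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def reshape(self, *shape):
        return _reshape(self, shape)


def _wrap(other) -> Tensor:
    return other if isinstance(other, Tensor) else Tensor(other)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)
    mask = out_data > 0

    def backward(g):
        x._accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable logistic: evaluate each branch only where safe
    d = x.data
    out_data = np.empty_like(d)
    pos = d >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ed = np.exp(d[~pos])
    out_data[~pos] = ed / (1.0 + ed)

    def backward(g):
        x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=backward)


def _reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(old))

    return Tensor(out_data, parents=(x,), backward=backward)


def flatten(x: Tensor) -> Tensor:
    return _reshape(x, (x.data.shape[0], -1))


# ---------------------------------------------------------------------------
# dense / convolution
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w.T + b`` with ``x`` of shape (N, in), ``w`` of shape (out, in)."""
    out_data = x.data @ w.data.T
    if b is not None:
        out_data = out_data + b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        x._accumulate(g @ w.data)
        w._accumulate(g.T @ x.data)
        if b is not None:
            b._accumulate(g.sum(axis=0))

    return Tensor(out_data, parents=parents, backward=backward)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, oh: int, ow: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. ``x``: (N,C,H,W); ``w``: (F,C,kh,kw)."""
    n, c, h, wd = x.data.shape
    f, cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {cw}")
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (wd + 2 * padding - kw) // stride + 1
    if oh < 1 or ow < 1:
        raise ValueError("conv2d output would be empty")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    cols = _im2col(xp, kh, kw, stride, oh, ow)
    cols2 = cols.reshape(n, c * kh * kw, oh * ow)
    wm = w.data.reshape(f, c * kh * kw)
    out = np.matmul(wm, cols2).reshape(n, f, oh, ow)
    if b is not None:
        out += b.data.reshape(1, f, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gm = g.reshape(n, f, oh * ow)
        # weight gradient: sum over batch of gm @ cols2^T
        dw = np.einsum("nfl,nkl->fk", gm, cols2, optimize=True).reshape(w.data.shape)
        w._accumulate(dw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        dcols2 = np.matmul(wm.T[None], gm)  # (n, c*kh*kw, oh*ow)
        dcols = dcols2.reshape(n, c, kh, kw, oh, ow)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]
        dx = dxp[:, :, padding : padding + h, padding : padding + wd] if padding else dxp
        x._accumulate(dx)

    return Tensor(out, parents=parents, backward=backward)


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
    """Per-channel batch normalisation over (N, H, W).

    ``running_mean``/``running_var`` are plain arrays mutated in place during
    training (exponential moving average, unbiased variance), matching the
    convention of mainstream frameworks.
    """
    n, c, h, w = x.data.shape
    if training:
        axes = (0, 2, 3)
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = n * h * w
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * (var * m / max(m - 1, 1))
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        gamma._accumulate(np.einsum("nchw,nchw->c", g, xhat, optimize=True))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gsc = g * gamma.data.reshape(1, c, 1, 1)
        if training:
            m = n * h * w
            sum_g = gsc.sum(axis=(0, 2, 3), keepdims=True)
            sum_gx = np.einsum("nchw,nchw->c", gsc, xhat, optimize=True).reshape(1, c, 1, 1)
            dx = (inv_std.reshape(1, c, 1, 1) / m) * (m * gsc - sum_g - xhat * sum_gx)
        else:
            dx = gsc * inv_std.reshape(1, c, 1, 1)
        x._accumulate(dx.astype(np.float32))

    return Tensor(out, parents=(x, gamma, beta), backward=backward)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.data.shape
    oh = (h + 2 * padding - kernel) // stride + 1
    ow = (w + 2 * padding - kernel) // stride + 1
    if padding:
        xp = np.full((n, c, h + 2 * padding, w + 2 * padding), -np.inf, dtype=np.float32)
        xp[:, :, padding : padding + h, padding : padding + w] = x.data
    else:
        xp = x.data
    cols = _im2col(xp, kernel, kernel, stride, oh, ow)
    flat = cols.reshape(n, c, kernel * kernel, oh, ow)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2).squeeze(2)

    def backward(g):
        dxp = np.zeros(xp.shape, dtype=np.float32)
        for i in range(kernel):
            for j in range(kernel):
                mask = arg == (i * kernel + j)
                dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += g * mask
        dx = dxp[:, :, padding : padding + h, padding : padding + w] if padding else dxp
        x._accumulate(dx)

    return Tensor(out, parents=(x,), backward=backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) mean over the spatial grid."""
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).astype(np.float32))

    return Tensor(out, parents=(x,), backward=backward)


def spatial_mean(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C, 1, 1) average-pool descriptor."""
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3), keepdims=True)

    def backward(g):
        x._accumulate(np.broadcast_to(g / (h * w), x.data.shape).astype(np.float32))

    return Tensor(out, parents=(x,), backward=backward)


def spatial_max(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C, 1, 1) max-pool descriptor."""
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2).reshape(n, c, 1, 1)

    def backward(g):
        dflat = np.zeros((n, c, h * w), dtype=np.float32)
        np.put_along_axis(dflat, arg[:, :, None], g.reshape(n, c, 1), axis=2)
        x._accumulate(dflat.reshape(x.data.shape))

    return Tensor(out, parents=(x,), backward=backward)


def channel_mean(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, 1, H, W) cross-channel mean map."""
    c = x.data.shape[1]
    out = x.data.mean(axis=1, keepdims=True)

    def backward(g):
        x._accumulate(np.broadcast_to(g / c, x.data.shape).astype(np.float32))

    return Tensor(out, parents=(x,), backward=backward)


def channel_max(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, 1, H, W) cross-channel max map."""
    arg = x.data.argmax(axis=1)
    out = np.take_along_axis(x.data, arg[:, None], axis=1)

    def backward(g):
        dx = np.zeros_like(x.data)
        np.put_along_axis(dx, arg[:, None], g, axis=1)
        x._accumulate(dx)

    return Tensor(out, parents=(x,), backward=backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        a._accumulate(g[:, :ca])
        b._accumulate(g[:, ca:])

    return Tensor(out, parents=(a, b), backward=backward)


def space_to_depth(x: Tensor) -> Tensor:
    """Move each 2x2 spatial block into four consecutive channels.

    Output channel ``4c + p`` at (i, j) equals input channel ``c`` at
    (2i + p//2, 2j + p%2): phases are ordered row-major, so the rearrangement
    is a lossless bijection inverted by :func:`depth_to_space`.
    """
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"space_to_depth requires even spatial dims, got {h}x{w}")
    out = (
        x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, 4 * c, h // 2, w // 2)
    )

    def backward(g):
        dx = (
            g.reshape(n, c, 2, 2, h // 2, w // 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, c, h, w)
        )
        x._accumulate(np.ascontiguousarray(dx))

    return Tensor(np.ascontiguousarray(out), parents=(x,), backward=backward)


def depth_to_space(x: Tensor) -> Tensor:
    """Inverse of :func:`space_to_depth`."""
    n, c4, h, w = x.data.shape
    if c4 % 4:
        raise ValueError(f"depth_to_space requires channels divisible by 4, got {c4}")
    c = c4 // 4
    out = (
        x.data.reshape(n, c, 2, 2, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, c, 2 * h, 2 * w)
    )

    def backward(g):
        dx = (
            g.reshape(n, c, h, 2, w, 2)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, c4, h, w)
        )
        x._accumulate(np.ascontiguousarray(dx))

    return Tensor(np.ascontiguousarray(out), parents=(x,), backward=backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor(out, parents=(x,), backward=backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, labels: np.ndarray, class_weights: np.ndarray | None = None) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``.

    ``class_weights`` (per-class multipliers, length K) implements
    inverse-frequency weighting; the loss is normalised by the summed weight
    of the batch so a uniformly weighted batch reproduces the plain mean.
    """
    labels = np.asarray(labels, dtype=np.int64)
    n, k = logits.data.shape
    if labels.shape != (n,):
        raise ValueError("labels must be a vector matching the batch size")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError("label outside [0, num_classes)")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    logp = z - np.log(ez.sum(axis=1, keepdims=True))
    if class_weights is None:
        wts = np.ones(n, dtype=np.float32)
    else:
        wts = np.asarray(class_weights, dtype=np.float32)[labels]
    wsum = wts.sum()
    loss = -(wts * logp[np.arange(n), labels]).sum() / wsum

    def backward(g):
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        d *= (wts / wsum)[:, None]
        logits._accumulate(g * d.astype(np.float32))

    return Tensor(np.float32(loss), parents=(logits,), backward=backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Plain-array softmax used at inference time."""
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)
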
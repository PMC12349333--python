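"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine providing exactly the operations a
grouped-convolution detection network needs: grouped 2-D convolution
(im2col/col2im), batch normalisation, stride-1 max pooling, nearest
upsampling, channel concatenation/slicing, the activations used by the
blocks, and the reductions needed by the losses.  Convolutions are lowered
to BLAS matmuls; backward passes are exact (not finite differences) and are
verified against central differences in the test-suite.

Arrays are float32 throughout; ``Tensor.backward()`` accumulates gradients
into ``.grad`` for every tensor with ``requires_grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "conv2d", "batch_norm2d", "max_pool2d_same", "upsample_nearest",
    "concat", "add", "mul", "sigmoid", "silu", "hardswish", "relu",
    "global_avg_pool", "conv1d_channels", "reshape", "transpose",
    "log_softmax", "softmax", "mean", "sum_", "bce_with_logits",
]


class Tensor:
    """An ndarray plus the tape machinery for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "trainable", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, trainable: bool = True):
        # float32 by default; float64 arrays are preserved (useful for
        # high-precision gradient verification)
        a = np.asarray(data)
        self.data = a if a.dtype == np.float64 else np.asarray(a, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self.trainable = bool(trainable)
        self._backward = None
        self._parents: tuple = ()

    # -- plumbing -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float32)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # convenience arithmetic (scalar or tensor operands)
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _const(-1.0)))

    def __neg__(self):
        return mul(self, _const(-1.0))


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _const(v):
    return Tensor(np.float32(v))


def _make(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.astype(np.float32, copy=False)


# -- elementwise ------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(g * b.data, a.shape),
                            _unbroadcast(g * a.data, b.shape)))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return _make(s, (x,), lambda g: (g * s * (1.0 - s),))


def relu(x: Tensor) -> Tensor:
    m = x.data > 0
    return _make(np.where(m, x.data, 0.0), (x,), lambda g: (g * m,))


def silu(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return _make(x.data * s, (x,), lambda g: (g * (s * (1.0 + x.data * (1.0 - s))),))


def hardswish(x: Tensor) -> Tensor:
    """x * clip(x + 3, 0, 6) / 6 — identical to the three-branch definition."""
    inner = np.clip(x.data + 3.0, 0.0, 6.0)
    # derivative: 0 for x<=-3, 1 for x>=3, (2x+3)/6 between
    d = np.where(x.data <= -3.0, 0.0, np.where(x.data >= 3.0, 1.0, (2.0 * x.data + 3.0) / 6.0))
    return _make(x.data * inner / 6.0, (x,), lambda g: (g * d.astype(np.float32),))


# -- shape ops --------------------------------------------------------------

def reshape(x: Tensor, shape) -> Tensor:
    old = x.shape
    return _make(x.data.reshape(shape), (x,), lambda g: (g.reshape(old),))


def transpose(x: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    return _make(x.data.transpose(axes), (x,), lambda g: (g.transpose(inv),))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice `length` entries from `start` along `axis` (differentiable)."""
    idx = [slice(None)] * x.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)

    def backward(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        return (full,)

    return _make(x.data[idx], (x,), backward)


# -- reductions -------------------------------------------------------------

def mean(x: Tensor, axis=None, keepdims=False) -> Tensor:
    out = x.data.mean(axis=axis, keepdims=keepdims)
    n = x.data.size / out.size

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, x.shape).astype(np.float32) / n,)

    return _make(out, (x,), backward)


def sum_(x: Tensor, axis=None, keepdims=False) -> Tensor:
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, x.shape).astype(np.float32).copy(),)

    return _make(out, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - dot),)

    return _make(s, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    s = np.exp(out)

    def backward(g):
        return (g - s * g.sum(axis=axis, keepdims=True),)

    return _make(out, (x,), backward)


def bce_with_logits(logits: Tensor, target: np.ndarray, weight=None) -> Tensor:
    """Mean binary cross-entropy on logits; `target` is a plain array."""
    t = np.asarray(target, dtype=np.float32)
    x = logits.data
    # numerically stable: max(x,0) - x*t + log(1+exp(-|x|))
    loss = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    w = np.float32(1.0) if weight is None else np.asarray(weight, dtype=np.float32)
    loss = loss * w
    n = loss.size

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-x))
        return (g * w * (s - t) / n,)

    return _make(loss.mean(), (logits,), backward)


# -- convolution ------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(B,C,H,W) padded input -> (B, C*k*k, oh*ow) patch matrix."""
    b, c, _, _ = xp.shape
    sb, sc, sh, sw = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, shape=(b, c, k, k, oh, ow),
        strides=(sb, sc, sh, sw, sh * stride, sw * stride), writeable=False)
    return win.reshape(b, c * k * k, oh * ow)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int | None = None, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution. Weight layout (Cout, Cin/g, k, k).

    `padding=None` means "same" for odd kernels at stride 1, k//2 otherwise
    (the stride-2 downsampling convention of the detection backbone).
    """
    B, C, H, W = x.shape
    Cout, Cin_g, k, _ = w.shape
    g = groups
    if C % g or Cout % g or Cin_g != C // g:
        raise ValueError(f"channel/group mismatch: C={C}, Cout={Cout}, groups={g}")
    p = k // 2 if padding is None else padding
    oh = (H + 2 * p - k) // stride + 1
    ow = (W + 2 * p - k) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = _im2col(xp, k, stride, oh, ow)            # (B, C*k*k, L)
    L = oh * ow
    cols_g = cols.reshape(B, g, Cin_g * k * k, L)
    wm = w.data.reshape(g, Cout // g, Cin_g * k * k)
    out = np.einsum("goc,bgcl->bgol", wm, cols_g, optimize=True)
    out = out.reshape(B, Cout, oh, ow)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)

    def backward(gout):
        gout_g = gout.reshape(B, g, Cout // g, L)
        gw = np.einsum("bgol,bgcl->goc", gout_g, cols_g, optimize=True)
        gw = gw.reshape(Cout, Cin_g, k, k).astype(np.float32)
        gcols = np.einsum("goc,bgol->bgcl", wm, gout_g, optimize=True)
        gcols = gcols.reshape(B, C, k, k, oh, ow)
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += gcols[:, :, i, j]
        gx = gxp[:, :, p:p + H, p:p + W] if p else gxp
        grads = [gx.astype(np.float32), gw]
        if b is not None:
            grads.append(gout.sum(axis=(0, 2, 3)).astype(np.float32))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def conv1d_channels(y: Tensor, w: Tensor) -> Tensor:
    """1-D convolution of width k across the channel axis of (B, C) input,
    zero "same" padding — the cross-channel interaction of ECA attention."""
    B, C = y.shape
    (k,) = w.shape
    p = k // 2
    yp = np.pad(y.data, ((0, 0), (p, p)))
    sb, sc = yp.strides
    win = np.lib.stride_tricks.as_strided(yp, (B, C, k), (sb, sc, sc), writeable=False)
    out = win @ w.data

    def backward(g):
        gw = np.einsum("bc,bck->k", g, win, optimize=True).astype(np.float32)
        gyp = np.zeros_like(yp)
        for i in range(k):
            gyp[:, i:i + C] += g * w.data[i]
        return (gyp[:, p:p + C].astype(np.float32), gw)

    return _make(out, (y, w), backward)


# -- normalisation / pooling / resize ---------------------------------------

def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool, momentum: float = 0.03,
                 eps: float = 1e-3) -> Tensor:
    """Batch normalisation over (B,H,W) per channel; updates running stats
    in-place when training."""
    B, C, H, W = x.shape
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = B * H * W
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * (var * n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
    out = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def backward(g):
        ggamma = (g * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        gbeta = g.sum(axis=(0, 2, 3)).astype(np.float32)
        gxhat = g * gamma.data.reshape(1, C, 1, 1)
        if training:
            n = B * H * W
            gx = (inv.reshape(1, C, 1, 1) / n) * (
                n * gxhat
                - gxhat.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True))
        else:
            gx = gxhat * inv.reshape(1, C, 1, 1)
        return (gx.astype(np.float32), ggamma, gbeta)

    return _make(out, (x, gamma, beta), backward)


def max_pool2d_same(x: Tensor, k: int = 5) -> Tensor:
    """Stride-1 max pooling with "same" zero... -inf padding (spatial size
    preserved) — the pooling used by the SPPF pyramid."""
    B, C, H, W = x.shape
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    sb, sc, sh, sw = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (B, C, H, W, k, k), (sb, sc, sh, sw, sh, sw), writeable=False)
    flat = win.reshape(B, C, H, W, k * k)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gxp = np.zeros_like(xp, dtype=np.float32)
        ii, jj = np.divmod(arg, k)
        bi, ci, hi, wi = np.indices((B, C, H, W), sparse=False)
        np.add.at(gxp, (bi, ci, hi + ii, wi + jj), g)
        return (gxp[:, :, p:p + H, p:p + W],)

    return _make(out, (x,), backward)


def upsample_nearest(x: Tensor, scale: int = 2) -> Tensor:
    out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)
    B, C, H, W = x.shape

    def backward(g):
        g = g.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5))
        return (g.astype(np.float32),)

    return _make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C) spatial mean (the squeeze step of channel attention)."""
    B, C, H, W = x.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        return (np.broadcast_to(g[:, :, None, None], x.shape).astype(np.float32) / (H * W),)

    return _make(out, (x,), backward)
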
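"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operator set needed by the segmentation network:
elementwise arithmetic, matmul, reductions, reshaping, padding/cropping,
concatenation, 3D convolution (stride 1, arbitrary dilation, "same"
padding), non-overlapping transposed 3D convolution, average pooling and
the usual nonlinearities.  All tensors are float32.

The engine is deliberately small: a ``Tensor`` wraps an ndarray, every op
records a closure that propagates gradients to its parents, and
``Tensor.backward`` runs the closures in reverse topological order.
"""

from __future__ import annotations

import numpy as np

_F32 = np.float32


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != _F32:
        a = a.astype(_F32)
    return a


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(_F32, copy=True)
        else:
            self.grad += g

    # -- graph plumbing --------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(_as_f32(grad))
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, power(_wrap(other), -1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __pow__(self, p):
        return power(self, p)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def transpose(self, axes):
        return transpose(self, axes)

    @property
    def T(self):
        return transpose(self, None)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient `g` down to `shape` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- elementwise ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a = _wrap(a)
    if isinstance(b, (int, float)):
        s = _F32(b)
        out_data = a.data * s

        def backward_s(g):
            a._accum(g * s)

        return _make(out_data, (a,), backward_s)
    b = _wrap(b)
    out_data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a, p) -> Tensor:
    a = _wrap(a)
    p = float(p)
    out_data = a.data ** _F32(p)

    def backward(g):
        a._accum(g * _F32(p) * a.data ** _F32(p - 1.0))

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accum(g * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = _wrap(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return _make(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    a = _wrap(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        a._accum(g * _F32(0.5) / out_data)

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    out_data = np.maximum(a.data, _F32(0))

    def backward(g):
        a._accum(g * (out_data > 0))

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    out_data = _F32(1.0) / (_F32(1.0) + np.exp(-a.data))

    def backward(g):
        a._accum(g * out_data * (_F32(1.0) - out_data))

    return _make(out_data, (a,), backward)


def softplus(a) -> Tensor:
    a = _wrap(a)
    # stable: softplus(x) = max(x, 0) + log1p(exp(-|x|))
    out_data = np.maximum(a.data, 0) + np.log1p(np.exp(-np.abs(a.data)))

    def backward(g):
        a._accum(g / (_F32(1.0) + np.exp(-a.data)))

    return _make(out_data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp with zero gradient outside [lo, hi]."""
    a = _wrap(a)
    out_data = np.clip(a.data, _F32(lo), _F32(hi))
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        a._accum(g * mask)

    return _make(out_data, (a,), backward)


# -- reductions / shape --------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape))

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    in_shape = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(in_shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    out_data = np.ascontiguousarray(a.data.transpose(axes))
    inv = None if axes is None else np.argsort(axes)

    def backward(g):
        a._accum(np.ascontiguousarray(g.transpose(inv)))

    return _make(out_data, (a,), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(gpart)

    return _make(out_data, tuple(tensors), backward)


def pad_spatial(a, pads) -> Tensor:
    """Zero-pad a rank-5 tensor on the last three axes.

    pads: ((z0,z1),(y0,y1),(x0,x1))
    """
    a = _wrap(a)
    full = ((0, 0), (0, 0)) + tuple(pads)
    out_data = np.pad(a.data, full)
    sl = tuple(slice(p0, out_data.shape[i] - p1) for i, (p0, p1) in enumerate(full))

    def backward(g):
        a._accum(g[sl])

    return _make(out_data, (a,), backward)


def crop_spatial(a, crops) -> Tensor:
    """Crop a rank-5 tensor on the last three axes; crops like pad_spatial."""
    a = _wrap(a)
    full = ((0, 0), (0, 0)) + tuple(crops)
    sl = tuple(slice(c0, a.data.shape[i] - c1) for i, (c0, c1) in enumerate(full))
    out_data = np.ascontiguousarray(a.data[sl])

    def backward(g):
        buf = np.zeros_like(a.data)
        buf[sl] = g
        a._accum(buf)

    return _make(out_data, (a,), backward)


def broadcast_spatial(a, spatial_shape) -> Tensor:
    """Broadcast (B, C, 1, 1, 1) to (B, C, *spatial_shape)."""
    a = _wrap(a)
    b, c = a.data.shape[:2]
    out_data = np.broadcast_to(a.data, (b, c) + tuple(spatial_shape)).copy()

    def backward(g):
        a._accum(g.sum(axis=(2, 3, 4), keepdims=True))

    return _make(out_data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def backward(g):
        a._accum(g @ b.data.T)
        b._accum(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def instance_norm(x, gamma, beta, eps: float = 1e-5) -> Tensor:
    """Fused per-(batch, channel) normalization over the spatial axes of a
    rank-5 tensor, with affine parameters shaped (1, C, 1, 1, 1)."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    axes = (2, 3, 4)
    nsp = int(np.prod(x.data.shape[2:]))
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + _F32(eps))
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def backward(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3, 4), keepdims=True))
        beta._accum(g.sum(axis=(0, 2, 3, 4), keepdims=True))
        gh = g * gamma.data
        m1 = gh.mean(axis=axes, keepdims=True)
        m2 = (gh * xhat).mean(axis=axes, keepdims=True)
        x._accum(inv * (gh - m1 - xhat * m2))

    return _make(out_data, (x, gamma, beta), backward)


# -- convolution ---------------------------------------------------------

def conv3d(x, w, b=None, dilation: int = 1) -> Tensor:
    """3D convolution, stride 1, "same" zero padding.

    x: (B, Ci, D, H, W); w: (Co, Ci, kd, kh, kw); b: (Co,) or None.
    Implemented as one GEMM per kernel tap so peak memory stays low.
    """
    x = _wrap(x)
    w = _wrap(w)
    B, Ci, D, H, W = x.data.shape
    Co, Ci2, kd, kh, kw = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"conv3d channel mismatch: input {Ci}, weight {Ci2}")
    d = int(dilation)
    pz, py, px = d * (kd - 1) // 2, d * (kh - 1) // 2, d * (kw - 1) // 2
    N = B * D * H * W

    if kd == kh == kw == 1:
        xm = x.data.transpose(1, 0, 2, 3, 4).reshape(Ci, N)
        wm = w.data.reshape(Co, Ci)
        om = wm @ xm
        if b is not None:
            om += b.data[:, None]
        out_data = om.reshape(Co, B, D, H, W).transpose(1, 0, 2, 3, 4)

        def backward1(g):
            gm = g.transpose(1, 0, 2, 3, 4).reshape(Co, N)
            w._accum((gm @ xm.T).reshape(w.data.shape))
            if b is not None:
                b._accum(gm.sum(axis=1))
            gx = wm.T @ gm
            x._accum(gx.reshape(Ci, B, D, H, W).transpose(1, 0, 2, 3, 4))

        parents = (x, w) if b is None else (x, w, b)
        return _make(out_data, parents, backward1)

    xp = np.pad(x.data, ((0, 0), (0, 0), (pz, pz), (py, py), (px, px)))
    taps = [(a_, b_, c_) for a_ in range(kd) for b_ in range(kh) for c_ in range(kw)]

    om = np.zeros((Co, N), dtype=_F32)
    for t, (ta, tb, tc) in enumerate(taps):
        sl = xp[:, :, ta * d:ta * d + D, tb * d:tb * d + H, tc * d:tc * d + W]
        xm = sl.transpose(1, 0, 2, 3, 4).reshape(Ci, N)
        om += w.data[:, :, ta, tb, tc] @ xm
    if b is not None:
        om += b.data[:, None]
    out_data = om.reshape(Co, B, D, H, W).transpose(1, 0, 2, 3, 4)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3, 4)).reshape(Co, N)
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for t, (ta, tb, tc) in enumerate(taps):
            sl = xp[:, :, ta * d:ta * d + D, tb * d:tb * d + H, tc * d:tc * d + W]
            xm = sl.transpose(1, 0, 2, 3, 4).reshape(Ci, N)
            gw[:, :, ta, tb, tc] = gm @ xm.T
            gsl = (w.data[:, :, ta, tb, tc].T @ gm).reshape(Ci, B, D, H, W)
            gxp[:, :, ta * d:ta * d + D, tb * d:tb * d + H, tc * d:tc * d + W] += \
                gsl.transpose(1, 0, 2, 3, 4)
        w._accum(gw)
        if b is not None:
            b._accum(gm.sum(axis=1))
        x._accum(gxp[:, :, pz:pz + D, py:py + H, px:px + W])

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def conv_transpose3d(x, w, b=None, factors=(2, 2, 2)) -> Tensor:
    """Transposed 3D convolution with kernel == stride (non-overlapping).

    x: (B, Ci, D, H, W); w: (Ci, Co, fz, fy, fx); output spatial dims are
    multiplied by the factors.  Each output voxel receives exactly one tap.
    """
    x = _wrap(x)
    w = _wrap(w)
    B, Ci, D, H, W = x.data.shape
    Ci2, Co, fz, fy, fx = w.data.shape
    if Ci != Ci2:
        raise ValueError(f"conv_transpose3d channel mismatch: {Ci} vs {Ci2}")
    if (fz, fy, fx) != tuple(factors):
        raise ValueError("kernel must equal the upsampling factors")
    N = B * D * H * W
    xm = x.data.transpose(1, 0, 2, 3, 4).reshape(Ci, N)
    out_data = np.empty((B, Co, D * fz, H * fy, W * fx), dtype=_F32)
    for ta in range(fz):
        for tb in range(fy):
            for tc in range(fx):
                om = w.data[:, :, ta, tb, tc].T @ xm  # (Co, N)
                if b is not None:
                    om = om + b.data[:, None]
                out_data[:, :, ta::fz, tb::fy, tc::fx] = \
                    om.reshape(Co, B, D, H, W).transpose(1, 0, 2, 3, 4)

    def backward(g):
        gx = np.zeros((Ci, N), dtype=_F32)
        gw = np.zeros_like(w.data)
        gb = np.zeros(Co, dtype=_F32) if b is not None else None
        for ta in range(fz):
            for tb in range(fy):
                for tc in range(fx):
                    gm = np.ascontiguousarray(
                        g[:, :, ta::fz, tb::fy, tc::fx].transpose(1, 0, 2, 3, 4)
                    ).reshape(Co, N)
                    gx += w.data[:, :, ta, tb, tc] @ gm
                    gw[:, :, ta, tb, tc] = xm @ gm.T
                    if gb is not None:
                        gb += gm.sum(axis=1)
        x._accum(gx.reshape(Ci, B, D, H, W).transpose(1, 0, 2, 3, 4))
        w._accum(gw)
        if b is not None:
            b._accum(gb)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out_data, parents, backward)


def avg_pool3d(x, factors) -> Tensor:
    """Average pooling by integer factors; spatial dims must be divisible."""
    x = _wrap(x)
    B, C, D, H, W = x.data.shape
    fz, fy, fx = factors
    if D % fz or H % fy or W % fx:
        raise ValueError(f"spatial dims {(D, H, W)} not divisible by {factors}")
    r = x.data.reshape(B, C, D // fz, fz, H // fy, fy, W // fx, fx)
    out_data = r.mean(axis=(3, 5, 7))
    inv = _F32(1.0 / (fz * fy * fx))

    def backward(g):
        ge = g[:, :, :, None, :, None, :, None] * inv
        gx = np.broadcast_to(ge, (B, C, D // fz, fz, H // fy, fy, W // fx, fx))
        x._accum(gx.reshape(B, C, D, H, W))

    return _make(out_data, (x,), backward)


def scan(a, u) -> Tensor:
    """Linear recurrence h_t = a_t * h_{t-1} + u_t over axis 0.

    a, u: (L, n) tensors; h_0 = 0.  Backward runs the adjoint recurrence
    in reverse time.
    """
    a, u = _wrap(a), _wrap(u)
    L, n = u.data.shape
    h = np.empty((L, n), dtype=_F32)
    prev = np.zeros(n, dtype=_F32)
    for t in range(L):
        prev = a.data[t] * prev + u.data[t]
        h[t] = prev
    if not np.all(np.isfinite(h)):
        bad = int(np.argwhere(~np.isfinite(h).all(axis=1))[0, 0])
        raise FloatingPointError(f"state-space scan diverged at step t={bad}")

    def backward(g):
        gu = np.empty_like(g)
        ga = np.empty_like(g)
        acc = np.zeros(n, dtype=_F32)
        for t in range(L - 1, -1, -1):
            acc = g[t] + (a.data[t + 1] * acc if t + 1 < L else 0.0)
            gu[t] = acc
            ga[t] = acc * (h[t - 1] if t > 0 else 0.0)
        a._accum(ga)
        u._accum(gu)

    return _make(h, (a, u), backward)
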
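"""Finite-difference and oracle checks for the autodiff engine."""

import numpy as np
import pytest

from hepaseg import autograd as ag
from hepaseg.autograd import Tensor


def numeric_grad(f, x, eps=1e-3):
    """Central finite differences of a scalar function of an ndarray."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


@pytest.mark.parametrize("op,np_op", [
    (ag.relu, lambda a: np.maximum(a, 0)),
    (ag.sigmoid, lambda a: 1 / (1 + np.exp(-a))),
    (ag.exp, np.exp),
    (ag.softplus, lambda a: np.log1p(np.exp(a))),
])
def test_elementwise_forward_and_grad(op, np_op, rng):
    x = rng.normal(0, 1, size=(3, 4)).astype(np.float32)
    t = Tensor(x, requires_grad=True)
    out = op(t).sum()
    np.testing.assert_allclose(op(Tensor(x)).data, np_op(x), rtol=1e-5, atol=1e-6)
    out.backward()
    num = numeric_grad(lambda a: float(np_op(a.astype(np.float64)).sum()), x)
    np.testing.assert_allclose(t.grad, num, rtol=1e-2, atol=1e-3)


def test_matmul_grad(rng):
    a = Tensor(rng.normal(size=(3, 4)).astype(np.float32), requires_grad=True)
    b = Tensor(rng.normal(size=(4, 2)).astype(np.float32), requires_grad=True)
    ((a @ b) ** 2.0).sum().backward()
    np.testing.assert_allclose(a.grad, 2 * (a.data @ b.data) @ b.data.T,
                               rtol=1e-4, atol=1e-5)


def test_broadcast_add_grad(rng):
    a = Tensor(rng.normal(size=(2, 3, 4)).astype(np.float32), requires_grad=True)
    b = Tensor(rng.normal(size=(1, 3, 1)).astype(np.float32), requires_grad=True)
    (ag.add(a, b) * 2.0).sum().backward()
    assert b.grad.shape == (1, 3, 1)
    np.testing.assert_allclose(b.grad, np.full((1, 3, 1), 16.0))


def test_conv3d_matches_scipy(rng):
    from scipy.ndimage import correlate
    x = rng.normal(size=(1, 1, 5, 6, 7)).astype(np.float32)
    w = rng.normal(size=(1, 1, 3, 3, 3)).astype(np.float32)
    out = ag.conv3d(Tensor(x), Tensor(w)).data[0, 0]
    ref = correlate(x[0, 0].astype(np.float64), w[0, 0].astype(np.float64),
                    mode="constant")
    np.testing.assert_allclose(out, ref, rtol=1e-4, atol=1e-5)


def test_conv3d_grad_finite_difference(rng):
    x = rng.normal(size=(1, 2, 3, 4, 4)).astype(np.float32)
    w = rng.normal(size=(3, 2, 3, 3, 3)).astype(np.float32)
    b = rng.normal(size=3).astype(np.float32)
    tx, tw, tb = (Tensor(v, requires_grad=True) for v in (x, w, b))
    (ag.conv3d(tx, tw, tb) ** 2.0).sum().backward()

    def f_x(a):
        return float((ag.conv3d(Tensor(a), Tensor(w), Tensor(b)).data ** 2).sum())

    np.testing.assert_allclose(tx.grad, numeric_grad(f_x, x), rtol=6e-2, atol=0.5)

    def f_w(a):
        return float((ag.conv3d(Tensor(x), Tensor(a), Tensor(b)).data ** 2).sum())

    np.testing.assert_allclose(tw.grad, numeric_grad(f_w, w), rtol=6e-2, atol=0.5)


def test_conv3d_dilation_receptive_field(rng):
    # impulse through a k=3 d=2 conv spans 5 voxels per axis
    x = np.zeros((1, 1, 9, 9, 9), dtype=np.float32)
    x[0, 0, 4, 4, 4] = 1.0
    w = np.ones((1, 1, 3, 3, 3), dtype=np.float32)
    out = ag.conv3d(Tensor(x), Tensor(w), dilation=2).data[0, 0]
    nz = np.argwhere(out != 0)
    ext = nz.max(axis=0) - nz.min(axis=0) + 1
    assert tuple(ext) == (5, 5, 5)


def test_conv_transpose3d_shapes_and_grad(rng):
    x = rng.normal(size=(1, 2, 2, 3, 3)).astype(np.float32)
    w = rng.normal(size=(2, 4, 2, 2, 2)).astype(np.float32)
    tx = Tensor(x, requires_grad=True)
    tw = Tensor(w, requires_grad=True)
    out = ag.conv_transpose3d(tx, tw, factors=(2, 2, 2))
    assert out.shape == (1, 4, 4, 6, 6)
    (out ** 2.0).sum().backward()

    def f(a):
        return float((ag.conv_transpose3d(Tensor(a), Tensor(w),
                                          factors=(2, 2, 2)).data ** 2).sum())

    np.testing.assert_allclose(tx.grad, numeric_grad(f, x), rtol=2e-2, atol=2e-2)


def test_avg_pool3d_and_grad(rng):
    x = rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32)
    t = Tensor(x, requires_grad=True)
    out = ag.avg_pool3d(t, (2, 2, 2))
    ref = x.reshape(1, 2, 2, 2, 2, 2, 2, 2).mean(axis=(3, 5, 7))
    np.testing.assert_allclose(out.data, ref, rtol=1e-6)
    out.sum().backward()
    np.testing.assert_allclose(t.grad, np.full_like(x, 1 / 8))


def test_instance_norm_forward_and_grad(rng):
    x = rng.normal(2.0, 3.0, size=(2, 3, 4, 4, 4)).astype(np.float32)
    gamma = np.ones((1, 3, 1, 1, 1), dtype=np.float32) * 1.5
    beta = np.full((1, 3, 1, 1, 1), 0.25, dtype=np.float32)
    t = Tensor(x, requires_grad=True)
    tg = Tensor(gamma, requires_grad=True)
    tb = Tensor(beta, requires_grad=True)
    out = ag.instance_norm(t, tg, tb)
    mu = x.mean(axis=(2, 3, 4), keepdims=True)
    sd = x.std(axis=(2, 3, 4), keepdims=True)
    np.testing.assert_allclose(out.data, (x - mu) / np.sqrt(sd ** 2 + 1e-5)
                               * gamma + beta, rtol=1e-4, atol=1e-4)
    loss = (out ** 2.0).sum()
    loss.backward()

    def f(a):
        a = a.astype(np.float64)
        m = a.mean(axis=(2, 3, 4), keepdims=True)
        v = a.var(axis=(2, 3, 4), keepdims=True)
        y = (a - m) / np.sqrt(v + 1e-5) * gamma + beta
        return float((y ** 2).sum())

    np.testing.assert_allclose(t.grad, numeric_grad(f, x), rtol=5e-2, atol=5e-2)


def test_scan_matches_unrolled(rng):
    L, n = 12, 3
    a = rng.uniform(0.1, 0.9, size=(L, n)).astype(np.float32)
    u = rng.normal(size=(L, n)).astype(np.float32)
    h = ag.scan(Tensor(a), Tensor(u)).data
    ref = np.zeros((L, n))
    prev = np.zeros(n)
    for t in range(L):
        prev = a[t] * prev + u[t]
        ref[t] = prev
    np.testing.assert_allclose(h, ref, rtol=1e-5, atol=1e-6)


def test_scan_grad_finite_difference(rng):
    L, n = 6, 2
    a = rng.uniform(0.2, 0.8, size=(L, n)).astype(np.float32)
    u = rng.normal(size=(L, n)).astype(np.float32)
    ta, tu = Tensor(a, requires_grad=True), Tensor(u, requires_grad=True)
    (ag.scan(ta, tu) ** 2.0).sum().backward()

    def f_a(v):
        return float((ag.scan(Tensor(v), Tensor(u)).data ** 2).sum())

    def f_u(v):
        return float((ag.scan(Tensor(a), Tensor(v)).data ** 2).sum())

    np.testing.assert_allclose(ta.grad, numeric_grad(f_a, a), rtol=2e-2, atol=2e-2)
    np.testing.assert_allclose(tu.grad, numeric_grad(f_u, u), rtol=2e-2, atol=2e-2)


def test_detach_blocks_gradient(rng):
    x = Tensor(rng.normal(size=(3,)).astype(np.float32), requires_grad=True)
    y = (x.detach() * 2.0 + x).sum()
    y.backward()
    np.testing.assert_allclose(x.grad, np.ones(3))


def test_concat_pad_crop_roundtrip(rng):
    x = rng.normal(size=(1, 2, 3, 3, 3)).astype(np.float32)
    t = Tensor(x, requires_grad=True)
    padded = ag.pad_spatial(t, ((1, 1), (0, 2), (1, 0)))
    cropped = ag.crop_spatial(padded, ((1, 1), (0, 2), (1, 0)))
    np.testing.assert_array_equal(cropped.data, x)
    cropped.sum().backward()
    np.testing.assert_allclose(t.grad, np.ones_like(x))
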
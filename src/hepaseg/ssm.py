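"""Selective state-space bottleneck: flatten the feature volume to a
sequence, run the gated linear recurrence

    h_t = a(x_t) ⊙ h_{t−1} + W_b x_t,   y_t = C_out h_t,

and reshape back with a residual connection.  The input-dependent decay
gate a(x_t) = exp(−softplus(W_a x_t + b_a)) lies in (0, 1)^n, so the
recurrence is contractive and matches a closed-form unrolled sum exactly.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Linear, Module


def flatten_to_sequence(x: Tensor) -> tuple[list[Tensor], tuple]:
    """(B, d, D, H, W) -> per-batch-item (L, d) sequences, L = D·H·W.

    Order is depth-major: z varies slowest, then y, then x, so each
    in-plane block is contiguous and z-blocks follow each other.
    """
    b, d, dd, hh, ww = x.shape
    perm = x.transpose((0, 2, 3, 4, 1))           # (B, D, H, W, d)
    flat = perm.reshape((b, dd * hh * ww, d))
    seqs = [_select_batch(flat, i) for i in range(b)]
    return seqs, x.shape


def _select_batch(flat: Tensor, i: int) -> Tensor:
    out = Tensor(flat.data[i])

    def backward(g):
        buf = np.zeros_like(flat.data)
        buf[i] = g
        flat._accum(buf)

    if flat.requires_grad or flat._parents:
        out._parents = (flat,)
        out._backward = backward
        out.requires_grad = flat.requires_grad
    return out


def sequence_to_volume(ys: list[Tensor], shape) -> Tensor:
    b, d, dd, hh, ww = shape
    stacked = ag.concat([y.reshape((1, dd * hh * ww, d)) for y in ys], axis=0)
    return stacked.reshape((b, dd, hh, ww, d)).transpose((0, 4, 1, 2, 3))


class SSMParams(Module):
    """Parameters of the recurrence; ``gate_mode='ones'`` bypasses the decay
    gate (a_t ≡ 1) for limit-case testing."""

    def __init__(self, rng: np.random.Generator, state_size: int = 16,
                 dim: int = 64, gate_mode: str = "softplus",
                 bidirectional: bool = False):
        if state_size < 1 or dim < 1:
            raise ValueError("state_size and dim must be >= 1")
        if gate_mode not in ("softplus", "ones"):
            raise ValueError(f"unknown gate_mode {gate_mode!r}")
        self.state_size = state_size
        self.dim = dim
        self.gate_mode = gate_mode
        self.bidirectional = bidirectional
        self.gate = Linear(rng, dim, state_size)          # W_a, b_a
        self.inproj = Linear(rng, dim, state_size)        # W_b (bias kept zero)
        self.inproj.bias.requires_grad = False
        self.outproj = Linear(rng, state_size, dim)       # C_out (bias zero)
        self.outproj.bias.requires_grad = False
        if bidirectional:
            self.gate_rev = Linear(rng, dim, state_size)
            self.inproj_rev = Linear(rng, dim, state_size)
            self.inproj_rev.bias.requires_grad = False
            self.outproj_rev = Linear(rng, state_size, dim)
            self.outproj_rev.bias.requires_grad = False


def _reverse(seq: Tensor) -> Tensor:
    out = Tensor(seq.data[::-1].copy())

    def backward(g):
        seq._accum(g[::-1].copy())

    if seq.requires_grad or seq._parents:
        out._parents = (seq,)
        out._backward = backward
        out.requires_grad = seq.requires_grad
    return out


def ssm_scan(seq: Tensor, params: SSMParams, h0: np.ndarray | None = None) -> Tensor:
    """Run the recurrence over an (L, d) sequence; returns the (L, d) output.

    h0 defaults to the zero state; a nonzero h0 is folded in by prepending
    it to the input drive (h_1 = a_1 ⊙ h_0 + u_1).
    """
    if seq.shape[1] != params.dim:
        raise ValueError(f"expected dim {params.dim}, got {seq.shape[1]}")
    u = params.inproj(seq)                                 # (L, n)
    if params.gate_mode == "ones":
        a = Tensor(np.ones_like(u.data))
    else:
        a = ag.exp(-ag.softplus(params.gate(seq)))         # in (0,1)
    if h0 is not None:
        h0 = np.asarray(h0, dtype=np.float32)
        first = a.data[0] * h0
        u = u + Tensor(np.concatenate([first[None], np.zeros(
            (seq.shape[0] - 1, params.state_size), dtype=np.float32)]))
    h = ag.scan(a, u)
    return params.outproj(h)


def global_repr_forward(x: Tensor, params: SSMParams) -> Tensor:
    """Bottleneck module: reshape → scan → reshape back, plus a residual."""
    seqs, shape = flatten_to_sequence(x)
    ys = []
    for s in seqs:
        y = ssm_scan(s, params)
        if params.bidirectional:
            r = _reverse(s)
            u = params.inproj_rev(r)
            a = ag.exp(-ag.softplus(params.gate_rev(r)))
            yr = params.outproj_rev(ag.scan(a, u))
            y = y + _reverse(yr)
        ys.append(y)
    return sequence_to_volume(ys, shape) + x
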
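"""Minimal reverse-mode automatic differentiation on numpy arrays.

Array-valued tape autodiff sized for small volumetric networks: a
:class:`Tensor` wraps a float32 ndarray, records its parents and a backward
closure, and :meth:`Tensor.backward` propagates gradients in reverse
topological order.  Only the operations needed by the inception-U-Net are
provided (N-dimensional "same" convolution, stride-2 transposed convolution,
max pooling, instance normalization, ReLU/sigmoid, channel concatenation,
dropout, and the soft-Dice / cross-entropy losses).  Tensors carry no batch
axis: a value is shaped ``(channels, *spatial)`` and one volume is processed
per step.

Every backward pass here is verified against central finite differences in
the test suite.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["Tensor", "Parameter"]

_SLC = slice(None)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward(t.grad)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def convnd(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same'-padded N-D convolution (cross-correlation) with odd kernels.

    ``x``: (C_in, *S); ``w``: (C_out, C_in, *K); output (C_out, *S).
    Implemented as a loop over kernel offsets, each a single GEMM, which keeps
    peak memory at one padded copy of the input.
    """
    cin = x.shape[0]
    cout, wcin = w.shape[:2]
    kernel = w.shape[2:]
    spatial = x.shape[1:]
    if wcin != cin:
        raise ValueError(f"kernel expects {wcin} input channels, got {cin}")
    if any(k % 2 == 0 for k in kernel):
        raise ValueError(f"convnd requires odd kernels, got {kernel}")
    pads = [(0, 0)] + [(k // 2, k // 2) for k in kernel]
    xp = np.pad(x.data, pads)
    out = np.zeros((cout,) + spatial, dtype=np.float32)
    offsets = list(itertools.product(*[range(k) for k in kernel]))
    for off in offsets:
        sl = (_SLC,) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
        out += np.tensordot(w.data[(_SLC, _SLC) + off], xp[sl], axes=1)
    if b is not None:
        out += b.data.reshape((cout,) + (1,) * len(spatial))

    parents = (x, w) + ((b,) if b is not None else ())
    res = Tensor(out, parents=parents)

    def backward(g):
        sp_axes = tuple(range(1, 1 + len(spatial)))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=sp_axes))
        dxp = np.zeros_like(xp) if x.requires_grad else None
        if w.requires_grad:
            dw = np.zeros_like(w.data)
        for off in offsets:
            sl = (_SLC,) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
            if w.requires_grad:
                dw[(_SLC, _SLC) + off] = np.tensordot(g, xp[sl], axes=(sp_axes, sp_axes))
            if dxp is not None:
                dxp[sl] += np.tensordot(w.data[(_SLC, _SLC) + off].T, g, axes=1)
        if w.requires_grad:
            w._accumulate(dw)
        if dxp is not None:
            core = (_SLC,) + tuple(slice(p[0], p[0] + s) for p, s in zip(pads[1:], spatial))
            x._accumulate(dxp[core])

    res._backward = backward
    return res


def conv_transpose_nd(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-2, kernel-2 transposed convolution doubling every spatial axis.

    ``w``: (C_out, C_in, 2, ..., 2).  With kernel == stride, each output voxel
    receives exactly one kernel tap, so the op is a channel mix scattered onto
    an upsampled grid.
    """
    cin = x.shape[0]
    cout = w.shape[0]
    spatial = x.shape[1:]
    rank = len(spatial)
    out = np.zeros((cout,) + tuple(2 * s for s in spatial), dtype=np.float32)
    offsets = list(itertools.product(range(2), repeat=rank))
    for off in offsets:
        sl = (_SLC,) + tuple(slice(o, None, 2) for o in off)
        out[sl] = np.tensordot(w.data[(_SLC, _SLC) + off], x.data, axes=1)
    if b is not None:
        out += b.data.reshape((cout,) + (1,) * rank)
    parents = (x, w) + ((b,) if b is not None else ())
    res = Tensor(out, parents=parents)

    def backward(g):
        sp_axes = tuple(range(1, 1 + rank))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=sp_axes))
        dx = np.zeros_like(x.data) if x.requires_grad else None
        if w.requires_grad:
            dw = np.zeros_like(w.data)
        for off in offsets:
            sl = (_SLC,) + tuple(slice(o, None, 2) for o in off)
            gs = g[sl]
            if w.requires_grad:
                dw[(_SLC, _SLC) + off] = np.tensordot(gs, x.data, axes=(sp_axes, sp_axes))
            if dx is not None:
                dx += np.tensordot(w.data[(_SLC, _SLC) + off].T, gs, axes=1)
        if w.requires_grad:
            w._accumulate(dw)
        if dx is not None:
            x._accumulate(dx)

    res._backward = backward
    return res


def maxpool_down(x: Tensor) -> Tensor:
    """2x downsampling max pool (kernel 2, stride 2) on every spatial axis."""
    c = x.shape[0]
    spatial = x.shape[1:]
    rank = len(spatial)
    if any(s % 2 for s in spatial):
        raise ValueError(f"maxpool_down requires even spatial dims, got {spatial}")
    half = tuple(s // 2 for s in spatial)
    split = (c,) + tuple(itertools.chain.from_iterable((s // 2, 2) for s in spatial))
    perm = (0,) + tuple(1 + 2 * i for i in range(rank)) + tuple(2 + 2 * i for i in range(rank))
    windows = x.data.reshape(split).transpose(perm).reshape((c,) + half + (2 ** rank,))
    arg = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]
    res = Tensor(out, parents=(x,))

    def backward(g):
        gw = np.zeros((c,) + half + (2 ** rank,), dtype=np.float32)
        np.put_along_axis(gw, arg[..., None], g[..., None], axis=-1)
        inv = np.argsort(perm)
        dx = gw.reshape((c,) + half + (2,) * rank).transpose(inv).reshape(x.data.shape)
        x._accumulate(dx)

    res._backward = backward
    return res


def maxpool_same(x: Tensor, size: int = 3) -> Tensor:
    """Stride-1 max pool with 'same' padding (the pooled inception branch)."""
    c = x.shape[0]
    spatial = x.shape[1:]
    rank = len(spatial)
    pad = size // 2
    xp = np.pad(x.data, [(0, 0)] + [(pad, pad)] * rank, constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (size,) * rank, axis=tuple(range(1, 1 + rank)))
    win = win.reshape((c,) + spatial + (size ** rank,))
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
    res = Tensor(out, parents=(x,))

    def backward(g):
        offs = np.unravel_index(arg, (size,) * rank)
        idx = np.indices((c,) + spatial, sparse=False)
        dxp = np.zeros_like(xp, dtype=np.float32)
        coords = (idx[0],) + tuple(idx[1 + a] + offs[a] for a in range(rank))
        np.add.at(dxp, coords, g)
        core = (_SLC,) + (slice(pad, -pad),) * rank
        x._accumulate(dxp[core])

    res._backward = backward
    return res


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)
    res = Tensor(out, parents=(x,))

    def backward(g):
        x._accumulate(g * (x.data > 0))

    res._backward = backward
    return res


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data.astype(np.float64)))
    out = out.astype(np.float32)
    res = Tensor(out, parents=(x,))

    def backward(g):
        x._accumulate(g * out * (1.0 - out))

    res._backward = backward
    return res


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes, with affine rescale."""
    rank = x.data.ndim - 1
    sp_axes = tuple(range(1, 1 + rank))
    mu = x.data.mean(axis=sp_axes, keepdims=True)
    var = x.data.var(axis=sp_axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gshape = (-1,) + (1,) * rank
    out = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)
    res = Tensor(out, parents=(x, gamma, beta))

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=sp_axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=sp_axes))
        if x.requires_grad:
            gx = g * gamma.data.reshape(gshape)
            m1 = gx.mean(axis=sp_axes, keepdims=True)
            m2 = (gx * xhat).mean(axis=sp_axes, keepdims=True)
            x._accumulate(inv * (gx - m1 - xhat * m2))

    res._backward = backward
    return res


def concat(tensors) -> Tensor:
    """Concatenate along the channel axis."""
    tensors = list(tensors)
    out = np.concatenate([t.data for t in tensors], axis=0)
    res = Tensor(out, parents=tuple(tensors))
    sizes = [t.shape[0] for t in tensors]
    bounds = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, bounds[:-1], bounds[1:]):
            if t.requires_grad:
                t._accumulate(g[lo:hi])

    res._backward = backward
    return res


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p == 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)
    res = Tensor(x.data * keep, parents=(x,))

    def backward(g):
        x._accumulate(g * keep)

    res._backward = backward
    return res


def soft_dice_loss_t(pred: Tensor, target: np.ndarray, eps: float = 1e-12) -> Tensor:
    """1 - soft Dice with the squared-sum denominator, as a graph node.

    Dice = 2 Σ p·g / (Σ p² + Σ g²); on binary p this reduces to
    2TP / (2TP + FP + FN).
    """
    g = np.asarray(target, dtype=np.float32)
    if g.shape != pred.shape:
        raise ValueError(f"prediction/target shape mismatch: {pred.shape} vs {g.shape}")
    num = 2.0 * float((pred.data * g).sum())
    den = float((pred.data ** 2).sum() + (g ** 2).sum())
    if den == 0.0:
        # both prediction and target identically zero: perfect agreement
        return Tensor(0.0, parents=(pred,), backward=lambda gr: None)
    loss = 1.0 - num / (den + eps)
    res = Tensor(loss, parents=(pred,))

    def backward(gr):
        if pred.requires_grad:
            d = -(2.0 * g * (den + eps) - num * 2.0 * pred.data) / (den + eps) ** 2
            pred._accumulate(float(gr) * d)

    res._backward = backward
    return res


def bce_loss_t(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy on probabilities (clipped away from {0,1})."""
    g = np.asarray(target, dtype=np.float32)
    if g.shape != pred.shape:
        raise ValueError(f"prediction/target shape mismatch: {pred.shape} vs {g.shape}")
    p = np.clip(pred.data, eps, 1.0 - eps)
    n = p.size
    loss = -float((g * np.log(p) + (1.0 - g) * np.log(1.0 - p)).sum()) / n
    res = Tensor(loss, parents=(pred,))

    def backward(gr):
        if pred.requires_grad:
            inside = (pred.data > eps) & (pred.data < 1.0 - eps)
            d = (-(g / p) + (1.0 - g) / (1.0 - p)) / n * inside
            pred._accumulate(float(gr) * d)

    res._backward = backward
    return res
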
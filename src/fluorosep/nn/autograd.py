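"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations the package's three networks need are implemented:
same-padding stride-1 N-D convolution (im2col via stride tricks), block max
pooling, kernel-equals-stride transposed convolution for upsampling, dense
layers, ReLU, channel concatenation, and the L1+L2 training losses.  All
tensors are float32; every op registers an explicit backward closure and
``Tensor.backward`` runs a topological sweep.

This exists because the execution environment provides no deep-learning
framework; the networks trained here are small enough that BLAS-backed
im2col convolutions are adequate on one CPU.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "add", "mul_const", "matmul", "relu", "reshape", "concat",
           "conv_nd", "maxpool_nd", "upconv_nd", "take_rows", "mean_axis0",
           "sub", "mixed_norm_rows", "scalar_sum", "scalar_scale", "l1l2_loss"]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
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
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            parent_grads = t._backward(g)
            for p, pg in zip(t._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                key = id(p)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    def detach(self):
        return Tensor(self.data)


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    return Tensor(out_data, _parents=(a, b),
                  _backward=lambda g: (_unbroadcast(g, a.data.shape),
                                       _unbroadcast(g, b.data.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data
    return Tensor(out_data, _parents=(a, b),
                  _backward=lambda g: (_unbroadcast(g, a.data.shape),
                                       -_unbroadcast(g, b.data.shape)))


def mul_const(a: Tensor, c) -> Tensor:
    c = np.asarray(c, dtype=np.float32)
    return Tensor(a.data * c, _parents=(a,),
                  _backward=lambda g: (_unbroadcast(g * c, a.data.shape),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data
    return Tensor(out, _parents=(a, b),
                  _backward=lambda g: (g @ b.data.T, a.data.T @ g))


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return Tensor(a.data * mask, _parents=(a,),
                  _backward=lambda g: (g * mask,))


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return Tensor(a.data.reshape(shape), _parents=(a,),
                  _backward=lambda g: (g.reshape(old),))


def concat(tensors, axis=1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, _parents=tuple(tensors), _backward=_bw)


def take_rows(a: Tensor, idx) -> Tensor:
    idx = np.asarray(idx)

    def _bw(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return (ga,)

    return Tensor(a.data[idx], _parents=(a,), _backward=_bw)


def mean_axis0(a: Tensor) -> Tensor:
    n = a.data.shape[0]
    return Tensor(a.data.mean(axis=0), _parents=(a,),
                  _backward=lambda g: (np.broadcast_to(g / n, a.data.shape).copy(),))


# ---------------------------------------------------------------------------
# convolution / pooling primitives
# ---------------------------------------------------------------------------

def _same_pad(x, kernel, nd):
    pads = [(0, 0), (0, 0)] + [(k // 2, k // 2) for k in kernel]
    return np.pad(x, pads)


def _conv_forward(x, w):
    """x: (N, C, *spatial); w: (O, C, *kernel); stride 1, same padding."""
    nd = w.ndim - 2
    kernel = w.shape[2:]
    xp = _same_pad(x, kernel, nd)
    win = sliding_window_view(xp, kernel, axis=tuple(range(2, 2 + nd)))
    # win: (N, C, *spatial, *kernel)
    axes_win = [1] + list(range(2 + nd, 2 + 2 * nd))
    axes_w = [1] + list(range(2, 2 + nd))
    y = np.tensordot(win, w, axes=(axes_win, axes_w))  # (N, *spatial, O)
    return np.ascontiguousarray(np.moveaxis(y, -1, 1)), win


def _conv_backward(x, w, win, gy):
    nd = w.ndim - 2
    kernel = w.shape[2:]
    # grad wrt weights: correlate input windows with output grad
    axes_g = [0] + list(range(2, 2 + nd))
    gw = np.tensordot(gy, win, axes=(axes_g, axes_g))  # (O, C, *kernel)
    # grad wrt input: full correlation of gy with spatially flipped w
    w_flip = w[(slice(None), slice(None)) + (slice(None, None, -1),) * nd]
    w_t = np.ascontiguousarray(np.swapaxes(w_flip, 0, 1))  # (C, O, *kernel)
    gx, _ = _conv_forward(gy, w_t)
    # same padding with odd kernels keeps shapes aligned
    return gx[(slice(None), slice(None)) + tuple(slice(0, s) for s in x.shape[2:])], gw


def conv_nd(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 convolution, 2D or 3D by kernel rank."""
    y, win = _conv_forward(x.data, w.data)
    if b is not None:
        nd = w.data.ndim - 2
        y = y + b.data.reshape((1, -1) + (1,) * nd)

    def _bw(g):
        gx, gw = _conv_backward(x.data, w.data, win, g)
        if b is None:
            return (gx, gw)
        gb = g.sum(axis=(0,) + tuple(range(2, g.ndim)))
        return (gx, gw, gb)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(y, _parents=parents, _backward=_bw)


def maxpool_nd(x: Tensor, block) -> Tensor:
    """Block max pooling; every spatial extent must divide its block size."""
    nd = len(block)
    shape = x.data.shape
    for s, bsz in zip(shape[2:], block):
        if s % bsz:
            raise ValueError(f"spatial extent {s} not divisible by pool {bsz}")
    new_sp = [s // bsz for s, bsz in zip(shape[2:], block)]
    rs_shape = [shape[0], shape[1]]
    for s, bsz in zip(new_sp, block):
        rs_shape += [s, bsz]
    r = x.data.reshape(rs_shape)
    # bring block axes last and flatten them
    perm = [0, 1] + [2 + 2 * i for i in range(nd)] + [3 + 2 * i for i in range(nd)]
    r = r.transpose(perm).reshape([shape[0], shape[1]] + new_sp + [int(np.prod(block))])
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def _bw(g):
        gr = np.zeros(r.shape, dtype=np.float32)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape([shape[0], shape[1]] + new_sp + list(block))
        inv = np.argsort(perm)
        gr = gr.transpose(inv).reshape(shape)
        return (gr,)

    return Tensor(np.ascontiguousarray(out), _parents=(x,), _backward=_bw)


def upconv_nd(x: Tensor, w: Tensor) -> Tensor:
    """Transposed convolution with kernel == stride (pure up-convolution).

    ``w`` has shape (C_in, C_out, *block); each input voxel expands to one
    output block, so forward and backward are a tensordot plus reshapes.
    """
    nd = w.data.ndim - 2
    block = w.data.shape[2:]
    N, C = x.data.shape[:2]
    sp = x.data.shape[2:]
    O = w.data.shape[1]
    y = np.tensordot(x.data, w.data, axes=([1], [0]))  # (N, *sp, O, *block)
    perm = [0, 1 + nd]
    for i in range(nd):
        perm += [1 + i, 2 + nd + i]
    y = y.transpose(perm)  # (N, O, sp0, b0, sp1, b1, ...)
    out_shape = [N, O] + [s * bsz for s, bsz in zip(sp, block)]
    y = y.reshape(out_shape)

    def _bw(g):
        inter = [N, O]
        for s, bsz in zip(sp, block):
            inter += [s, bsz]
        gr = g.reshape(inter)
        inv = np.argsort(perm)
        gr = gr.transpose(inv)  # (N, *sp, O, *block)
        ax_g = list(range(1 + nd, 2 + 2 * nd))
        gx = np.tensordot(gr, w.data, axes=(ax_g, list(range(1, 2 + nd))))
        # gx: (N, *sp, C) -> (N, C, *sp)
        gx = np.moveaxis(gx, -1, 1)
        gw = np.tensordot(x.data, gr, axes=([0] + list(range(2, 2 + nd)),
                                            [0] + list(range(1, 1 + nd))))
        return (np.ascontiguousarray(gx), gw)

    return Tensor(np.ascontiguousarray(y), _parents=(x, w), _backward=_bw)


# ---------------------------------------------------------------------------
# norms and losses
# ---------------------------------------------------------------------------

def mixed_norm_rows(a: Tensor) -> Tensor:
    """Row-wise average of L1 and L2 norms: ``(‖v‖₁ + ‖v‖₂) / 2``."""
    d = a.data
    l1 = np.abs(d).sum(axis=-1)
    l2 = np.sqrt((d * d).sum(axis=-1))
    out = 0.5 * (l1 + l2)

    def _bw(g):
        safe = np.maximum(l2, 1e-12)[..., None]
        ga = 0.5 * g[..., None] * (np.sign(d) + d / safe)
        return (ga.astype(np.float32),)

    return Tensor(out, _parents=(a,), _backward=_bw)


def scalar_sum(tensors) -> Tensor:
    tensors = list(tensors)
    out = np.float32(sum(float(t.data) for t in tensors))
    return Tensor(out, _parents=tuple(tensors),
                  _backward=lambda g: tuple(g for _ in tensors))


def scalar_scale(a: Tensor, c: float) -> Tensor:
    return mul_const(a, c)


def smean(a: Tensor) -> Tensor:
    """Mean of all elements as a scalar tensor."""
    n = a.data.size
    return Tensor(a.data.mean(), _parents=(a,),
                  _backward=lambda g: ((g / n) * np.ones_like(a.data),))


def l1l2_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Equally weighted mean-absolute plus mean-squared error."""
    t = np.asarray(target, dtype=np.float32)
    if pred.data.shape != t.shape:
        raise ValueError(f"shape mismatch {pred.data.shape} vs {t.shape}")
    d = pred.data - t
    n = d.size
    loss = np.abs(d).mean() + (d * d).mean()

    def _bw(g):
        return ((g * (np.sign(d) + 2.0 * d) / n).astype(np.float32),)

    return Tensor(np.float32(loss), _parents=(pred,), _backward=_bw)
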
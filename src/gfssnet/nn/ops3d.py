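"""Volumetric primitives: correlation (conv3d), separable linear
interpolation, and the linear state-space scan — each with a hand-written
backward pass registered on the autograd graph.

conv3d decomposes the kernel into its k^3 spatial offsets and accumulates
one BLAS matmul per offset over shifted input slices; the input gradient
reverses the same decomposition by scatter-adding into the padded volume.
"""

from __future__ import annotations

import itertools

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = ["conv3d", "interpolate", "linear_scan", "global_avg_pool3d"]


def _offsets(k: int):
    return itertools.product(range(k), range(k), range(k))


def _shift_slice(i, j, l, stride, dilation, out_shape):
    return (slice(None), slice(None),
            slice(i * dilation, i * dilation + (out_shape[0] - 1) * stride + 1, stride),
            slice(j * dilation, j * dilation + (out_shape[1] - 1) * stride + 1, stride),
            slice(l * dilation, l * dilation + (out_shape[2] - 1) * stride + 1, stride))


def _conv_fwd(xp: np.ndarray, w: np.ndarray, stride: int, dilation: int,
              groups: int, out_shape) -> np.ndarray:
    B, Cin = xp.shape[:2]
    Cout, Cg, k = w.shape[0], w.shape[1], w.shape[2]
    N = int(np.prod(out_shape))
    out = np.zeros((B, Cout, N), dtype=xp.dtype)
    depthwise = groups == Cin and Cg == 1 and Cout == Cin
    for i, j, l in _offsets(k):
        xs = xp[_shift_slice(i, j, l, stride, dilation, out_shape)]
        xs = xs.reshape(B, Cin, N)
        if groups == 1:
            out += np.matmul(w[:, :, i, j, l], xs)
        elif depthwise:
            out += w[:, 0, i, j, l][None, :, None] * xs
        else:
            gi, go = Cin // groups, Cout // groups
            for g_ in range(groups):
                out[:, g_ * go:(g_ + 1) * go] += np.matmul(
                    w[g_ * go:(g_ + 1) * go, :, i, j, l],
                    xs[:, g_ * gi:(g_ + 1) * gi])
    return out.reshape(B, Cout, *out_shape)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           padding: int | None = None, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """3D cross-correlation over (B, C, D, H, W); same-padding by default."""
    x, w = as_tensor(x), as_tensor(w)
    if x.ndim != 5:
        raise ValueError(f"conv3d expects a 5-axis input, got shape {x.shape}")
    Cout, Cg, k = w.shape[0], w.shape[1], w.shape[2]
    Cin = x.shape[1]
    if Cg * groups != Cin:
        raise ValueError(
            f"channel mismatch: input has {Cin} channels, kernel expects "
            f"{Cg * groups} (groups={groups})")
    if padding is None:
        padding = ((k - 1) * dilation) // 2  # same-padding for odd k
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    ke = (k - 1) * dilation + 1
    out_shape = tuple((s + 2 * p - ke) // stride + 1 for s in x.shape[2:])
    out_data = _conv_fwd(xp, w.data, stride, dilation, groups, out_shape)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1, 1)

    parents = [x, w] if b is None else [x, w, b]
    B = x.shape[0]
    N = int(np.prod(out_shape))
    depthwise = groups == Cin and Cg == 1 and Cout == Cin

    def bwd(g):
        gs = g.reshape(B, Cout, N)
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(w.data)
        for i, j, l in _offsets(k):
            sl = _shift_slice(i, j, l, stride, dilation, out_shape)
            xs = xp[sl].reshape(B, Cin, N)
            if groups == 1:
                dw[:, :, i, j, l] = np.einsum("bon,bcn->oc", gs, xs,
                                              optimize=True)
                contrib = np.matmul(w.data[:, :, i, j, l].T, gs)
            elif depthwise:
                dw[:, 0, i, j, l] = (gs * xs).sum(axis=(0, 2))
                contrib = w.data[:, 0, i, j, l][None, :, None] * gs
            else:
                gi, go = Cin // groups, Cout // groups
                contrib = np.empty((B, Cin, N), dtype=xp.dtype)
                for g_ in range(groups):
                    go_sl = slice(g_ * go, (g_ + 1) * go)
                    gi_sl = slice(g_ * gi, (g_ + 1) * gi)
                    dw[go_sl, :, i, j, l] = np.einsum(
                        "bon,bcn->oc", gs[:, go_sl], xs[:, gi_sl],
                        optimize=True)
                    contrib[:, gi_sl] = np.matmul(
                        w.data[go_sl, :, i, j, l].T, gs[:, go_sl])
            dxp[sl] += contrib.reshape(B, Cin, *out_shape)
        dx = dxp[:, :, p:p + x.shape[2], p:p + x.shape[3], p:p + x.shape[4]]
        grads = [(x, dx), (w, dw)]
        if b is not None:
            grads.append((b, g.sum(axis=(0, 2, 3, 4))))
        return grads

    return Tensor._make(out_data, parents, bwd)


def _interp_matrix(n_in: int, n_out: int, dtype=np.float64) -> np.ndarray:
    """Row-stochastic (n_out, n_in) linear-interpolation matrix
    (half-pixel-centre convention, edges clamped)."""
    M = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    t = src - lo
    M[np.arange(n_out), lo] += 1.0 - t
    M[np.arange(n_out), hi] += t
    return M


def interpolate(x: Tensor, size: tuple[int, int, int]) -> Tensor:
    """Trilinear resize of (B, C, D, H, W) to spatial ``size`` — applied as
    three separable 1D linear maps, so the backward pass is their transpose."""
    x = as_tensor(x)
    mats = [np.ascontiguousarray(_interp_matrix(x.shape[2 + i], size[i]))
            .astype(x.dtype) for i in range(3)]
    out = x.data
    for i, M in enumerate(mats):
        out = np.moveaxis(np.tensordot(M, out, axes=(1, 2 + i)), 0, 2 + i)

    def bwd(g):
        for i, M in enumerate(mats):
            g = np.moveaxis(np.tensordot(M.T, g, axes=(1, 2 + i)), 0, 2 + i)
        return [(x, g)]

    return Tensor._make(np.ascontiguousarray(out), (x,), bwd)


def global_avg_pool3d(x: Tensor) -> Tensor:
    """(B, C, D, H, W) -> (B, C) mean over all spatial positions."""
    return as_tensor(x).mean(axis=(2, 3, 4))


def linear_scan(abar: Tensor, bx: Tensor, c: Tensor) -> Tensor:
    """Evaluate ``h[t] = abar[t] * h[t-1] + bx[t]``, ``y[t] = sum_s c[t,...,s] h[t,...,s]``
    along axis 0 in O(T), with an explicit reverse-sweep backward.

    Shapes: abar, bx, c all (T, ..., S) where S is the state size; abar may be
    time-invariant per entry (already broadcast by the caller).  Returns
    y of shape (T, ...).
    """
    abar, bx, c = as_tensor(abar), as_tensor(bx), as_tensor(c)
    if abar.shape != bx.shape or c.shape != bx.shape:
        raise ValueError("linear_scan operands must share one shape")
    T = bx.shape[0]
    h = np.zeros(bx.shape[1:], dtype=bx.dtype)
    hs = np.empty_like(bx.data)
    for t in range(T):
        h = abar.data[t] * h + bx.data[t]
        hs[t] = h
    y = (c.data * hs).sum(axis=-1)

    def bwd(g):
        da = np.empty_like(abar.data)
        db = np.empty_like(bx.data)
        dc = g[..., None] * hs
        gh = np.zeros(bx.shape[1:], dtype=bx.dtype)
        for t in range(T - 1, -1, -1):
            gh = gh + g[t][..., None] * c.data[t]
            hprev = hs[t - 1] if t > 0 else 0.0
            da[t] = gh * hprev
            db[t] = gh
            gh = gh * abar.data[t]
        return [(abar, da), (bx, db), (c, dc)]

    return Tensor._make(y, (abar, bx, c), bwd)
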
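"""Structured array ops (convolution, pooling, resampling) with gradients."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = ["conv2d", "max_pool2d", "upsample_nearest"]


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    # xp: padded input (N, C, Hp, Wp) -> (N, Ho*Wo, C*kh*kw)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernel, no dilation."""
    n, c, h, wd = x.data.shape
    co, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, kernel expects {ci}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(co, -1)
    out_mat = cols @ wmat.T  # (N, Ho*Wo, Co)
    out_data = out_mat.transpose(0, 2, 1).reshape(n, co, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, co, 1, 1)

    prev = tuple(t for t in (x, w, b) if t is not None)
    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in prev), _prev=prev)
    if not out.requires_grad:
        return out

    def backward(g):
        gmat = g.reshape(n, co, ho * wo).transpose(0, 2, 1)  # (N, Ho*Wo, Co)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.tensordot(gmat, cols, axes=([0, 1], [0, 1]))  # (Co, C*kh*kw)
            w._accum(dw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
            hp, wp = xp.shape[2], xp.shape[3]
            dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
            for i in range(kh):
                hi = i + stride * ho
                for j in range(kw):
                    wj = j + stride * wo
                    dxp[:, :, i:hi:stride, j:wj:stride] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:hp - padding, padding:wp - padding]
            x._accum(dxp)

    out._backward = backward
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    stride = stride or kernel
    n, c, h, w = x.data.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    out = Tensor(out_data, requires_grad=x.requires_grad, _prev=(x,))
    if not out.requires_grad:
        return out

    def backward(g):
        hp, wp = xp.shape[2], xp.shape[3]
        dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        ki, kj = np.divmod(arg, kernel)
        hi = np.arange(ho)[:, None] * stride + ki  # (n,c,ho,wo) row index
        wj = np.arange(wo)[None, :] * stride + kj
        ni = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (ni, cc, hi, wj), g)
        if padding:
            dxp = dxp[:, :, padding:hp - padding, padding:wp - padding]
        x._accum(dxp)

    out._backward = backward
    return out


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.data.shape
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)

    out = Tensor(out_data, requires_grad=x.requires_grad, _prev=(x,))
    if not out.requires_grad:
        return out

    def backward(g):
        x._accum(g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5)))

    out._backward = backward
    return out
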
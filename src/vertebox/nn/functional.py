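"""Convolution, pooling, normalization and resampling primitives.

Gradients are hand-written for memory economy on a single CPU: convolutions
use a shift-and-matmul formulation (one matmul per kernel tap on an NHWC
view) and re-derive the padded input in the backward pass instead of storing
patch matrices; max pooling stores only int8 argmax indices; batch
normalization is a single fused op keeping one normalized copy.  Only
stride-1 'same' convolutions and kernel==stride transposed convolutions are
provided — the shapes the encoder–decoder actually uses.
"""

from __future__ import annotations

import functools

import numpy as np

from .tensor import Tensor

__all__ = ["conv2d", "conv_transpose2d", "max_pool2d", "upsample_bilinear",
           "softmax", "batch_norm"]


def _nhwc_padded(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    return np.ascontiguousarray(x.transpose(0, 2, 3, 1))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 same-padding 2D convolution (cross-correlation convention).

    ``x``: (N,C,H,W); ``weight``: (O,C,kh,kw); ``bias``: (O,) or None.
    """
    n, c, h, w = x.data.shape
    o, ci, kh, kw = weight.data.shape
    if ci != c:
        raise ValueError(f"weight expects {ci} input channels, got {c}")
    ph, pw = kh // 2, kw // 2
    wt = weight.data.reshape(o, c, kh * kw)

    xt = _nhwc_padded(x.data, ph, pw)
    acc = np.zeros((n, h, w, o), dtype=x.data.dtype)
    for k in range(kh * kw):
        i, j = divmod(k, kw)
        acc += xt[:, i:i + h, j:j + w, :] @ wt[:, :, k].T
    if bias is not None:
        acc += bias.data
    out = np.ascontiguousarray(acc.transpose(0, 3, 1, 2))
    del xt, acc

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))        # n,h,w,o
        xt = _nhwc_padded(x.data, ph, pw)                          # recomputed
        gw = np.empty((o, c, kh * kw), dtype=weight.data.dtype)
        gxt = np.zeros_like(xt) if x.requires_grad else None
        for k in range(kh * kw):
            i, j = divmod(k, kw)
            patch = xt[:, i:i + h, j:j + w, :]
            gw[:, :, k] = np.tensordot(gt, patch, axes=([0, 1, 2], [0, 1, 2]))
            if gxt is not None:
                gxt[:, i:i + h, j:j + w, :] += gt @ wt[:, :, k]
        gx = None
        if gxt is not None:
            gx = np.ascontiguousarray(
                gxt[:, ph:ph + h, pw:pw + w, :].transpose(0, 3, 1, 2))
        grads = [gx, gw.reshape(weight.data.shape)]
        if bias is not None:
            grads.append(gt.sum(axis=(0, 1, 2)))
        return grads

    return Tensor._make(out, parents, bw)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution with kernel == stride (exact 2x upsampling).

    ``x``: (N,C,H,W); ``weight``: (C,O,k,k); output (N,O,H*k,W*k).
    """
    n, c, h, w = x.data.shape
    ci, o, kh, kw = weight.data.shape
    if ci != c or kh != stride or kw != stride:
        raise ValueError("conv_transpose2d requires weight (C,O,s,s) matching input channels")
    out6 = np.einsum("nchw,coij->nohiwj", x.data, weight.data, optimize=True)
    out = np.ascontiguousarray(out6).reshape(n, o, h * kh, w * kw)
    del out6
    if bias is not None:
        out += bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        g6 = g.reshape(n, o, h, kh, w, kw)
        gx = np.einsum("nohiwj,coij->nchw", g6, weight.data, optimize=True) \
            if x.requires_grad else None
        gw = np.einsum("nohiwj,nchw->coij", g6, x.data, optimize=True)
        grads = [gx, gw]
        if bias is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return grads

    return Tensor._make(out, parents, bw)


def max_pool2d(x: Tensor, size: int = 2) -> Tensor:
    """Non-overlapping max pooling; spatial dims must be divisible by size."""
    n, c, h, w = x.data.shape
    if h % size or w % size:
        raise ValueError(f"spatial size ({h},{w}) not divisible by pool size {size}")
    ho, wo = h // size, w // size
    windows = np.ascontiguousarray(
        x.data.reshape(n, c, ho, size, wo, size).transpose(0, 1, 2, 4, 3, 5)
    ).reshape(n, c, ho, wo, size * size)
    idx = windows.argmax(axis=-1).astype(np.int8)
    out = np.take_along_axis(windows, idx[..., None].astype(np.intp), axis=-1)[..., 0]
    del windows

    def bw(g):
        gwin = np.zeros((n, c, ho, wo, size * size), dtype=g.dtype)
        np.put_along_axis(gwin, idx[..., None].astype(np.intp), g[..., None], axis=-1)
        gx = gwin.reshape(n, c, ho, wo, size, size) \
                 .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return [np.ascontiguousarray(gx)]

    return Tensor._make(np.ascontiguousarray(out), (x,), bw)


def batch_norm(x: Tensor, weight: Tensor, bias: Tensor,
               running_mean: np.ndarray | None = None,
               running_var: np.ndarray | None = None,
               eps: float = 1e-5) -> Tensor:
    """Fused per-channel batch normalization over (N, ·, H, W).

    Batch statistics are used when ``running_mean`` is None (training mode);
    otherwise the provided running statistics (inference mode).
    """
    c = x.data.shape[1]
    g_ = weight.data.reshape(1, c, 1, 1)
    b_ = bias.data.reshape(1, c, 1, 1)

    if running_mean is None:
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        var = np.square(x.data - mu).mean(axis=(0, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mu) * inv
        out = g_ * xhat + b_

        def bw(grad):
            dgamma = (grad * xhat).sum(axis=(0, 2, 3))
            dbeta = grad.sum(axis=(0, 2, 3))
            gx = None
            if x.requires_grad:
                dxhat = grad * g_
                m1 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
                m2 = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = inv * (dxhat - m1 - xhat * m2)
            return [gx, dgamma, dbeta]

        return Tensor._make(out, (x, weight, bias), bw)

    rm = running_mean.reshape(1, c, 1, 1)
    rinv = 1.0 / np.sqrt(running_var.reshape(1, c, 1, 1) + eps)
    out = (x.data - rm) * (rinv * g_) + b_
    xhat_fn = lambda: (x.data - rm) * rinv  # cheap, recomputed on demand

    def bw_eval(grad):
        dgamma = (grad * xhat_fn()).sum(axis=(0, 2, 3))
        dbeta = grad.sum(axis=(0, 2, 3))
        gx = grad * (g_ * rinv) if x.requires_grad else None
        return [gx, dgamma, dbeta]

    return Tensor._make(out, (x, weight, bias), bw_eval)


@functools.lru_cache(maxsize=64)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1D linear-interpolation operator (half-pixel-centre convention)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = (src - i0).astype(np.float32)
    m[np.arange(n_out), i0] += 1 - frac
    m[np.arange(n_out), i1] += frac
    return m


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of (N,C,H,W) to spatial ``size`` (separable linear map)."""
    n, c, h, w = x.data.shape
    ho, wo = size
    mh = _interp_matrix(h, ho).astype(x.data.dtype)
    mw = _interp_matrix(w, wo).astype(x.data.dtype)
    out = np.einsum("oh,nchw,pw->ncop", mh, x.data, mw, optimize=True)

    def bw(g):
        return [np.einsum("oh,ncop,pw->nchw", mh, g, mw, optimize=True)]

    return Tensor._make(out, (x,), bw)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
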
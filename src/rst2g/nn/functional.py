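"""Structured differentiable operations: convolution, pooling, resampling.

Convolution uses an im2col/GEMM formulation; its backward pass is the exact
transpose (col2im scatter-add). All ops assume NCHW layout.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, is_grad_enabled

__all__ = [
    "conv2d", "max_pool2d", "upsample_bilinear2x", "softmax", "gelu",
]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> (B, C*k*k, H*W) patches for stride-1 same convolution."""
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(B, C, k, k, H, W),
        strides=(s[0], s[1], s[2], s[3], s[2], s[3]), writeable=False)
    return windows.reshape(B, C * k * k, H * W)


def _col2im(cols: np.ndarray, shape: tuple[int, ...], k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    B, C, H, W = shape
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(B, C, k, k, H, W)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + H, j:j + W] += cols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1, same-padding 2D convolution (cross-correlation).

    weight: (C_out, C_in, k, k) with odd k; bias: (C_out,) or None.
    """
    cout, cin, k, k2 = weight.shape
    if k != k2 or k % 2 == 0:
        raise ValueError("conv2d requires square, odd-sized kernels")
    B, C, H, W = x.shape
    if C != cin:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {cin}")
    pad = k // 2
    cols = _im2col(x.data, k, pad)                       # (B, C*k*k, N)
    wmat = weight.data.reshape(cout, cin * k * k)
    out_data = np.einsum("ok,bkn->bon", wmat, cols, optimize=True)
    out_data = out_data.reshape(B, cout, H, W)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(out):
        dout = out.grad.reshape(B, cout, H * W)
        if bias is not None and bias.requires_grad:
            bias._accum(out.grad.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.einsum("bon,bkn->ok", dout, cols, optimize=True)
            weight._accum(dw.reshape(weight.shape))
        if x.requires_grad:
            dcols = np.einsum("ok,bon->bkn", wmat, dout, optimize=True)
            x._accum(_col2im(dcols, x.shape, k, pad))

    return x._make(out_data, parents, backward)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2. Ties route the gradient to the first
    maximum (raster order) so the pooling gradient is a partition."""
    B, C, H, W = x.shape
    if H < 2 or W < 2:
        raise ValueError("max_pool2d needs spatial dims >= 2")
    if H % 2 or W % 2:
        raise ValueError("max_pool2d requires even spatial dims")
    H2, W2 = H // 2, W // 2
    win = x.data.reshape(B, C, H2, 2, W2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(B, C, H2, W2, 4)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(out):
        if x.requires_grad:
            dwin = np.zeros_like(win)
            np.put_along_axis(dwin, idx[..., None], out.grad[..., None], axis=-1)
            g = dwin.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x._accum(g.reshape(B, C, H, W))

    return x._make(out_data, (x,), backward)


def _linear_coords(n_out: int, n_in: int):
    """Half-pixel-centre source coordinates for 2x bilinear upsampling."""
    coords = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    i0 = np.clip(np.floor(coords).astype(np.intp), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    frac = np.clip(coords - np.floor(coords), 0.0, 1.0)
    frac = np.where(i1 == i0, 0.0, frac)
    return i0, i1, frac


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling (half-pixel alignment), separable."""
    B, C, H, W = x.shape
    r0, r1, fr = _linear_coords(2 * H, H)
    c0, c1, fc = _linear_coords(2 * W, W)
    fr_ = fr[None, None, :, None].astype(x.dtype)
    fc_ = fc[None, None, None, :].astype(x.dtype)

    xr = x.data[:, :, r0, :] * (1 - fr_) + x.data[:, :, r1, :] * fr_
    out_data = xr[:, :, :, c0] * (1 - fc_) + xr[:, :, :, c1] * fc_

    def backward(out):
        if not x.requires_grad:
            return
        dxr = np.zeros((B, C, 2 * H, W), dtype=out.grad.dtype)
        np.add.at(dxr, (slice(None), slice(None), slice(None), c0),
                  out.grad * (1 - fc_))
        np.add.at(dxr, (slice(None), slice(None), slice(None), c1),
                  out.grad * fc_)
        dx = np.zeros_like(x.data)
        np.add.at(dx, (slice(None), slice(None), r0, slice(None)),
                  dxr * (1 - fr_))
        np.add.at(dx, (slice(None), slice(None), r1, slice(None)),
                  dxr * fr_)
        x._accum(dx)

    return x._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis`."""
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(x: Tensor) -> Tensor:
    """GELU activation (tanh approximation)."""
    inner = _GELU_C * (x + 0.044715 * x * x * x)
    return 0.5 * x * (1.0 + inner.tanh())
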
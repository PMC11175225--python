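"""Differentiable ops used by the networks (NCHW layout throughout)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._from_op(out_data, (x,), backward)


def leaky_relu(x: Tensor, negative_slope: float = 0.2) -> Tensor:
    mask = x.data > 0
    scale = np.where(mask, 1.0, negative_slope).astype(x.dtype)
    out_data = x.data * scale

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * scale)

    return Tensor._from_op(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable two-sided formulation
    d = x.data
    out_data = np.empty_like(d)
    pos = d >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ed = np.exp(d[~pos])
    out_data[~pos] = ed / (1.0 + ed)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._from_op(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    out_data = np.log(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    return Tensor._from_op(out_data, (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    out_data = np.sqrt(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * 0.5 / out_data)

    return Tensor._from_op(out_data, (x,), backward)


def clamp(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clip values; gradient passes only where no clipping occurred."""
    mask = (x.data >= lo) & (x.data <= hi)
    out_data = np.clip(x.data, lo, hi)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._from_op(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concatenate(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


def pixel_shuffle(x: Tensor, upscale: int) -> Tensor:
    """Rearrange (N, C·r², H, W) → (N, C, H·r, W·r); a bijection on entries."""
    n, c_r2, h, w = x.shape
    r = upscale
    if c_r2 % (r * r):
        raise ValueError(f"channel count {c_r2} not divisible by {r}^2")
    c = c_r2 // (r * r)
    out_data = (x.data.reshape(n, c, r, r, h, w)
                .transpose(0, 1, 4, 2, 5, 3)
                .reshape(n, c, h * r, w * r))

    def backward(g):
        if x.requires_grad:
            gx = (g.reshape(n, c, h, r, w, r)
                  .transpose(0, 1, 3, 5, 2, 4)
                  .reshape(n, c_r2, h, w))
            x._accumulate(np.ascontiguousarray(gx))

    return Tensor._from_op(np.ascontiguousarray(out_data), (x,), backward)


# ---------------------------------------------------------------------------
# convolution (im2col) and pooling
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(N, C, Hp, Wp) → columns (N·Ho·Wo, C·kh·kw) plus output dims."""
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # win: (N, C, Ho, Wo, kh, kw) → (N, Ho, Wo, C, kh, kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * ho * wo, c * kh * kw), ho, wo


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, zero same-padding convention left to the caller.

    ``weight`` has shape (C_out, C_in, kh, kw); ``x`` is (N, C_in, H, W).
    """
    n, cin, h, w = x.shape
    cout, cin_w, kh, kw = weight.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input has {cin}, "
                         f"weight expects {cin_w}")
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                             (padding, padding)))
    else:
        xp = x.data
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    w2d = weight.data.reshape(cout, cin * kh * kw)
    out = cols @ w2d.T
    if bias is not None:
        out += bias.data
    out_data = np.ascontiguousarray(
        out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2))

    def backward(g):
        g2d = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
        if weight.requires_grad:
            gw = g2d.T @ cols
            weight._accumulate(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g2d.sum(axis=0))
        if x.requires_grad:
            gcols = (g2d @ w2d).reshape(n, ho, wo, cin, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                gxp = gxp[:, :, padding:padding + h, padding:padding + w]
            x._accumulate(gxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._from_op(out_data, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 2) -> Tensor:
    """Non-overlapping max pooling (kernel == stride); ties go to the first."""
    n, c, h, w = x.shape
    if h % kernel or w % kernel:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool {kernel}")
    ho, wo = h // kernel, w // kernel
    patches = (x.data.reshape(n, c, ho, kernel, wo, kernel)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, ho, wo, kernel * kernel))
    arg = patches.argmax(axis=-1)
    out_data = np.take_along_axis(patches, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gp = np.zeros_like(patches)
        np.put_along_axis(gp, arg[..., None], g[..., None], axis=-1)
        gx = (gp.reshape(n, c, ho, wo, kernel, kernel)
              .transpose(0, 1, 2, 4, 3, 5)
              .reshape(n, c, h, w))
        x._accumulate(np.ascontiguousarray(gx))

    return Tensor._from_op(np.ascontiguousarray(out_data), (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) → (N, C)."""
    return x.mean(axis=(2, 3))


def global_max_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) → (N, C); ties send the gradient to the first maximum."""
    n, c, h, w = x.shape
    flat = x.data.reshape(n, c, h * w)
    arg = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(flat)
        np.put_along_axis(gx, arg[..., None], g[..., None], axis=-1)
        x._accumulate(gx.reshape(n, c, h, w))

    return Tensor._from_op(out_data, (x,), backward)


def channel_mean_max(x: Tensor) -> Tensor:
    """Per-pixel mean and max across channels, stacked as a 2-channel map."""
    n, c, h, w = x.shape
    mean_map = x.mean(axis=1, keepdims=True)
    arg = x.data.argmax(axis=1)  # (N, H, W)
    max_data = np.take_along_axis(x.data, arg[:, None], axis=1)

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, arg[:, None], g, axis=1)
        x._accumulate(gx)

    max_map = Tensor._from_op(max_data, (x,), backward)
    return concatenate([mean_map, max_map], axis=1)
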
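"""Structured differentiable operations on NCHW tensors.

Convolutions run through im2col / col2im with explicit backward rules;
bilinear resizing is expressed as two dense interpolation matrices so its
adjoint is a plain transposed product; the horizontal warp implements the
standard differentiable bilinear sampler with zero padding outside the image,
with gradients flowing to both the sampled source and the disparity.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "bilinear_resize",
    "upsample2x",
    "warp_horizontal",
    "box_mean",
    "batch_norm_train",
]


def _sliding_windows(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """View (N, C, H, W) -> (N, C, kh, kw, Ho, Wo), no copy."""
    n, c, h, w = x.shape
    ho = (h - kh) // sh + 1
    wo = (w - kw) // sw + 1
    sn, sc, sh_, sw_ = x.strides
    return as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(sn, sc, sh_, sw_, sh_ * sh, sw_ * sw),
        writeable=False,
    )


def _im2col(x: np.ndarray, kh, kw, sh, sw, ph, pw):
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = _sliding_windows(x, kh, kw, sh, sw)
    n = x.shape[0]
    ho, wo = win.shape[4], win.shape[5]
    cols = win.transpose(0, 1, 2, 3, 4, 5).reshape(n, -1, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh, kw, sh, sw, ph, pw, ho, wo):
    """Adjoint of _im2col: scatter-add columns back into the input layout."""
    n, c, h, w = x_shape
    out = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        hi = i + sh * ho
        for j in range(kw):
            wj = j + sw * wo
            out[:, :, i:hi:sh, j:wj:sw] += cols[:, :, i, j]
    if ph or pw:
        out = out[:, :, ph:ph + h, pw:pw + w]
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation; ``weight`` is (Cout, Cin, kh, kw)."""
    x, weight = as_tensor(x), as_tensor(weight)
    co, ci, kh, kw = weight.data.shape
    if x.data.shape[1] != ci:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[1]}, weight expects {ci}"
        )
    cols, ho, wo = _im2col(x.data, kh, kw, stride, stride, padding, padding)
    wmat = weight.data.reshape(co, -1)
    out = np.matmul(wmat, cols)  # (N, Co, Ho*Wo) via batched BLAS
    n = x.data.shape[0]
    out = out.reshape(n, co, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gmat = np.ascontiguousarray(g.reshape(n, co, ho * wo))
        if weight.requires_grad:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)
            gx = _col2im(gcols, x.data.shape, kh, kw, stride, stride,
                         padding, padding, ho, wo)
            x._accumulate(gx)

    return Tensor._make(out, parents, bwd)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed convolution; ``weight`` is (Cin, Cout, kh, kw).

    Output size follows ``(H - 1) * stride - 2 * padding + kh``; the default
    kernel-4 / stride-2 / padding-1 configuration exactly doubles H and W.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    ci, co, kh, kw = weight.data.shape
    if x.data.shape[1] != ci:
        raise ValueError(
            f"conv_transpose2d channel mismatch: input has {x.data.shape[1]}, weight expects {ci}"
        )
    n, _, hi, wi = x.data.shape
    ho = (hi - 1) * stride - 2 * padding + kh
    wo = (wi - 1) * stride - 2 * padding + kw
    wmat = weight.data.reshape(ci, co * kh * kw)
    xmat = np.ascontiguousarray(x.data.reshape(n, ci, hi * wi))
    cols = np.matmul(wmat.T, xmat)
    out = _col2im(cols, (n, co, ho, wo), kh, kw, stride, stride,
                  padding, padding, hi, wi)
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gcols, _, _ = _im2col(g, kh, kw, stride, stride, padding, padding)
        if x.requires_grad:
            gx = np.matmul(wmat, gcols)
            x._accumulate(gx.reshape(x.data.shape))
        if weight.requires_grad:
            gweight = np.matmul(xmat, gcols.transpose(0, 2, 1)).sum(axis=0)
            weight._accumulate(gweight.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out, parents, bwd)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    win = _sliding_windows(xp, kernel, kernel, stride, stride)
    n_, c_, _, _, ho, wo = win.shape
    flat = win.reshape(n, c, kernel * kernel, ho, wo)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def bwd(g):
        gflat = np.zeros((n, c, kernel * kernel, ho, wo), dtype=g.dtype)
        np.put_along_axis(gflat, arg[:, :, None], g[:, :, None], axis=2)
        gcols = gflat.reshape(n, c * kernel * kernel, ho * wo)
        gxp = _col2im(gcols, (n, c, h, w), kernel, kernel,
                      stride, stride, padding, padding, ho, wo)
        x._accumulate(gxp)

    return Tensor._make(out, (x,), bwd)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix, half-pixel-centre convention."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = (src - i0).astype(np.float32)
    m[np.arange(n_out), i0] += 1.0 - f
    m[np.arange(n_out), i1] += f
    return m


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of the trailing two axes of an NCHW tensor."""
    x = as_tensor(x)
    h, w = x.data.shape[-2:]
    ho, wo = out_hw
    mh = _interp_matrix(ho, h)
    mw = _interp_matrix(wo, w)
    lead = x.data.shape[:-2]
    tmp = np.matmul(mh, x.data.reshape(-1, h, w))
    out = np.matmul(tmp, mw.T).reshape(lead + (ho, wo))

    def bwd(g):
        tmp_g = np.matmul(mh.T, g.reshape(-1, ho, wo))
        gx = np.matmul(tmp_g, mw).reshape(lead + (h, w))
        x._accumulate(gx)

    return Tensor._make(out, (x,), bwd)


def upsample2x(x: Tensor) -> Tensor:
    h, w = x.data.shape[-2:]
    return bilinear_resize(x, (2 * h, 2 * w))


def warp_horizontal(source: Tensor, disparity: Tensor) -> Tensor:
    """Sample ``source`` at column ``x - d(x, y)`` with bilinear weights.

    ``source`` is (N, C, H, W); ``disparity`` is (N, 1, H, W) in pixels at the
    same resolution.  Samples falling outside the image read as zero.
    Differentiable in both arguments; the disparity gradient is the finite
    difference of the two bilinear taps.
    """
    source, disparity = as_tensor(source), as_tensor(disparity)
    n, c, h, w = source.data.shape
    if disparity.data.shape != (n, 1, h, w):
        raise ValueError(
            f"warp: disparity shape {disparity.data.shape} does not match source {(n, 1, h, w)}"
        )
    xs = np.arange(w, dtype=np.float32)[None, None, None, :]
    src_x = xs - disparity.data  # (N,1,H,W)
    x0 = np.floor(src_x).astype(np.int64)
    frac = (src_x - x0).astype(np.float32)
    x1 = x0 + 1
    in0 = (x0 >= 0) & (x0 <= w - 1)
    in1 = (x1 >= 0) & (x1 <= w - 1)
    x0c = np.clip(x0, 0, w - 1)
    x1c = np.clip(x1, 0, w - 1)

    bidx = np.arange(n)[:, None, None, None]
    ridx = np.arange(h)[None, None, :, None]
    cidx = np.arange(c)[None, :, None, None]
    g0 = source.data[bidx, cidx, ridx, x0c] * in0
    g1 = source.data[bidx, cidx, ridx, x1c] * in1
    out = (1.0 - frac) * g0 + frac * g1

    def bwd(g):
        if source.requires_grad:
            gs = np.zeros_like(source.data)
            np.add.at(gs, (bidx + 0 * x0c, cidx + 0 * x0c, ridx + 0 * x0c, x0c),
                      g * (1.0 - frac) * in0)
            np.add.at(gs, (bidx + 0 * x1c, cidx + 0 * x1c, ridx + 0 * x1c, x1c),
                      g * frac * in1)
            source._accumulate(gs)
        if disparity.requires_grad:
            # d out / d src_x = g1 - g0 ; d src_x / d disparity = -1
            gd = (g * (g0 - g1)).sum(axis=1, keepdims=True)
            disparity._accumulate(gd)

    return Tensor._make(out, (source, disparity), bwd)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch norm over (N, H, W) per channel.

    Returns (out, batch_mean, batch_var) with the statistics as plain
    arrays for the running-average update.  The backward pass uses the
    closed-form expression instead of tracing the statistic subgraph.
    """
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    m = n * h * w
    mu = x.data.mean(axis=(0, 2, 3))
    xc = x.data - mu.reshape(1, c, 1, 1)
    var = np.mean(xc * xc, axis=(0, 2, 3))
    inv_sd = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv_sd.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gg = g * gamma.data.reshape(1, c, 1, 1)
            sum_gg = gg.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
            sum_gg_xhat = (gg * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
            gx = (inv_sd.reshape(1, c, 1, 1) / m) * (
                m * gg - sum_gg - xhat * sum_gg_xhat
            )
            x._accumulate(gx.astype(np.float32))

    return Tensor._make(out, (x, gamma, beta), bwd), mu, var


def box_mean(x: Tensor, k: int) -> Tensor:
    """Mean over sliding k x k windows, valid positions only (no padding)."""
    x = as_tensor(x)
    h, w = x.data.shape[-2:]
    if k > h or k > w:
        raise ValueError(f"box_mean window {k} exceeds spatial size {(h, w)}")
    ho, wo = h - k + 1, w - k + 1
    inv = 1.0 / (k * k)
    # accumulate in double: k^2 single-precision adds otherwise leave noise
    # comparable to the SSIM stabilizers when variances nearly cancel
    out = np.zeros(x.data.shape[:-2] + (ho, wo), dtype=np.float64)
    for i in range(k):
        for j in range(k):
            out += x.data[..., i:i + ho, j:j + wo]
    out = (out * inv).astype(np.float32)

    def bwd(g):
        gx = np.zeros_like(x.data)
        gs = g * inv
        for i in range(k):
            for j in range(k):
                gx[..., i:i + ho, j:j + wo] += gs
        x._accumulate(gx)

    return Tensor._make(out, (x,), bwd)
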
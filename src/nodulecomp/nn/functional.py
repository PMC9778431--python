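"""Differentiable spatial primitives (NCHW layout): convolution, pooling,
bilinear resizing and batch normalization, each with a hand-written backward
pass built on im2col/col2im."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = ["conv2d", "max_pool2d", "avg_pool2d", "bilinear_resize", "batch_norm2d"]


def _pair(v) -> tuple[int, int]:
    return (v, v) if np.isscalar(v) else tuple(v)


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int,
            dh: int, dw: int, ho: int, wo: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N,C,kh,kw,Ho,Wo) patch view copy."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i * dh: i * dh + sh * ho: sh,
                                  j * dw: j * dw + sw * wo: sw]
    return cols


def _col2im(cols_grad: np.ndarray, x_shape: tuple[int, ...], pad: tuple[int, int],
            kh: int, kw: int, sh: int, sw: int, dh: int, dw: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = x_shape
    ph, pw = pad
    xg = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=cols_grad.dtype)
    for i in range(kh):
        for j in range(kw):
            xg[:, :, i * dh: i * dh + sh * ho: sh,
               j * dw: j * dw + sw * wo: sw] += cols_grad[:, :, i, j]
    if ph or pw:
        xg = xg[:, :, ph: ph + h, pw: pw + w]
    return xg


def _out_size(h: int, k: int, s: int, d: int, p: int) -> int:
    keff = (k - 1) * d + 1
    return (h + 2 * p - keff) // s + 1


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride=1, padding=0, dilation=1) -> Tensor:
    """2-D cross-correlation. weight: (Cout, Cin, kh, kw)."""
    x, weight = as_tensor(x), as_tensor(weight)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    co, ci, kh, kw = weight.shape
    n, c, h, w = x.shape
    if c != ci:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    ho = _out_size(h, kh, sh, dh, ph)
    wo = _out_size(w, kw, sw, dw, pw)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    cols = _im2col(xp, kh, kw, sh, sw, dh, dw, ho, wo)
    # (N,C,kh,kw,Ho,Wo) x (Co,C,kh,kw) -> (N,Co,Ho,Wo)
    out = np.tensordot(cols, weight.data, axes=([1, 2, 3], [1, 2, 3]))
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if bias is not None:
        out += bias.data.reshape(1, -1, 1, 1)

    parents = [x, weight] + ([bias] if bias is not None else [])

    def bwd(o: Tensor) -> None:
        gy = o.grad  # (N,Co,Ho,Wo)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gy.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.tensordot(gy, cols, axes=([0, 2, 3], [0, 4, 5]))
            weight._accumulate(gw)  # (Co,C,kh,kw)
        if x.requires_grad:
            # (N,Co,Ho,Wo) x (Co,C,kh,kw) -> (N,C,kh,kw,Ho,Wo)
            gcols = np.tensordot(gy, weight.data, axes=([1], [0]))
            gcols = np.ascontiguousarray(gcols.transpose(0, 3, 4, 5, 1, 2))
            x._accumulate(_col2im(gcols, x.shape, (ph, pw), kh, kw,
                                  sh, sw, dh, dw, ho, wo))

    return Tensor._make(out, parents, bwd)


def max_pool2d(x: Tensor, kernel=2, stride=None, padding=0) -> Tensor:
    x = as_tensor(x)
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride if stride is not None else kernel)
    ph, pw = _pair(padding)
    n, c, h, w = x.shape
    ho = _out_size(h, kh, sh, 1, ph)
    wo = _out_size(w, kw, sw, 1, pw)
    if ph or pw:
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    cols = _im2col(xp, kh, kw, sh, sw, 1, 1, ho, wo)
    flat = cols.reshape(n, c, kh * kw, ho, wo)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def bwd(o: Tensor) -> None:
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, arg[:, :, None], o.grad[:, :, None], axis=2)
        gcols = gflat.reshape(n, c, kh, kw, ho, wo)
        x._accumulate(_col2im(gcols, x.shape, (ph, pw), kh, kw, sh, sw, 1, 1, ho, wo))

    return Tensor._make(out, (x,), bwd)


def avg_pool2d(x: Tensor, kernel=2, stride=None, padding=0) -> Tensor:
    """Average pooling; zero padding counts toward the kernel-area divisor."""
    x = as_tensor(x)
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride if stride is not None else kernel)
    ph, pw = _pair(padding)
    n, c, h, w = x.shape
    ho = _out_size(h, kh, sh, 1, ph)
    wo = _out_size(w, kw, sw, 1, pw)
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    cols = _im2col(xp, kh, kw, sh, sw, 1, 1, ho, wo)
    out = cols.mean(axis=(2, 3))

    def bwd(o: Tensor) -> None:
        g = o.grad / (kh * kw)
        gcols = np.broadcast_to(g[:, :, None, None], (n, c, kh, kw, ho, wo))
        x._accumulate(_col2im(np.ascontiguousarray(gcols), x.shape, (ph, pw),
                              kh, kw, sh, sw, 1, 1, ho, wo))

    return Tensor._make(out, (x,), bwd)


def _resize_coords(n_in: int, n_out: int):
    """Half-pixel-centre source coordinates (align_corners=False)."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.floor(src).astype(np.int64)
    frac = src - i0
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    return i0c, i1c, frac


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of (N,C,H,W) to (N,C,*out_hw); exact for constants."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    ho, wo = out_hw
    if (ho, wo) == (h, w):
        def bwd_id(o: Tensor) -> None:
            x._accumulate(o.grad)
        return Tensor._make(x.data.copy(), (x,), bwd_id)
    y0, y1, fy = _resize_coords(h, ho)
    x0, x1, fx = _resize_coords(w, wo)
    fy = fy.reshape(-1, 1)
    fx = fx.reshape(1, -1)
    d = x.data
    top = d[:, :, y0][:, :, :, x0] * (1 - fx) + d[:, :, y0][:, :, :, x1] * fx
    bot = d[:, :, y1][:, :, :, x0] * (1 - fx) + d[:, :, y1][:, :, :, x1] * fx
    out = top * (1 - fy) + bot * fy

    def bwd(o: Tensor) -> None:
        g = np.zeros_like(d)
        gy = o.grad
        for wy, yi in (((1 - fy), y0), (fy, y1)):
            rows = gy * wy
            for wx, xi in (((1 - fx), x0), (fx, x1)):
                np.add.at(g, (slice(None), slice(None),
                              yi[:, None], xi[None, :]), rows * wx)
        x._accumulate(g)

    return Tensor._make(out.astype(d.dtype), (x,), bwd)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization; updates running stats in place."""
    x = as_tensor(x)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    muc = mu.reshape(1, -1, 1, 1)
    invc = inv.reshape(1, -1, 1, 1)
    xhat = (x.data - muc) * invc
    out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bwd(o: Tensor) -> None:
        gy = o.grad
        if gamma.requires_grad:
            gamma._accumulate((gy * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(gy.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = gy * gamma.data.reshape(1, -1, 1, 1)
            if training:
                s1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                s2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = invc * (gxhat - s1 / m - xhat * s2 / m)
            else:
                gx = gxhat * invc
            x._accumulate(gx)

    return Tensor._make(out.astype(x.data.dtype), (x, gamma, beta), bwd)
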
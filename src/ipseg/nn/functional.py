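"""Differentiable neural-network primitives with hand-written backwards.

Convolution uses a tap-loop im2col (at most ``kh*kw`` slice copies) feeding a
single BLAS matmul, which is the fastest portable strategy at the feature-map
sizes this package works with.  Resampling is separable linear interpolation
with half-pixel centers; its adjoint is an ``np.add.at`` scatter.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, accumulate, make_node

__all__ = [
    "conv2d",
    "conv1d",
    "batch_norm",
    "resize_linear_1d",
    "resize_bilinear",
    "adaptive_avg_pool_1d",
    "softmax_cross_entropy",
    "softmax",
]


def _pair(v):
    return v if isinstance(v, tuple) else (v, v)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride=1,
           dilation=1, padding=0) -> Tensor:
    """2D cross-correlation: x (N,C,H,W), w (O,C,kh,kw) -> (N,O,Ho,Wo)."""
    sh, sw = _pair(stride)
    dh, dw = _pair(dilation)
    ph, pw = _pair(padding)
    xd = x.data
    n, c, h, wdt = xd.shape
    o, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {ci}")
    xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else xd
    eh = dh * (kh - 1) + 1
    ew = dw * (kw - 1) + 1
    ho = (h + 2 * ph - eh) // sh + 1
    wo = (wdt + 2 * pw - ew) // sw + 1
    if ho < 1 or wo < 1:
        raise ValueError("kernel (with dilation) exceeds padded input extent")

    col = np.empty((n, c, kh, kw, ho, wo), dtype=xd.dtype)
    for a in range(kh):
        for bb in range(kw):
            col[:, :, a, bb] = xp[:, :,
                                  a * dh: a * dh + (ho - 1) * sh + 1: sh,
                                  bb * dw: bb * dw + (wo - 1) * sw + 1: sw]
    col2 = col.reshape(n, c * kh * kw, ho * wo)
    wm = w.data.reshape(o, c * kh * kw)
    out = np.matmul(wm, col2).reshape(n, o, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2 = g.reshape(n, o, ho * wo)
        if b is not None and b.requires_grad:
            accumulate(b, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.matmul(g2, col2.transpose(0, 2, 1)).sum(axis=0)
            accumulate(w, gw.reshape(w.data.shape))
        if x.requires_grad:
            gcol = np.matmul(wm.T, g2).reshape(n, c, kh, kw, ho, wo)
            gxp = np.zeros_like(xp)
            for a in range(kh):
                for bb in range(kw):
                    gxp[:, :,
                        a * dh: a * dh + (ho - 1) * sh + 1: sh,
                        bb * dw: bb * dw + (wo - 1) * sw + 1: sw] += gcol[:, :, a, bb]
            gx = gxp[:, :, ph: ph + h, pw: pw + wdt] if (ph or pw) else gxp
            accumulate(x, gx)

    return make_node(out, parents, backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride=1,
           padding=0) -> Tensor:
    """1D cross-correlation over (N,C,L) via the 2D kernel with height 1."""
    n, c, ln = x.data.shape
    o, ci, k = w.data.shape
    x4 = x.reshape((n, c, 1, ln))
    w4 = w.reshape((o, ci, 1, k))
    out = conv2d(x4, w4, b, stride=(1, stride), padding=(0, padding))
    return out.reshape((n, o, out.shape[-1]))


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, *, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Batch normalization over all axes except channel axis 1.

    ``running_mean``/``running_var`` are plain arrays updated in place during
    training (biased variance in the normalizer, unbiased in the running
    estimate, matching common deep-learning practice).
    """
    xd = x.data
    axes = (0,) + tuple(range(2, xd.ndim))
    shape = [1] * xd.ndim
    shape[1] = xd.shape[1]
    m = xd.size // xd.shape[1]

    if training:
        mean = xd.mean(axis=axes)
        var = xd.var(axis=axes)
        if m > 1:
            running_var *= (1.0 - momentum)
            running_var += momentum * var * (m / (m - 1))
        else:  # degenerate single-element batch: keep the biased estimate
            running_var *= (1.0 - momentum)
            running_var += momentum * var
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
    else:
        mean = running_mean
        var = running_var

    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean.reshape(shape)) * ivar.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def backward(g):
        if gamma.requires_grad:
            accumulate(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            accumulate(beta, g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data.reshape(shape)
            if training:
                t1 = dxhat.sum(axis=axes, keepdims=True)
                t2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                gx = (ivar.reshape(shape) / m) * (m * dxhat - t1 - xhat * t2)
            else:
                gx = dxhat * ivar.reshape(shape)
            accumulate(x, gx)

    return make_node(out, (x, gamma, beta), backward)


def _linear_resize_coords(in_len: int, out_len: int):
    """Half-pixel-center source coordinates, clamped (edge replication)."""
    src = (np.arange(out_len) + 0.5) * (in_len / out_len) - 0.5
    src = np.clip(src, 0.0, in_len - 1.0)
    i0 = np.floor(src).astype(np.intp)
    i0 = np.minimum(i0, in_len - 1)
    i1 = np.minimum(i0 + 1, in_len - 1)
    t = src - i0
    return i0, i1, t


def resize_linear_1d(x: Tensor, out_len: int, axis: int = -1) -> Tensor:
    """Linear interpolation along one axis (half-pixel centers)."""
    axis = axis % x.ndim
    in_len = x.shape[axis]
    i0, i1, t = _linear_resize_coords(in_len, out_len)
    xd = np.moveaxis(x.data, axis, -1)
    tt = t.astype(xd.dtype)
    out = xd[..., i0] * (1.0 - tt) + xd[..., i1] * tt
    out = np.moveaxis(out, -1, axis)

    def backward(g):
        gm = np.moveaxis(g, axis, -1)
        gx = np.zeros(np.moveaxis(x.data, axis, -1).shape, dtype=g.dtype)
        np.add.at(gx, (..., i0), gm * (1.0 - tt))
        np.add.at(gx, (..., i1), gm * tt)
        accumulate(x, np.moveaxis(gx, -1, axis))

    return make_node(out, (x,), backward)


def resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of the two trailing axes of (..., H, W)."""
    y = resize_linear_1d(x, out_h, axis=-2)
    return resize_linear_1d(y, out_w, axis=-1)


def adaptive_avg_pool_1d(x: Tensor, out_len: int) -> Tensor:
    """Average pooling over contiguous bins covering the last axis.

    Bin ``k`` covers ``[floor(kL/M), ceil((k+1)L/M))``; every input position
    belongs to at least one bin, so a constant input stays constant.
    """
    in_len = x.shape[-1]
    if out_len < 1:
        raise ValueError("output length must be >= 1")
    starts = (np.arange(out_len) * in_len) // out_len
    ends = -((-(np.arange(1, out_len + 1) * in_len)) // out_len)
    out = np.stack([x.data[..., s:e].mean(axis=-1)
                    for s, e in zip(starts, ends)], axis=-1)

    def backward(g):
        gx = np.zeros_like(x.data)
        for k, (s, e) in enumerate(zip(starts, ends)):
            gx[..., s:e] += g[..., k:k + 1] / (e - s)
        accumulate(x, gx)

    return make_node(out, (x,), backward)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean pixelwise cross-entropy.

    logits: (N, K, *spatial); target: integer class indices (N, *spatial).
    """
    ld = logits.data
    n_classes = ld.shape[1]
    target = np.asarray(target)
    if target.shape != ld.shape[:1] + ld.shape[2:]:
        raise ValueError(f"target shape {target.shape} does not match logits "
                         f"{ld.shape}")
    if target.min() < 0 or target.max() >= n_classes:
        raise ValueError("target labels out of range")
    z = ld - ld.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    log_probs = z - logsumexp
    onehot_sel = np.take_along_axis(log_probs, target[:, None], axis=1)[:, 0]
    count = onehot_sel.size
    loss = -onehot_sel.sum() / count

    def backward(g):
        if logits.requires_grad:
            grad = np.exp(log_probs)  # softmax; subtract 1 at the target class
            np.put_along_axis(
                grad, target[:, None],
                np.take_along_axis(grad, target[:, None], axis=1) - 1.0,
                axis=1)
            accumulate(logits, grad * (g / count))

    return make_node(np.asarray(loss, dtype=ld.dtype), (logits,), backward)
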
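"""Low-level array operations: convolution, pooling, activations.

All operators are written directly in NumPy with explicit forward and
backward (adjoint) routines, since training rules in this package manipulate
error signals by hand rather than relying on an autodiff graph.

Conventions
-----------
* images are channel-first ``(N, C, H, W)`` float arrays in ``[0, 1]``
* convolution weights are ``(C_out, C_in, k, k)``; no bias terms anywhere
  (the forward computation is ``h = W x``)
* max-pool ties break on the first (row-major) index, so traces are
  bit-reproducible
"""

from __future__ import annotations

import numpy as np


class NumericError(RuntimeError):
    """Raised when a computation produces non-finite values."""


def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold sliding windows of ``x`` into columns.

    Returns ``(cols, out_h, out_w)`` where ``cols`` has shape
    ``(N, C*k*k, out_h*out_w)``.
    """
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    if oh < 1 or ow < 1:
        raise ValueError(
            f"kernel {k} (stride {stride}, pad {pad}) does not fit "
            f"input of spatial size {h}x{w}"
        )
    s = x.strides
    win = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, oh, ow, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back onto an image."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols6[
                :, :, i, j
            ]
    if pad:
        return xp[:, :, pad : pad + h, pad : pad + w]
    return xp


def conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int | None = None) -> np.ndarray:
    """2-D cross-correlation, ``y = W * x`` with 'same'-style default padding."""
    co, ci, k, _ = w.shape
    if pad is None:
        pad = (k - 1) // 2
    if x.shape[1] != ci:
        raise ValueError(f"input has {x.shape[1]} channels, weight expects {ci}")
    cols, oh, ow = im2col(x, k, stride, pad)
    y = np.einsum("oc,ncl->nol", w.reshape(co, -1), cols, optimize=True)
    return y.reshape(x.shape[0], co, oh, ow)


def conv2d_grad_input(dy: np.ndarray, w: np.ndarray, x_shape, stride: int = 1,
                      pad: int | None = None) -> np.ndarray:
    """Gradient of ``conv2d`` w.r.t. its input; also the transposed convolution."""
    co, ci, k, _ = w.shape
    n = dy.shape[0]
    if pad is None:
        pad = (k - 1) // 2
    dyf = dy.reshape(n, co, -1)
    cols = np.einsum("oc,nol->ncl", w.reshape(co, -1), dyf, optimize=True)
    return col2im(cols, x_shape, k, stride, pad)


def conv2d_grad_weight(dy: np.ndarray, x: np.ndarray, k: int, stride: int = 1,
                       pad: int | None = None) -> np.ndarray:
    """Gradient of ``conv2d`` w.r.t. the weight, summed over the batch."""
    n, co = dy.shape[0], dy.shape[1]
    ci = x.shape[1]
    if pad is None:
        pad = (k - 1) // 2
    cols, _, _ = im2col(x, k, stride, pad)
    dyf = dy.reshape(n, co, -1)
    dw = np.einsum("nol,ncl->oc", dyf, cols, optimize=True)
    return dw.reshape(co, ci, k, k)


def maxpool(x: np.ndarray, size: int):
    """Non-overlapping max pooling; returns ``(y, argmax)``.

    Trailing rows/columns that do not fill a window are dropped (floor
    semantics). ``argmax`` holds the flat within-window index of the
    maximum, first occurrence winning ties.
    """
    n, c, h, w = x.shape
    oh, ow = h // size, w // size
    if oh < 1 or ow < 1:
        raise ValueError(f"pool size {size} larger than input {h}x{w}")
    xc = (
        x[:, :, : oh * size, : ow * size]
        .reshape(n, c, oh, size, ow, size)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, oh, ow, size * size)
    )
    idx = xc.argmax(axis=-1)
    y = np.take_along_axis(xc, idx[..., None], axis=-1)[..., 0]
    return y, idx


def maxpool_grad(dy: np.ndarray, idx: np.ndarray, x_shape, size: int) -> np.ndarray:
    """Route pooled error back to the recorded argmax positions."""
    n, c, h, w = x_shape
    oh, ow = h // size, w // size
    gwin = np.zeros((n, c, oh, ow, size * size), dtype=dy.dtype)
    np.put_along_axis(gwin, idx[..., None], dy[..., None], axis=-1)
    g = np.zeros(x_shape, dtype=dy.dtype)
    g[:, :, : oh * size, : ow * size] = (
        gwin.reshape(n, c, oh, ow, size, size)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, oh * size, ow * size)
    )
    return g


def avgpool(x: np.ndarray, size: int) -> np.ndarray:
    n, c, h, w = x.shape
    oh, ow = h // size, w // size
    if oh < 1 or ow < 1:
        raise ValueError(f"pool size {size} larger than input {h}x{w}")
    return (
        x[:, :, : oh * size, : ow * size]
        .reshape(n, c, oh, size, ow, size)
        .mean(axis=(3, 5))
    )


def avgpool_grad(dy: np.ndarray, x_shape, size: int) -> np.ndarray:
    n, c, h, w = x_shape
    oh, ow = h // size, w // size
    g = np.zeros(x_shape, dtype=dy.dtype)
    spread = np.repeat(np.repeat(dy, size, axis=2), size, axis=3) / (size * size)
    g[:, :, : oh * size, : ow * size] = spread
    return g


# ---------------------------------------------------------------------------
# element-wise nonlinearities

def activate(h: np.ndarray, kind: str) -> np.ndarray:
    if kind == "none":
        return h
    if kind == "hardtanh":
        return np.clip(h, -1.0, 1.0)
    if kind == "tanh":
        return np.tanh(h)
    raise ValueError(f"unknown activation {kind!r}")


def activation_grad(h: np.ndarray, x: np.ndarray, kind: str) -> np.ndarray:
    """sigma'(h) given pre-activation ``h`` and post-activation ``x = sigma(h)``.

    hardtanh' is the 0/1 indicator of the open linear region (-1, 1).
    """
    if kind == "none":
        return np.ones_like(h)
    if kind == "hardtanh":
        return ((h > -1.0) & (h < 1.0)).astype(h.dtype)
    if kind == "tanh":
        return 1.0 - x * x
    raise ValueError(f"unknown activation {kind!r}")


def check_finite(a: np.ndarray, where: str) -> None:
    if not np.all(np.isfinite(a)):
        raise NumericError(f"non-finite values in {where}")
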
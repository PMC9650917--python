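"""Neural-network operations built on the autograd tape.

Convolution uses im2col + BLAS matmul; its backward pass is registered
manually because the column gather/scatter is cheaper hand-written than
composed from primitive ops.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d",
    "max_pool2d",
    "softmax",
    "log_softmax",
    "l2_normalize",
    "cross_entropy",
]


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, OH*OW)."""
    n, c, h, w = x.shape
    oh, ow = _out_size(h, kh, stride, pad), _out_size(w, kw, stride, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * kh * kw, oh * ow)


def _col2im(
    cols: np.ndarray,
    x_shape: tuple[int, ...],
    kh: int,
    kw: int,
    stride: int,
    pad: int,
) -> np.ndarray:
    """Adjoint of `_im2col`: scatter-add columns back to (N,C,H,W)."""
    n, c, h, w = x_shape
    oh, ow = _out_size(h, kh, stride, pad), _out_size(w, kw, stride, pad)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    if pad:
        xp = xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. x: (N,C,H,W); weight: (O,C,kh,kw); bias: (O,)."""
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.shape
    o, ci, kh, kw = weight.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input has {c}, weight expects {ci}")
    oh, ow = _out_size(h, kh, stride, padding), _out_size(w, kw, stride, padding)
    cols = _im2col(x.data, kh, kw, stride, padding)  # (N, K, P)
    wm = weight.data.reshape(o, -1)  # (O, K)
    out_data = np.matmul(wm, cols).reshape(n, o, oh, ow)

    parents = (x, weight)

    def bwd(g):
        g2 = g.reshape(n, o, oh * ow)  # (N, O, P)
        if weight.requires_grad:
            gw = np.einsum("nop,nkp->ok", g2, cols, optimize=True)
            weight._accumulate(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = np.matmul(wm.T, g2)  # (N, K, P)
            x._accumulate(_col2im(gcols, x.shape, kh, kw, stride, padding))

    out = Tensor(out_data, _parents=parents, _backward=bwd)
    if bias is not None:
        out = out + as_tensor(bias).reshape(1, o, 1, 1)
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Max pooling over (N,C,H,W). Padded positions are -inf (never selected)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    oh, ow = _out_size(h, kernel, stride, padding), _out_size(w, kernel, stride, padding)
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)), constant_values=-np.inf)
    windows = np.empty((n, c, kernel * kernel, oh, ow), dtype=x.data.dtype)
    for i in range(kernel):
        for j in range(kernel):
            windows[:, :, i * kernel + j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    arg = windows.argmax(axis=2)  # (N,C,OH,OW)
    out_data = np.take_along_axis(windows, arg[:, :, None], axis=2)[:, :, 0]

    def bwd(g):
        if not x.requires_grad:
            return
        gw = np.zeros((n, c, kernel * kernel, oh, ow), dtype=g.dtype)
        np.put_along_axis(gw, arg[:, :, None], g[:, :, None], axis=2)
        gw = gw.reshape(n, c, kernel, kernel, oh, ow)
        gxp = np.zeros(
            (n, c, h + 2 * padding, w + 2 * padding), dtype=g.dtype
        )
        for i in range(kernel):
            for j in range(kernel):
                gxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += gw[:, :, i, j]
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp)

    return Tensor(out_data, _parents=(x,), _backward=bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max subtracted as a constant)."""
    x = as_tensor(x)
    shift = x - x.data.max(axis=axis, keepdims=True)
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shift = x - x.data.max(axis=axis, keepdims=True)
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """Unit-normalize along `axis`, epsilon-guarded for the zero vector."""
    x = as_tensor(x)
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps**2) ** 0.5
    return x / norm


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax logits (N,K)."""
    labels = np.asarray(labels)
    n = logits.shape[0]
    logp = log_softmax(logits, axis=-1)
    picked = logp[np.arange(n), labels]
    return -picked.mean()
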
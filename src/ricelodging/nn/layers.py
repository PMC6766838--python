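"""Minimal NumPy layers with explicit backpropagation.

All tensors are NCHW ``float32`` by default (``float64`` supported for
numerical gradient checks).  Convolutions use im2col + BLAS matmul; im2col
buffers are rebuilt during the backward pass instead of cached, and the batch
is processed in chunks sized to cap the transient buffer, which keeps peak
memory modest for large feature maps.
"""

from __future__ import annotations

import numpy as np

# cap on a single im2col scratch buffer, in elements
_COL_BUDGET = 48_000_000


class Layer:
    """Base class: parameters in ``params``, gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        self.grads = {}


def _im2col(xp: np.ndarray, k: int, out_h: int, out_w: int) -> np.ndarray:
    """(C, hs+k-1, Wp) padded slab -> (C*k*k, out_h*out_w) columns."""
    c = xp.shape[0]
    cols = np.empty((c, k, k, out_h, out_w), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, i, j] = xp[:, i:i + out_h, j:j + out_w]
    return cols.reshape(c * k * k, out_h * out_w)


def _col2im(dcols: np.ndarray, dxp: np.ndarray, k: int, r0: int,
            out_h: int, out_w: int) -> None:
    """Scatter-add strip column gradients into the padded input gradient."""
    c = dxp.shape[0]
    dc = dcols.reshape(c, k, k, out_h, out_w)
    for i in range(k):
        for j in range(k):
            dxp[:, r0 + i:r0 + i + out_h, j:j + out_w] += dc[:, i, j]


class Conv2d(Layer):
    """2-D convolution, stride 1, square kernel with symmetric zero padding.

    im2col + matmul per sample, with output rows processed in strips sized so
    the column buffer never exceeds the budget; large inference tiles
    therefore run in bounded memory.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 pad: int | None = None, dtype=np.float32) -> None:
        super().__init__()
        if in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.pad = kernel // 2 if pad is None else pad
        self.params = {
            "weight": np.zeros((out_channels, in_channels, kernel, kernel), dtype=dtype),
            "bias": np.zeros(out_channels, dtype=dtype),
        }
        self._x: np.ndarray | None = None

    def _strip(self, h: int, w: int) -> int:
        rows = _COL_BUDGET // max(self.cin * self.k * self.k * w, 1)
        return int(min(max(rows, 1), h))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        self._x = x if train else None
        p, k = self.pad, self.k
        w2 = self.params["weight"].reshape(self.cout, -1)
        out = np.empty((n, self.cout, h, w), dtype=x.dtype)
        strip = self._strip(h, w)
        for s in range(n):
            xp = np.pad(x[s], ((0, 0), (p, p), (p, p)))
            for r0 in range(0, h, strip):
                hs = min(strip, h - r0)
                cols = _im2col(xp[:, r0:r0 + hs + k - 1], k, hs, w)
                out[s, :, r0:r0 + hs] = (w2 @ cols).reshape(self.cout, hs, w)
        out += self.params["bias"][None, :, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        if x is None:
            raise RuntimeError("backward before forward(train=True)")
        n, _, h, w = x.shape
        p, k = self.pad, self.k
        w2 = self.params["weight"].reshape(self.cout, -1)
        dw = np.zeros_like(w2)
        dx = np.empty_like(x)
        strip = self._strip(h, w)
        for s in range(n):
            xp = np.pad(x[s], ((0, 0), (p, p), (p, p)))
            dxp = np.zeros_like(xp)
            for r0 in range(0, h, strip):
                hs = min(strip, h - r0)
                cols = _im2col(xp[:, r0:r0 + hs + k - 1], k, hs, w)
                g = grad[s, :, r0:r0 + hs].reshape(self.cout, hs * w)
                dw += g @ cols.T
                _col2im(w2.T @ g, dxp, k, r0, hs, w)
            dx[s] = dxp[:, p:h + p, p:w + p] if p else dxp
        self.grads = {
            "weight": dw.reshape(self.params["weight"].shape),
            "bias": grad.sum(axis=(0, 2, 3)),
        }
        return dx


class ConvTranspose2d(Layer):
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling)."""

    def __init__(self, in_channels: int, out_channels: int, dtype=np.float32) -> None:
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, 2
        self.params = {
            "weight": np.zeros((in_channels, out_channels, 2, 2), dtype=dtype),
            "bias": np.zeros(out_channels, dtype=dtype),
        }
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        self._x = x if train else None
        wgt = self.params["weight"]
        out = np.empty((n, self.cout, 2 * h, 2 * w), dtype=x.dtype)
        for i in range(2):
            for j in range(2):
                # out[:, :, 2r+i, 2c+j] = sum_cin x[:, cin, r, c] * w[cin, :, i, j]
                out[:, :, i::2, j::2] = np.tensordot(
                    x, wgt[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
        out += self.params["bias"][None, :, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        if x is None:
            raise RuntimeError("backward before forward(train=True)")
        wgt = self.params["weight"]
        dw = np.zeros_like(wgt)
        dx = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                g = grad[:, :, i::2, j::2]
                dw[:, :, i, j] = np.einsum("nchw,nohw->co", x, g, optimize=True)
                dx += np.tensordot(g, wgt[:, :, i, j], axes=([1], [1])
                                   ).transpose(0, 3, 1, 2)
        self.grads = {"weight": dw, "bias": grad.sum(axis=(0, 2, 3))}
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.c = channels
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "weight": np.ones(channels, dtype=dtype),
            "bias": np.zeros(channels, dtype=dtype),
        }
        self.buffers = {
            "running_mean": np.zeros(channels, dtype=dtype),
            "running_var": np.ones(channels, dtype=dtype),
        }
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            nobs = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * nobs / max(nobs - 1, 1)
            self.buffers["running_mean"] = (
                (1 - m) * self.buffers["running_mean"] + m * mean
            ).astype(x.dtype)
            self.buffers["running_var"] = (
                (1 - m) * self.buffers["running_var"] + m * unbiased
            ).astype(x.dtype)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd)
        return self.params["weight"][None, :, None, None] * xhat + \
            self.params["bias"][None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward before forward(train=True)")
        xhat, invstd = self._cache
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        dgamma = (grad * xhat).sum(axis=(0, 2, 3))
        dbeta = grad.sum(axis=(0, 2, 3))
        gscaled = grad * self.params["weight"][None, :, None, None]
        dx = (invstd[None, :, None, None] / n) * (
            n * gscaled
            - gscaled.sum(axis=(0, 2, 3), keepdims=True)
            - xhat * (gscaled * xhat).sum(axis=(0, 2, 3), keepdims=True)
        )
        self.grads = {"weight": dgamma, "bias": dbeta}
        self._cache = None
        return dx.astype(grad.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        self._mask = (x > 0) if train else None
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; even spatial dimensions required."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size {h}x{w} not divisible by 2")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(dflat, self._idx[..., None], grad[..., None], axis=-1)
        return dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
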
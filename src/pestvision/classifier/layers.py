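"""Numpy building blocks for the convolutional classifier.

Minimal forward/backward layers: im2col convolution, ReLU, overlapping
3x3/stride-2 max pooling, inverted dropout and dense layers.  Everything
is float32 and fully deterministic given the generator handed to
``forward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool", "Dropout", "Flatten", "Dense"]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N, C, H, W) -> (N*Ho*Wo, C*kh*kw) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                    # N, C, Ho, Wo, kh, kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add transpose of :func:`_im2col`."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = cols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for dy in range(kh):
        for dx in range(kw):
            out[:, :, dy : dy + stride * ho : stride, dx : dx + stride * wo : stride] += cols[
                :, :, :, :, dy, dx
            ]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


class Layer:
    params: list
    grads: list
    decay: list  # parallel to params: apply weight decay?

    def __init__(self):
        self.params, self.grads, self.decay = [], [], []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, in_channels, n_filters, kernel_size, stride=1, padding=0, *, rng, init_std=0.01):
        super().__init__()
        self.k, self.stride, self.pad = kernel_size, stride, padding
        shape = (n_filters, in_channels * kernel_size * kernel_size)
        self.w = rng.normal(0.0, init_std, shape).astype(np.float32)
        self.b = np.zeros(n_filters, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.decay = [True, False]

    def forward(self, x, train=False, rng=None):
        cols, ho, wo = _im2col(x, self.k, self.k, self.stride, self.pad)
        self._cache = (cols, x.shape, ho, wo)
        out = cols @ self.w.T + self.b
        return out.reshape(x.shape[0], ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, g):
        cols, x_shape, ho, wo = self._cache
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, self.w.shape[0])
        self.grads[0][...] = g2.T @ cols
        self.grads[1][...] = g2.sum(axis=0)
        dcols = g2 @ self.w
        return _col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool(Layer):
    """Overlapping max pooling (3x3 window, stride 2 by default)."""

    def __init__(self, size=3, stride=2):
        super().__init__()
        self.size, self.stride = size, stride

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        k, s = self.size, self.stride
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n_, c_, ho, wo, _, _ = win.shape
        flat = win.reshape(n, c, ho, wo, k * k)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, arg, ho, wo)
        return out

    def backward(self, g):
        (n, c, h, w), arg, ho, wo = self._cache
        k, s = self.size, self.stride
        dx = np.zeros((n, c, h * w), dtype=g.dtype)
        hy = np.arange(ho)[:, None] * s
        wx = np.arange(wo)[None, :] * s
        base = hy * w + wx                                  # (ho, wo) top-left flat index
        offset = (arg // k) * w + (arg % k)                 # (n, c, ho, wo)
        flat_idx = base[None, None] + offset
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(dx, (ni, ci, flat_idx), g)
        return dx.reshape(n, c, h, w)


class Dropout(Layer):
    """Inverted dropout: scaling happens at train time, eval is identity."""

    def __init__(self, ratio):
        super().__init__()
        if not (0.0 <= ratio < 1.0):
            raise ValueError("dropout ratio must lie in [0, 1)")
        self.ratio = ratio

    def forward(self, x, train=False, rng=None):
        if not train or self.ratio == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.ratio
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, *, rng, init_std=0.01):
        super().__init__()
        self.w = rng.normal(0.0, init_std, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.decay = [True, False]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.w.T
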
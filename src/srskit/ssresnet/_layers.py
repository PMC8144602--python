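"""NumPy building blocks for the spatial-spectral residual network.

Feature maps are rank-5 arrays ordered (batch, channels, lambda, y, x).
Every layer implements ``forward`` (caching what backward needs) and
``backward`` (returning the gradient with respect to its input and storing
parameter gradients in ``.grads``).  All parameters and activations are
float32; gradients are accumulated in float32 as well.

The separable spatial-spectral convolution pair is the point here: a
1x3x3 kernel sees spatial neighbourhoods within one spectral plane, a 3x1x1
kernel sees the spectrum of a single pixel, and their sum replaces a full
3x3x3 kernel at a third of the cost while respecting the different physical
correlations of the two domains.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv1x1",
    "SpatialConv3x3",
    "SpectralConv3",
    "SSConvBlock",
    "MaxPoolYX",
    "UpsampleYX",
    "Adam",
]

_DT = np.float32


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(_DT)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv1x1(Layer):
    """Pointwise (1x1x1) convolution, optionally followed by ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 relu: bool = False) -> None:
        super().__init__()
        self.c_in, self.c_out, self.relu = c_in, c_out, relu
        self.W = _he_init(rng, (c_out, c_in), c_in)
        self.b = np.zeros(c_out, dtype=_DT)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out = np.einsum("oc,ncdyx->nodyx", self.W, x, optimize=True)
        out += self.b[None, :, None, None, None]
        if self.relu:
            self._mask = out > 0
            out = np.where(self._mask, out, 0.0)
        return out.astype(_DT, copy=False)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.relu:
            g = np.where(self._mask, g, 0.0)
        self.grads[0] += np.einsum("nodyx,ncdyx->oc", g, self._x, optimize=True)
        self.grads[1] += g.sum(axis=(0, 2, 3, 4))
        return np.einsum("oc,nodyx->ncdyx", self.W, g, optimize=True).astype(_DT, copy=False)


def _conv_spatial(x: np.ndarray, Wmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded 1x3x3 correlation.  Wmat is (c_out, c_in*9)."""
    n, c, d, h, w = x.shape
    xpad = np.pad(x, ((0, 0), (0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xpad, (3, 3), axis=(3, 4))  # (n,c,d,h,w,3,3)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6)).reshape(-1, c * 9)
    out = cols @ Wmat.T  # (n*d*h*w, c_out)
    out = out.reshape(n, d, h, w, -1).transpose(0, 4, 1, 2, 3)
    return out.astype(_DT, copy=False), cols


def _conv_spectral(x: np.ndarray, Wmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded 3x1x1 correlation along the spectral axis."""
    n, c, d, h, w = x.shape
    xpad = np.pad(x, ((0, 0), (0, 0), (1, 1), (0, 0), (0, 0)))
    win = sliding_window_view(xpad, 3, axis=2)  # (n,c,d,h,w,3)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5)).reshape(-1, c * 3)
    out = cols @ Wmat.T
    out = out.reshape(n, d, h, w, -1).transpose(0, 4, 1, 2, 3)
    return out.astype(_DT, copy=False), cols


class SpatialConv3x3(Layer):
    """1x3x3 convolution (same padding, no bias)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.W = _he_init(rng, (c_out, c_in, 3, 3), c_in * 9)
        self.params = [self.W]
        self.grads = [np.zeros_like(self.W)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        out, self._cols = _conv_spatial(x, self.W.reshape(self.c_out, -1))
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, _, d, h, w = self._shape
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, self.c_out)
        self.grads[0] += (gmat.T @ self._cols).reshape(self.W.shape)
        dcols = (gmat @ self.W.reshape(self.c_out, -1)).reshape(n, d, h, w, self.c_in, 3, 3)
        dxpad = np.zeros((n, self.c_in, d, h + 2, w + 2), dtype=_DT)
        for i in range(3):
            for j in range(3):
                dxpad[:, :, :, i:i + h, j:j + w] += dcols[..., i, j].transpose(0, 4, 1, 2, 3)
        return dxpad[:, :, :, 1:-1, 1:-1]


class SpectralConv3(Layer):
    """3x1x1 convolution along the spectral axis (same padding, no bias)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.W = _he_init(rng, (c_out, c_in, 3), c_in * 3)
        self.params = [self.W]
        self.grads = [np.zeros_like(self.W)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        out, self._cols = _conv_spectral(x, self.W.reshape(self.c_out, -1))
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, _, d, h, w = self._shape
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, self.c_out)
        self.grads[0] += (gmat.T @ self._cols).reshape(self.W.shape)
        dcols = (gmat @ self.W.reshape(self.c_out, -1)).reshape(n, d, h, w, self.c_in, 3)
        dxpad = np.zeros((n, self.c_in, d + 2, h, w), dtype=_DT)
        for i in range(3):
            dxpad[:, :, i:i + d] += dcols[..., i].transpose(0, 4, 1, 2, 3)
        return dxpad[:, :, 1:-1]


class SSConvBlock(Layer):
    """Parallel spatial (1x3x3) and spectral (3x1x1) paths, summed, biased, ReLU.

    Channel count is preserved (channel changes are the 1x1x1 layers' job).
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 relu: bool = True) -> None:
        super().__init__()
        self.channels, self.relu = channels, relu
        self.spatial = SpatialConv3x3(channels, channels, rng)
        self.spectral = SpectralConv3(channels, channels, rng)
        self.b = np.zeros(channels, dtype=_DT)
        self.params = self.spatial.params + self.spectral.params + [self.b]
        self.grads = self.spatial.grads + self.spectral.grads + [np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.spatial.forward(x) + self.spectral.forward(x)
        out += self.b[None, :, None, None, None]
        if self.relu:
            self._mask = out > 0
            out = np.where(self._mask, out, 0.0)
        return out.astype(_DT, copy=False)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self.relu:
            g = np.where(self._mask, g, 0.0)
        self.grads[-1] += g.sum(axis=(0, 2, 3, 4))
        return self.spatial.backward(g) + self.spectral.backward(g)


class MaxPoolYX(Layer):
    """Spatial-only (1,2,2) max pooling; the spectral axis is left intact."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, d, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for (1,2,2) pooling")
        win = x.reshape(n, c, d, h // 2, 2, w // 2, 2)
        flat = win.transpose(0, 1, 2, 3, 5, 4, 6).reshape(n, c, d, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        dflat = np.zeros((n, c, d, h // 2, w // 2, 4), dtype=_DT)
        np.put_along_axis(dflat, self._arg[..., None], g[..., None], axis=-1)
        dwin = dflat.reshape(n, c, d, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 3, 5, 4, 6)
        return dwin.reshape(n, c, d, h, w)


class UpsampleYX(Layer):
    """Nearest-neighbour (1,2,2) spatial upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=3), 2, axis=4)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, d, h, w = g.shape
        return g.reshape(n, c, d, h // 2, 2, w // 2, 2).sum(axis=(4, 6)).astype(_DT, copy=False)


class Adam:
    """Adaptive-moment gradient descent over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= (self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)).astype(p.dtype)
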
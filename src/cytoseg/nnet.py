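"""A minimal CPU convolutional-network engine with manual backpropagation.

Only what the segmentation and detection models need: 2-D convolution (with
dilation), 2x2 transposed convolution, 2x2 max pooling, nearest upsampling,
ReLU, dropout, channel concatenation, softmax/sigmoid heads and plain SGD
with an explicit L2 weight penalty.  Arrays are ``(N, C, H, W)`` float64.

Every layer instance caches what its single forward pass needs and exposes a
matching ``backward``; models wire layers explicitly and mirror the wiring
in their backward passes.  All parameter initialisation is driven by a
caller-supplied :class:`numpy.random.Generator`, so training is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Param", "Conv2d", "ConvTranspose2x2", "MaxPool2x2", "NearestUpsample2x2",
    "ReLU", "Dropout", "SGD", "softmax", "sigmoid", "he_init",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "decay")

    def __init__(self, data: np.ndarray, decay: bool = True):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.decay = decay  # participates in L2 penalty (weights yes, biases no)


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _im2col(x: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patches under 'same' padding."""
    n, c, h, w = x.shape
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i * dilation:i * dilation + h,
                                  j * dilation:j * dilation + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, x_shape: tuple[int, ...], k: int, dilation: int) -> np.ndarray:
    n, c, h, w = x_shape
    pad = dilation * (k - 1) // 2
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            xp[:, :, i * dilation:i * dilation + h,
               j * dilation:j * dilation + w] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w] if pad else xp


class Conv2d:
    """Same-padded k x k convolution, optionally dilated; stride 1."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 dilation: int = 1):
        if k % 2 != 1 or k < 1:
            raise ValueError("kernel size must be odd and >= 1")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        self.k, self.dilation = k, dilation
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = Param(he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k))
        self.b = Param(np.zeros(out_ch), decay=False)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, _c, h, w = x.shape
        col = _im2col(x, self.k, self.dilation)
        wm = self.w.data.reshape(self.out_ch, -1)
        out = np.matmul(wm, col) + self.b.data[None, :, None]
        self._cache = (x.shape, col)
        return out.reshape(n, self.out_ch, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, col = self._cache
        n, _o, h, w = dout.shape
        dflat = dout.reshape(n, self.out_ch, h * w)
        self.w.grad += np.matmul(dflat, col.transpose(0, 2, 1)).sum(axis=0).reshape(self.w.data.shape)
        self.b.grad += dflat.sum(axis=(0, 2))
        wm = self.w.data.reshape(self.out_ch, -1)
        dcol = np.matmul(wm.T, dflat)
        return _col2im(dcol, x_shape, self.k, self.dilation)


class ConvTranspose2x2:
    """2x2, stride-2 transposed convolution (non-overlapping upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.w = Param(he_init(rng, (in_ch, out_ch, 2, 2), in_ch))
        self.b = Param(np.zeros(out_ch), decay=False)
        self._x = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, _c, h, w = x.shape
        self._x = x
        # out[n,o,2h+i,2w+j] = sum_c W[c,o,i,j] x[n,c,h,w] + b[o]
        y = np.einsum("coij,nchw->noijhw", self.w.data, x)  # i,j in {0,1}
        y = y.transpose(0, 1, 4, 2, 5, 3).reshape(n, self.out_ch, 2 * h, 2 * w)
        return y + self.b.data[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        n, _c, h, w = x.shape
        d = dout.reshape(n, self.out_ch, h, 2, w, 2).transpose(0, 1, 3, 5, 2, 4)
        self.w.grad += np.einsum("noijhw,nchw->coij", d, x)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        return np.einsum("coij,noijhw->nchw", self.w.data, d)


class MaxPool2x2:
    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pooling needs even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        self._cache = (x.shape, idx)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, idx = self._cache
        n, c, h, w = x_shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class NearestUpsample2x2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ReLU:
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout:
    """Inverted dropout; identity when inactive (inference)."""

    def __init__(self, p: float):
        if not (0.0 <= p <= 1.0):
            raise ValueError("dropout probability must lie in [0, 1]")
        self.p = p
        self._mask = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray, axis: int = 1) -> np.ndarray:
    """Gradient w.r.t. logits given gradient w.r.t. softmax outputs."""
    inner = (dprobs * probs).sum(axis=axis, keepdims=True)
    return probs * (dprobs - inner)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SGD:
    """Plain stochastic gradient descent with explicit L2 weight penalty."""

    def __init__(self, params: list[Param], lr: float, l2_lambda: float = 0.0,
                 grad_clip: float | None = None):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        if l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")
        self.params = params
        self.lr = lr
        self.l2 = l2_lambda
        self.grad_clip = grad_clip  # global gradient-norm ceiling

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        scale = 1.0
        if self.grad_clip is not None:
            total = math.sqrt(sum(float(np.sum(p.grad ** 2)) for p in self.params))
            if total > self.grad_clip:
                scale = self.grad_clip / total
        for p in self.params:
            g = p.grad if scale == 1.0 else p.grad * scale
            if self.l2 and p.decay:
                g = g + self.l2 * p.data
            p.data -= self.lr * g


def save_params(path, named_params: dict[str, Param]) -> None:
    np.savez(path, **{k: p.data for k, p in named_params.items()})


def load_params(path, named_params: dict[str, Param]) -> None:
    with np.load(path) as data:
        for k, p in named_params.items():
            p.data[...] = data[k]
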
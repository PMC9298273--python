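"""Minimal feed-forward network engine on numpy.

Provides exactly what the classifier stack needs: 3x3 strided
convolutions, ReLU, global average pooling and a dense head, trained with
stochastic gradient descent on the softmax cross-entropy loss, with full
backpropagation to the *input* so that path-integral attribution can reuse
the same machinery.  Convolution is im2col + matmul; the backward pass
scatters gradients back with the mirrored loop, so both directions are
exact (not approximated) gradients.

All randomness flows through a ``numpy.random.Generator`` supplied by the
caller; given the same generator state and data, training is bit-for-bit
reproducible on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "GlobalAvgPool", "Dense", "Flatten",
           "Sequential", "SmallCNN", "LinearNet",
           "softmax", "cross_entropy_grad", "sgd_step"]


class Conv2D:
    """3x3 (or kxk) convolution with stride and zero padding."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad
        fan_in = in_ch * k * k
        # He-normal init suits the ReLU blocks that follow
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch))
        self.b = np.zeros(out_ch)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _out_hw(self, h: int, w: int) -> tuple[int, int]:
        return ((h + 2 * self.pad - self.k) // self.stride + 1,
                (w + 2 * self.pad - self.k) // self.stride + 1)

    def _im2col(self, xp: np.ndarray, oh: int, ow: int) -> np.ndarray:
        n, c = xp.shape[:2]
        s, k = self.stride, self.k
        cols = np.empty((n, oh, ow, c, k, k), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[..., i, j] = xp[:, :, i:i + s * oh:s, j:j + s * ow:s].transpose(0, 2, 3, 1)
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self._out_hw(h, w)
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = self._im2col(xp, oh, ow)
        self._cache = (cols.reshape(n * oh * ow, -1), (n, c, h, w), (oh, ow))
        out = self._cache[0] @ self.W + self.b
        return out.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols2d, (n, c, h, w), (oh, ow) = self._cache
        d2 = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch)
        self.dW += cols2d.T @ d2
        self.db += d2.sum(axis=0)
        dcols = (d2 @ self.W.T).reshape(n, oh, ow, c, self.k, self.k)
        p, s, k = self.pad, self.stride, self.k
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[..., i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU:
    params: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool:
    """(N, C, H, W) -> (N, C) spatial mean."""

    params: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Flatten:
    params: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backpropagate to the input, accumulating parameter gradients."""
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0

    def input_gradient(self, x: np.ndarray, class_index: np.ndarray | int) -> np.ndarray:
        """d(logit of ``class_index``)/d(input), batched; leaves parameter
        gradients untouched in expectation by zeroing before and after."""
        logits = self.forward(x)
        dout = np.zeros_like(logits)
        idx = np.broadcast_to(np.asarray(class_index), (x.shape[0],))
        dout[np.arange(x.shape[0]), idx] = 1.0
        self.zero_grad()
        dx = self.backward(dout)
        self.zero_grad()
        return dx


def SmallCNN(rng: np.random.Generator, in_ch: int = 3,
             channels: tuple[int, ...] = (8, 16, 32, 32),
             n_classes: int = 2) -> Sequential:
    """Four stride-2 conv/ReLU blocks, global average pooling, 2-way head.

    ~15k parameters at the default widths; intended for training from
    scratch on modest synthetic datasets.
    """
    layers: list = []
    prev = in_ch
    for ch in channels:
        layers += [Conv2D(prev, ch, rng, stride=2, pad=1), ReLU()]
        prev = ch
    layers += [GlobalAvgPool(), Dense(prev, n_classes, rng)]
    return Sequential(layers)


def LinearNet(rng: np.random.Generator, input_shape: tuple[int, int, int],
              n_classes: int = 2) -> Sequential:
    """Single dense layer on the flattened image: a linear scorer."""
    c, h, w = input_shape
    return Sequential([Flatten(), Dense(c * h * w, n_classes, rng)])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    return loss, g / n


def sgd_step(model: Sequential, lr: float, momentum: float = 0.0,
             velocity: list[np.ndarray] | None = None) -> list[np.ndarray]:
    """In-place SGD update; returns the (possibly new) velocity buffers."""
    params = model.params
    if velocity is None:
        velocity = [np.zeros_like(p) for p, _ in params]
    for v, (p, g) in zip(velocity, params):
        v *= momentum
        v -= lr * g
        p += v
    return velocity
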
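"""Minimal convolutional network in numpy for binary crop classification.

Three 3x3 conv blocks (conv + ReLU + 2x2 max-pool) and a small dense head
with softmax cross-entropy, trained by Adam.  Everything is plain numpy
matmuls via im2col, so training is deterministic for a fixed seed and the
gradients can be (and are, in the test suite) verified against numerical
differentiation.

Images enter as ``(N, H, W)`` arrays in [0, 1]; the network is built for a
fixed square input size (default 32).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallCNN"]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for stride-1 'same' conv."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    n, c, h, w = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


def _col2im(cols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    cols = cols.reshape(n, h, w, c, k, k)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di:di + h, dj:dj + w] += cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    return dxp[:, :, pad:pad + h, pad:pad + w]


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        self.k, self.pad = k, k // 2
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, scale, (c_out, c_in * k * k))
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        self.cols = _im2col(x, self.k, self.pad)
        n, c, h, w = x.shape
        out = self.cols @ self.W.T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
        self.dW = dflat.T @ self.cols
        self.db = dflat.sum(0)
        dcols = dflat @ self.W
        return _col2im(dcols, self.x_shape, self.k, self.pad)

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout):
        return dout * self.mask


class _MaxPool2:
    """2x2 stride-2 max pooling (input H, W must be even)."""

    params: list = []
    grads: list = []

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self.arg = flat.argmax(-1)
        self.in_shape = x.shape
        return flat.max(-1)

    def backward(self, dout):
        n, c, h2, w2 = dout.shape
        dflat = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dflat, self.arg[..., None], dout[..., None], axis=-1)
        dxr = dflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(self.in_shape)


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.in_shape)


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self.x.T @ dout
        self.db = dout.sum(0)
        return dout @ self.W.T

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """conv8-pool / conv16-pool / conv32-pool / dense64 / dense(n_classes)."""

    def __init__(self, input_size: int = 32, n_classes: int = 2,
                 channels: tuple[int, int, int] = (8, 16, 32),
                 hidden: int = 64, seed: int = 0):
        if input_size % 8 != 0:
            raise ValueError("input_size must be divisible by 8")
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        feat = (input_size // 8) ** 2 * c3
        self.input_size = input_size
        self.n_classes = n_classes
        self.layers = [
            _Conv(1, c1, rng), _ReLU(), _MaxPool2(),
            _Conv(c1, c2, rng), _ReLU(), _MaxPool2(),
            _Conv(c2, c3, rng), _ReLU(), _MaxPool2(),
            _Flatten(), _Dense(feat, hidden, rng), _ReLU(),
            _Dense(hidden, n_classes, rng),
        ]
        self._adam_m = None
        self._adam_v = None
        self._adam_t = 0

    # -- inference ---------------------------------------------------------

    def logits(self, x: np.ndarray) -> np.ndarray:
        out = x[:, None, :, :].astype(float)
        for layer in self.layers:
            out = layer.forward(out)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.logits(x))

    # -- training ----------------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> float:
        probs = _softmax(self.logits(x))
        n = len(y)
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
        dout = probs.copy()
        dout[np.arange(n), y] -= 1.0
        dout /= n
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return loss

    def adam_step(self, lr: float = 1e-3, beta1: float = 0.9,
                  beta2: float = 0.999, eps: float = 1e-8) -> None:
        params = [p for l in self.layers for p in l.params]
        grads = [g for l in self.layers for g in l.grads]
        if self._adam_m is None:
            self._adam_m = [np.zeros_like(p) for p in params]
            self._adam_v = [np.zeros_like(p) for p in params]
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- serialization -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                arrays[f"layer{i}_p{j}"] = p
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p[...] = arrays[f"layer{i}_p{j}"]
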
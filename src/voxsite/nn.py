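"""Minimal 3D convolutional network engine in numpy.

Implements exactly the layer set the detector needs — 3x3x3 'same'
convolutions, per-channel batch normalization, ReLU, 2x stride-2 max
pooling, sigmoid — with hand-written backprop and an Adam optimizer.
Tensors are channels-last: (batch, D, H, W, C), float32.

Convolutions use im2col per batch element (keeps peak memory bounded);
the input gradient is computed as a full correlation with the spatially
flipped, channel-transposed kernel.
"""

from __future__ import annotations

import numpy as np


class Conv3D:
    """3D convolution, kernel k x k x k, stride 1, 'same' zero padding.

    Computed as a shift-and-add sum over the k^3 kernel offsets: each offset
    contributes a (voxels x C_in) @ (C_in x C_out) product.  This keeps peak
    memory at one padded copy of the activations and avoids materializing
    im2col patch matrices.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 bias_init: float = 0.0):
        self.k, self.c_in, self.c_out = k, c_in, c_out
        fan_in = k ** 3 * c_in
        # He initialization (ReLU nonlinearity follows every layer but the last)
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(k, k, k, c_in, c_out)).astype(np.float32)
        self.b = np.full(c_out, bias_init, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None
        self._shape = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        return np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, d, h, w, _ = x.shape
        xp = self._pad(x)
        out = np.zeros((b * d * h * w, self.c_out), dtype=np.result_type(x, self.w))
        for a in range(self.k):
            for bb in range(self.k):
                for c in range(self.k):
                    sl = xp[:, a:a + d, bb:bb + h, c:c + w, :]
                    out += sl.reshape(-1, self.c_in) @ self.w[a, bb, c]
        out += self.b
        self._xp = xp if train else None
        self._shape = x.shape
        return out.reshape(b, d, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, d, h, w, _ = self._shape
        k, p = self.k, self.k // 2
        dyf = np.ascontiguousarray(dy).reshape(-1, self.c_out)
        self.db[...] = dyf.sum(axis=0)
        dxp = np.zeros_like(self._xp)
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    sl = self._xp[:, a:a + d, bb:bb + h, c:c + w, :]
                    self.dw[a, bb, c] = sl.reshape(-1, self.c_in).T @ dyf
                    dxp[:, a:a + d, bb:bb + h, c:c + w, :] += (
                        dyf @ self.w[a, bb, c].T).reshape(b, d, h, w, self.c_in)
        self._xp = None
        return dxp[:, p:p + d, p:p + h, p:p + w, :]

    def l2(self) -> float:
        return float(np.sum(self.w.astype(np.float64) ** 2))

    def add_l2_grad(self, gamma: float) -> None:
        self.dw += (2.0 * gamma) * self.w


class BatchNorm:
    """Per-channel batch normalization over batch and spatial dims."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros(c, dtype=np.float32)
        self.dbeta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 1, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        m = dy.size / dy.shape[-1]
        axes = (0, 1, 2, 3)
        self.dgamma[...] = np.sum(dy * xhat, axis=axes)
        self.dbeta[...] = np.sum(dy, axis=axes)
        dxhat = dy * self.gamma
        sum_dxhat = dxhat.sum(axis=axes)
        sum_dxhat_xhat = np.sum(dxhat * xhat, axis=axes)
        return (inv / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class ReLU:
    def params(self):
        return []

    def forward(self, x, train=True):
        self._mask = x > 0 if train else None
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool2:
    """2x2x2 max pooling, stride 2."""

    def params(self):
        return []

    def forward(self, x, train=True):
        b, d, h, w, c = x.shape
        xr = x.reshape(b, d // 2, 2, h // 2, 2, w // 2, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4, 6, 7).reshape(
            b, d // 2, h // 2, w // 2, 8, c)
        idx = xr.argmax(axis=4)
        out = np.take_along_axis(xr, idx[:, :, :, :, None, :], axis=4)[
            :, :, :, :, 0, :]
        if train:
            self._idx, self._shape = idx, x.shape
        return np.ascontiguousarray(out)

    def backward(self, dy):
        b, d, h, w, c = self._shape
        dxr = np.zeros((b, d // 2, h // 2, w // 2, 8, c), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[:, :, :, :, None, :],
                          dy[:, :, :, :, None, :], axis=4)
        dxr = dxr.reshape(b, d // 2, h // 2, w // 2, 2, 2, 2, c)
        return np.ascontiguousarray(
            dxr.transpose(0, 1, 4, 2, 5, 3, 6, 7)).reshape(b, d, h, w, c)


class Sigmoid:
    """Logistic activation clipped to the open interval (0, 1).

    The clip keeps outputs strictly inside (0, 1) where float32 would
    saturate, so decoded scores and coordinates always satisfy their range
    contract and the gradient never vanishes exactly.
    """

    EPS = 1e-6

    def params(self):
        return []

    def forward(self, x, train=True):
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -50.0, 50.0)))
        out = np.clip(out, self.EPS, 1.0 - self.EPS)
        self._out = out if train else None
        return out

    def backward(self, dy):
        return dy * self._out * (1.0 - self._out)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train: bool = True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def conv_layers(self):
        return [l for l in self.layers if isinstance(l, Conv3D)]


class Adam:
    """Adam with the standard defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
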
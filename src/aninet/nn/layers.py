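"""Minimal CNN layers with explicit forward/backward passes.

Tensors are NCHW float32.  Each layer owns :class:`Param` objects whose
``grad`` buffers are accumulated by ``backward`` and consumed by the
optimizer.  The layer set is exactly what the ancestry classifier needs:
same-padded (optionally dilated) convolution, batch normalization, ReLU,
2 x 2 max pooling, dense layers and the squeeze-and-excitation gate.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded k x k convolution with dilation (k in {1, 3})."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        if ksize not in (1, 3):
            raise ValueError("ksize must be 1 or 3")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        self.in_ch, self.out_ch, self.k, self.d = in_ch, out_ch, ksize, dilation
        self.pad = dilation * (ksize - 1) // 2
        rng = rng or np.random.default_rng()
        fan_in = in_ch * ksize * ksize
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, ksize, ksize))
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(out_ch), f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _taps(self):
        return [(ki, kj) for ki in range(self.k) for kj in range(self.k)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        N, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        if self.k == 1:
            y = np.tensordot(self.W.value[:, :, 0, 0], x, axes=([1], [1]))  # (O,N,H,W)
            y = np.ascontiguousarray(np.moveaxis(y, 0, 1)) + self.b.value[None, :, None, None]
            self._cache = (x, None)
            return y
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        L = H * W
        # accumulate one batched matmul per kernel tap; avoids an im2col buffer
        yf = np.zeros((N, self.out_ch, L), dtype=DTYPE)
        for ki, kj in self._taps():
            patch = xp[:, :, ki * self.d:ki * self.d + H, kj * self.d:kj * self.d + W]
            yf += self.W.value[:, :, ki, kj] @ patch.reshape(N, C, L)
        y = yf.reshape(N, self.out_ch, H, W) + self.b.value[None, :, None, None]
        self._cache = (x.shape, xp)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        if self.k == 1:
            x, _ = self._cache
            N, C, H, W = x.shape
            self.b.grad += dy.sum(axis=(0, 2, 3))
            dW = np.tensordot(dy, x, axes=([0, 2, 3], [0, 2, 3]))  # (O, C)
            self.W.grad += dW[:, :, None, None]
            dx = np.tensordot(self.W.value[:, :, 0, 0].T, dy, axes=([1], [1]))
            return np.ascontiguousarray(np.moveaxis(dx, 0, 1))
        (N, C, H, W), xp = self._cache
        L = H * W
        dyf = np.ascontiguousarray(dy.reshape(N, self.out_ch, L))
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for ki, kj in self._taps():
            sl = (slice(None), slice(None),
                  slice(ki * self.d, ki * self.d + H),
                  slice(kj * self.d, kj * self.d + W))
            patch = xp[sl].reshape(N, C, L)
            # dW tap: sum_n dy[n] @ patch[n]^T
            self.W.grad[:, :, ki, kj] += np.matmul(
                dyf, patch.transpose(0, 2, 1)).sum(axis=0)
            dpatch = self.W.value[:, :, ki, kj].T @ dyf  # (N, C, L)
            dxp[sl] += dpatch.reshape(N, C, H, W)
        return dxp[:, :, self.pad:self.pad + H, self.pad:self.pad + W]


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.gamma = Param(np.ones(ch), f"{name}.gamma")
        self.beta = Param(np.zeros(ch), f"{name}.beta")
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self._cache = None
        self._acc = None  # (sum, sumsq, count) during recalibration

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def begin_accumulation(self) -> None:
        self._acc = [np.zeros(self.ch, dtype=np.float64),
                     np.zeros(self.ch, dtype=np.float64), 0]

    def end_accumulation(self) -> None:
        s, ss, n = self._acc
        if n:
            mean = s / n
            self.running_mean = mean.astype(DTYPE)
            self.running_var = np.maximum(ss / n - mean**2, 0.0).astype(DTYPE)
        self._acc = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self._acc is not None:
                self._acc[0] += x.sum(axis=(0, 2, 3), dtype=np.float64)
                self._acc[1] += (x.astype(np.float64) ** 2).sum(axis=(0, 2, 3))
                self._acc[2] += x.shape[0] * x.shape[2] * x.shape[3]
            else:
                self.running_mean = (
                    (1 - self.momentum) * self.running_mean + self.momentum * mean
                )
                self.running_var = (
                    (1 - self.momentum) * self.running_var + self.momentum * var
                )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv_std[None, :, None, None]
        mean_dy = dy.mean(axis=(0, 2, 3), keepdims=True)
        mean_dy_xhat = (dy * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        return g * (dy - mean_dy - xhat * mean_dy_xhat)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d(Layer):
    """2 x 2 max pooling with stride 2 (even spatial sizes assumed)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("MaxPool2d requires even spatial dimensions")
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(N, C, H // 2, W // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._in_shape = (N, C, H, W)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._in_shape
        flat = np.zeros((N, C, H // 2, W // 2, 4), dtype=DTYPE)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(flat).reshape(N, C, H, W)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None,
                 name: str = "dense"):
        rng = rng or np.random.default_rng()
        w = rng.normal(0.0, np.sqrt(2.0 / in_f), size=(in_f, out_f))
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(out_f), f"{name}.b")
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SEBlock(Layer):
    """Squeeze-and-excitation channel gate.

    Global-average squeeze, then a two-layer bottleneck (C -> C/r ReLU ->
    C sigmoid) whose output rescales each channel.  ``identity_gate``
    short-circuits the gate to the constant 1, which reduces the block to
    the identity map — used to verify that SE adds gating and nothing else.
    """

    def __init__(self, ch: int, reduction: int = 4, identity_gate: bool = False,
                 rng: np.random.Generator | None = None, name: str = "se"):
        self.ch = ch
        self.reduced = max(1, ch // reduction)
        self.identity_gate = identity_gate
        rng = rng or np.random.default_rng()
        self.fc1 = Dense(ch, self.reduced, rng=rng, name=f"{name}.fc1")
        self.fc2 = Dense(self.reduced, ch, rng=rng, name=f"{name}.fc2")
        self.last_gates: np.ndarray | None = None
        self._cache = None

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.identity_gate:
            self.last_gates = np.ones((x.shape[0], self.ch), dtype=DTYPE)
            return x
        g = x.mean(axis=(2, 3))  # squeeze (N, C)
        h_pre = self.fc1.forward(g, train)
        h = np.maximum(h_pre, 0.0)
        # fc2 caches its input; feed the post-ReLU activation
        self.fc2._x = h
        z = h @ self.fc2.W.value + self.fc2.b.value
        s = sigmoid(z)
        self.last_gates = s
        self._cache = (x, h_pre, s)
        return x * s[:, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.identity_gate:
            return dy
        x, h_pre, s = self._cache
        N, C, H, W = x.shape
        ds = (dy * x).sum(axis=(2, 3))
        dx = dy * s[:, :, None, None]
        dz = ds * s * (1.0 - s)
        dh = self.fc2.backward(dz)
        dh_pre = dh * (h_pre > 0)
        dg = self.fc1.backward(dh_pre)
        dx += dg[:, :, None, None] / (H * W)
        return dx
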
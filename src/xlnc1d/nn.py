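"""Minimal feed-forward network core: 1D convolution, max-pooling, dropout
and dense layers with explicit backpropagation, in float32 numpy.

This exists so the classifier and its attribution pipeline share one exact
gradient machinery: the same backward pass that trains the model also
supplies the input gradients the attribution estimator integrates. The
layer set is intentionally limited to what the transcript classifier needs.

Conventions: activations have shape (N, L, C) for convolutional layers and
(N, F) after flattening; the network outputs logits, and the softmax is
applied by the callers (training loss, probability prediction).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base layer: forward caches what backward needs; params/grads align."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1D convolution, stride 1; 'same' (zero) or 'valid' padding.

    Weights are He-initialized: std = sqrt(2 / fan_in) with fan_in = k * c_in.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel_size: int,
        rng: np.random.Generator,
        padding: str = "same",
        stride: int = 1,
    ):
        if kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.k = kernel_size
        self.c_in = c_in
        self.c_out = c_out
        self.padding = padding
        self.stride = stride
        fan_in = kernel_size * c_in
        self.W = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _dense_length(self, L: int) -> int:
        """Output length before striding (stride-1 sliding windows)."""
        return L if self.padding == "same" else L - self.k + 1

    def out_length(self, L: int) -> int:
        base = self._dense_length(L)
        return -(-base // self.stride)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, L, C = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        if self._dense_length(L) < 1:
            raise ValueError(f"input length {L} too short for kernel {self.k}")
        self._in_shape = x.shape
        pad = self.k // 2 if self.padding == "same" else 0
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0))) if pad else x
        Ld = self._dense_length(L)
        # (N, Ld, C, k) -> (N, Ld, k, C) -> (N*Ld, k*C)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(N * Ld, self.k * C)
        self._cols = cols
        y = (cols @ self.W + self.b).reshape(N, Ld, self.c_out)
        return y[:, :: self.stride, :] if self.stride > 1 else y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, L, C = self._in_shape
        Ld = self._dense_length(L)
        if self.stride > 1:
            full = np.zeros((N, Ld, self.c_out), dtype=DTYPE)
            full[:, :: self.stride, :] = dy
            dy = full
        dy_flat = dy.reshape(N * Ld, self.c_out)
        self.dW[...] = self._cols.T @ dy_flat
        self.db[...] = dy_flat.sum(axis=0)
        # input gradient as a transposed convolution: correlate dy (padded by
        # k-1) with the kernel flipped along k and swapped in channels, as one
        # im2col matmul instead of a k-step scatter loop
        w_t = (
            self.W.reshape(self.k, self.c_in, self.c_out)[::-1]
            .transpose(0, 2, 1)
            .reshape(self.k * self.c_out, self.c_in)
        )
        dy_pad = np.pad(dy, ((0, 0), (self.k - 1, self.k - 1), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(dy_pad, self.k, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            N * (Ld + self.k - 1), self.k * self.c_out
        )
        dxp = (cols @ w_t).reshape(N, Ld + self.k - 1, self.c_in)
        pad = self.k // 2 if self.padding == "same" else 0
        return dxp[:, pad : pad + L, :]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (remainder dropped)."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, train=False):
        N, L, C = x.shape
        Lp = L // self.pool
        if Lp < 1:
            raise ValueError(f"length {L} too short to pool by {self.pool}")
        self._in_shape = x.shape
        xr = x[:, : Lp * self.pool, :].reshape(N, Lp, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dy):
        N, L, C = self._in_shape
        Lp = L // self.pool
        dx = np.zeros((N, Lp, self.pool, C), dtype=DTYPE)
        n_i, l_i, c_i = np.ogrid[:N, :Lp, :C]
        dx[n_i, l_i, self._argmax, c_i] = dy
        out = np.zeros((N, L, C), dtype=DTYPE)
        out[:, : Lp * self.pool, :] = dx.reshape(N, Lp * self.pool, C)
        return out


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A plain layer stack producing logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate to the input; parameter grads are left on the layers."""
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def input_gradient(self, x: np.ndarray, output_index: int = 1) -> np.ndarray:
        """d p[output_index] / d x for each sample, dropout inactive.

        For a two-class softmax, dp1/dz = p1*p0 * (-1, +1).
        """
        logits = self.forward(x, train=False)
        p = softmax(logits)
        coef = (p[:, 0] * p[:, 1]).astype(DTYPE)
        dlogits = np.zeros_like(logits)
        sign = np.ones(logits.shape[1], dtype=DTYPE) * -1.0
        sign[output_index] = 1.0
        dlogits[:] = coef[:, None] * sign[None, :]
        return self.backward(dlogits)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(weights)}")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w.astype(DTYPE)


class SGDMomentum:
    """Classical momentum SGD: v <- mu*v - lr*g; p <- p + v."""

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v


def cross_entropy(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    n = len(labels)
    return float(-np.log(probs[np.arange(n), labels] + eps).mean())
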
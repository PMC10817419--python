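"""Minimal numpy neural-network layers with explicit backpropagation.

Only what the five text-classification architectures need: a (trainable)
embedding lookup, 1-D same-padding convolutions with ReLU, batch
normalization, inverted dropout, global max/average pooling over the
sequence axis, a dense layer, and softmax cross-entropy.  Everything is
float64 and deterministic given the generator passed to the model.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray | None:  # pragma: no cover
        raise NotImplementedError


class Embedding(Layer):
    """Index lookup into a trainable table; the PAD row (index 0) stays zero."""

    def __init__(self, table: np.ndarray, pad_index: int = 0) -> None:
        self.W = Param(table.copy())
        self.pad_index = pad_index
        self.W.value[pad_index] = 0.0
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return self.W.value[x]

    def backward(self, dout: np.ndarray) -> None:
        np.add.at(self.W.grad, self._x, dout)
        self.W.grad[self.pad_index] = 0.0  # PAD row excluded from updates
        return None


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class BatchNorm(Layer):
    """Normalization over all but the last (feature) axis, with running stats."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        shape = x.shape
        flat = x.reshape(-1, shape[-1])
        if train:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mean) * inv_std
        self._cache = (xhat, inv_std, shape)
        out = self.gamma.value * xhat + self.beta.value
        return out.reshape(shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        dflat = dout.reshape(-1, shape[-1])
        n = dflat.shape[0]
        self.gamma.grad += (dflat * xhat).sum(axis=0)
        self.beta.grad += dflat.sum(axis=0)
        dxhat = dflat * self.gamma.value
        dx = (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )
        return dx.reshape(shape)


class Conv1D(Layer):
    """Same-padding 1-D convolution over (batch, length, channels) with ReLU."""

    def __init__(
        self, in_channels: int, filters: int, width: int, rng: np.random.Generator
    ) -> None:
        if width < 1 or filters < 1:
            raise ValueError("kernel width and filter count must be >= 1")
        fan_in = width * in_channels
        bound = np.sqrt(6.0 / (fan_in + filters))  # Glorot uniform
        self.W = Param(rng.uniform(-bound, bound, size=(fan_in, filters)))
        self.b = Param(np.zeros(filters))
        self.width = width
        self.in_channels = in_channels
        self.filters = filters
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        B, L, C = x.shape
        left = (self.width - 1) // 2
        right = self.width - 1 - left
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.width, axis=1)
        # win: (B, L, C, width) -> (B, L, width*C) matching W's (width*C) layout
        cols = win.transpose(0, 1, 3, 2).reshape(B, L, self.width * C)
        return cols, left, L

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, left, L = self._im2col(x)
        z = cols @ self.W.value + self.b.value
        out = np.maximum(z, 0.0)
        self._cache = (cols, z > 0, left, L, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, relu_mask, left, L, x_shape = self._cache
        dz = dout * relu_mask
        B = x_shape[0]
        dz_flat = dz.reshape(-1, self.filters)
        self.W.grad += cols.reshape(-1, self.width * self.in_channels).T @ dz_flat
        self.b.grad += dz_flat.sum(axis=0)
        dcols = (dz @ self.W.value.T).reshape(B, L, self.width, self.in_channels)
        right = self.width - 1 - left
        dxp = np.zeros((B, L + left + right, self.in_channels))
        for k in range(self.width):
            dxp[:, k : k + L, :] += dcols[:, :, k, :]
        return dxp[:, left : left + L, :]


class ParallelConv(Layer):
    """Several convolutions over the same input, concatenated on the filter axis."""

    def __init__(self, convs: list[Conv1D]) -> None:
        if not convs:
            raise ValueError("ParallelConv needs at least one convolution")
        self.convs = convs
        self.filters = sum(c.filters for c in convs)

    def params(self) -> list[Param]:
        return [p for c in self.convs for p in c.params()]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return np.concatenate([c.forward(x, train) for c in self.convs], axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = None
        offset = 0
        for c in self.convs:
            d = c.backward(dout[..., offset : offset + c.filters])
            offset += c.filters
            dx = d if dx is None else dx + d
        return dx


class GlobalMaxPool(Layer):
    """Max over the sequence axis: (B, L, F) -> (B, F)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._argmax = x.argmax(axis=1)
        self._shape = x.shape
        return x.max(axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, F = self._shape
        dx = np.zeros(self._shape)
        b_idx = np.arange(B)[:, None]
        f_idx = np.arange(F)[None, :]
        dx[b_idx, self._argmax, f_idx] = dout
        return dx


class GlobalAvgPool(Layer):
    """Mean over the sequence axis: (B, L, F) -> (B, F)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, F = self._shape
        return np.repeat(dout[:, None, :], L, axis=1) / L


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        bound = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = Param(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.b = Param(np.zeros(out_dim))
        self._x = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.log(probs[np.arange(n), labels] + 1e-12).mean())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam optimizer over a list of Params."""

    def __init__(
        self,
        params: list[Param],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
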
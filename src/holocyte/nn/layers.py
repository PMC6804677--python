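"""Minimal spatio-temporal CNN layers with explicit forward/backward passes.

Tensors are numpy float32 arrays of shape (n, c, t, h, w).  Every layer
caches what its backward pass needs; ``backward`` consumes the upstream
gradient and returns the input gradient while accumulating parameter
gradients in ``Param.grad``.  Convolutions here are tiny (1x3x3, 3x1x1,
1x7x7, 9x1x1), so both passes loop over kernel offsets and batch the rest
through einsum.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Conv3d", "BatchNorm3d", "ReLU", "MaxPool3d",
    "Dropout", "Flatten", "Linear", "softmax", "SoftmaxCrossEntropy",
]


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    train_mode: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def _triple(v):
    return (v, v, v) if np.isscalar(v) else tuple(v)


class Conv3d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel,
                 stride=1, padding=0, bias: bool = True):
        self.ci, self.co = in_channels, out_channels
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        kt, kh, kw = self.kernel
        self.weight = Param(np.zeros((out_channels, in_channels, kt, kh, kw)))
        self.bias = Param(np.zeros(out_channels)) if bias else None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def out_shape(self, shape):
        t, h, w = shape
        (kt, kh, kw), (st, sh, sw), (pt, ph, pw) = self.kernel, self.stride, self.padding
        out = ((t + 2 * pt - kt) // st + 1, (h + 2 * ph - kh) // sh + 1,
               (w + 2 * pw - kw) // sw + 1)
        if min(out) < 1:
            raise ValueError(f"conv kernel {self.kernel} does not fit input {shape}")
        return out

    def forward(self, x):
        (kt, kh, kw), (st, sh, sw), (pt, ph, pw) = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        To, Ho, Wo = self.out_shape(x.shape[2:])
        n = x.shape[0]
        y = np.zeros((n, self.co, To, Ho, Wo), dtype=np.float32)
        W = self.weight.value
        for a in range(kt):
            for b in range(kh):
                for c in range(kw):
                    xs = xp[:, :, a : a + st * To : st, b : b + sh * Ho : sh,
                            c : c + sw * Wo : sw]
                    y += np.einsum("oc,ncthw->nothw", W[:, :, a, b, c], xs,
                                   optimize=True)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None, None]
        self._cache = (xp, x.shape)
        return y

    def backward(self, dy):
        xp, x_shape = self._cache
        (kt, kh, kw), (st, sh, sw), (pt, ph, pw) = self.kernel, self.stride, self.padding
        To, Ho, Wo = dy.shape[2:]
        W = self.weight.value
        dxp = np.zeros_like(xp)
        for a in range(kt):
            for b in range(kh):
                for c in range(kw):
                    sl = (slice(None), slice(None),
                          slice(a, a + st * To, st),
                          slice(b, b + sh * Ho, sh),
                          slice(c, c + sw * Wo, sw))
                    self.weight.grad[:, :, a, b, c] += np.einsum(
                        "nothw,ncthw->oc", dy, xp[sl], optimize=True)
                    dxp[sl] += np.einsum("oc,nothw->ncthw", W[:, :, a, b, c],
                                         dy, optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3, 4))
        t, h, w = x_shape[2:]
        return dxp[:, :, pt : pt + t, ph : ph + h, pw : pw + w]


class BatchNorm3d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        axes = (0, 2, 3, 4)
        if self.train_mode:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        self._cache = (xhat, inv)
        return (self.gamma.value[None, :, None, None, None] * xhat
                + self.beta.value[None, :, None, None, None])

    def backward(self, dy):
        xhat, inv = self._cache
        axes = (0, 2, 3, 4)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value[None, :, None, None, None]
        if not self.train_mode:
            return dy * g * inv[None, :, None, None, None]
        dxhat = dy * g
        term = (dxhat - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        return term * inv[None, :, None, None, None]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class MaxPool3d(Layer):
    """2x2x2 max pooling with stride 2 (trailing odd samples dropped)."""

    def forward(self, x):
        n, c, t, h, w = x.shape
        To, Ho, Wo = t // 2, h // 2, w // 2
        if min(To, Ho, Wo) < 1:
            raise ValueError(f"input {x.shape[2:]} is not poolable")
        xw = x[:, :, : 2 * To, : 2 * Ho, : 2 * Wo].reshape(
            n, c, To, 2, Ho, 2, Wo, 2)
        xw = xw.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, To, Ho, Wo, 8)
        idx = xw.argmax(axis=-1)
        y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, x_shape = self._cache
        n, c, t, h, w = x_shape
        To, Ho, Wo = t // 2, h // 2, w // 2
        flat = np.zeros((n, c, To, Ho, Wo, 8), dtype=np.float32)
        np.put_along_axis(flat, idx[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(n, c, To, Ho, Wo, 2, 2, 2).transpose(
            0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, 2 * To, 2 * Ho, 2 * Wo)
        dx = np.zeros(x_shape, dtype=np.float32)
        dx[:, :, : 2 * To, : 2 * Ho, : 2 * Wo] = flat
        return dx


class Dropout(Layer):
    def __init__(self, p: float = 0.5):
        self.p = p
        self.rng = np.random.default_rng(0)  # reseeded by the trainer

    def forward(self, x):
        if not self.train_mode or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int):
        self.weight = Param(np.zeros((out_features, in_features)))
        self.bias = Param(np.zeros(out_features))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.value


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SoftmaxCrossEntropy:
    """Fused softmax + cross-entropy loss (mean over the batch)."""

    def forward(self, logits: np.ndarray, labels: np.ndarray):
        p = softmax(logits)
        n = logits.shape[0]
        loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
        self._cache = (p, labels)
        return loss, p

    def backward(self):
        p, labels = self._cache
        n = p.shape[0]
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        return d / n
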
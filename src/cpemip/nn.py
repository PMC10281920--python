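"""Minimal neural-network layers on numpy.

Just enough machinery for this package's models: strided 3x3 convolutions,
dense layers, ReLU, batch normalisation, alpha-dropout, global average
pooling, a softmax cross-entropy loss and Adam.  Layers expose
``forward(x, train)`` / ``backward(grad)`` and dictionaries of parameters
and gradients; ``Sequential`` chains them.  All randomness flows through
numpy Generators supplied by the caller, so training runs are reproducible
bit-for-bit.
"""

from __future__ import annotations

import numpy as np

# SELU constants used by alpha-dropout
_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805
_ALPHA_PRIME = -_SELU_SCALE * _SELU_ALPHA


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable = True

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) convolution with stride, 'same'-style zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self.k, self.stride, self.c_in, self.c_out = k, stride, c_in, c_out
        self.pad = k // 2
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k)).astype(np.float32)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        windows = windows[:, :, ::s, ::s, :, :]  # (n, c, ho, wo, k, k)
        ho, wo = windows.shape[2], windows.shape[3]
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        w_mat = self.params["W"].reshape(self.c_out, c * k * k)
        out = cols @ w_mat.T + self.params["b"]
        self._cache = (x.shape, cols, ho, wo)
        return out.transpose(0, 2, 1).reshape(n, self.c_out, ho, wo).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        (n, c, h, w), cols, ho, wo = self._cache
        k, s, p = self.k, self.stride, self.pad
        g = grad.reshape(n, self.c_out, ho * wo).transpose(0, 2, 1)  # (n, L, c_out)
        w_mat = self.params["W"].reshape(self.c_out, c * k * k)
        self.grads["W"] = np.einsum("nlo,nlc->oc", g, cols).reshape(self.params["W"].shape)
        self.grads["b"] = g.sum(axis=(0, 1))
        dcols = (g @ w_mat).reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[:, :, :, :, ki, kj]
        return dxp[:, :, p : p + h, p : p + w]


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out)).astype(np.float32)
        self.params["b"] = np.zeros(d_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self.trainable = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class GlobalAvgPool(Layer):
    """(n, c, h, w) -> (n, c)."""

    def __init__(self) -> None:
        super().__init__()
        self.trainable = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class GlobalMaxPool(Layer):
    """(n, c, h, w) -> (n, c): strongest response of each filter anywhere in
    the image, decoupling the feature vector from how much of the image is
    occupied."""

    def __init__(self) -> None:
        super().__init__()
        self.trainable = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        flat = x.reshape(x.shape[0], x.shape[1], -1)
        self._idx = flat.argmax(axis=2)
        return flat.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = np.zeros(self._shape, dtype=np.float32).reshape(
            self._shape[0], self._shape[1], -1
        )
        ii, jj = np.meshgrid(
            np.arange(self._shape[0]), np.arange(self._shape[1]), indexing="ij"
        )
        out[ii, jj, self._idx] = grad
        return out.reshape(self._shape)


class BatchNorm1d(Layer):
    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(dim, dtype=np.float32)
        self.params["beta"] = np.zeros(dim, dtype=np.float32)
        self.running_mean = np.zeros(dim, dtype=np.float32)
        self.running_var = np.ones(dim, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0]
        xhat, std = self._xhat, self._std
        self.grads["gamma"] = (grad * xhat).sum(axis=0)
        self.grads["beta"] = grad.sum(axis=0)
        dxhat = grad * self.params["gamma"]
        return (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std


class AlphaDropout(Layer):
    """Dropout that sets dropped units to the SELU saturation value and
    renormalises so the layer output keeps zero-mean/unit-variance statistics."""

    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.trainable = False
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        q = 1.0 - p
        if p > 0:
            self._a = (q + _ALPHA_PRIME**2 * q * p) ** -0.5
            self._b = -self._a * p * _ALPHA_PRIME
        else:
            self._a, self._b = 1.0, 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = self.rng.uniform(size=x.shape) >= self.p
        out = np.where(self._mask, x, _ALPHA_PRIME)
        return self._a * out + self._b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask * self._a


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers if layer.trainable for name in layer.params]

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                out[f"{i}.{name}"] = value.copy()
            if isinstance(layer, BatchNorm1d):
                out[f"{i}.running_mean"] = layer.running_mean.copy()
                out[f"{i}.running_var"] = layer.running_var.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.array(weights[f"{i}.{name}"])
            if isinstance(layer, BatchNorm1d):
                layer.running_mean = np.array(weights[f"{i}.running_mean"])
                layer.running_var = np.array(weights[f"{i}.running_var"])


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SoftmaxCrossEntropy:
    def forward(self, logits: np.ndarray, y: np.ndarray) -> float:
        self._probs = softmax(logits)
        self._y = y
        n = logits.shape[0]
        return float(-np.log(self._probs[np.arange(n), y] + 1e-12).mean())

    def backward(self) -> np.ndarray:
        n = self._probs.shape[0]
        grad = self._probs.copy()
        grad[np.arange(n), self._y] -= 1.0
        return grad / n


class Adam:
    """Adam over an explicit list of (layer, parameter-name) pairs."""

    def __init__(self, params: list[tuple[Layer, str]], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for idx, (layer, name) in enumerate(self.params):
            grad = layer.grads.get(name)
            if grad is None:
                continue
            if idx not in self.m:
                self.m[idx] = np.zeros_like(layer.params[name])
                self.v[idx] = np.zeros_like(layer.params[name])
            self.m[idx] = self.b1 * self.m[idx] + (1 - self.b1) * grad
            self.v[idx] = self.b2 * self.v[idx] + (1 - self.b2) * grad**2
            mhat = self.m[idx] / (1 - self.b1**self.t)
            vhat = self.v[idx] / (1 - self.b2**self.t)
            layer.params[name] = (layer.params[name] - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
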
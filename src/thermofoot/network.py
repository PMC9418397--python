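"""Minimal CPU neural-network engine: conv/pool/dense layers, Adam, weighted CE.

Implements exactly what the grading CNN needs - same-padded 3x3 convolutions
via im2col matrix multiplication, 2x2 max pooling, inverted dropout, dense
layers, softmax cross-entropy with optional per-class weights, and Adam.
Everything is float32 and seeded; forward in inference mode is deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dropout",
    "Dense",
    "Network",
    "Adam",
    "softmax",
    "weighted_cross_entropy",
]


class Layer:
    """Base layer: stateless unless it declares params/grads."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) same-padded convolution, stride 1, im2col implementation."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.W = w.astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x, train, rng):
        n, c, h, w = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # windows: (n, c, h, w, k, k) view over the padded array
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=self.W.dtype)
        out = cols @ self.W.T + self.b
        self._cols = cols if train else None
        self._in_shape = (n, c, h, w)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c, h, w = self._in_shape
        k, p = self.k, self.k // 2
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        g = np.ascontiguousarray(g, dtype=self.W.dtype)
        self.grads[0][...] = g.T @ self._cols
        self.grads[1][...] = g.sum(axis=0)
        dcols = (g @ self.W).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=self.W.dtype)
        # scatter-add each kernel offset back into the padded gradient
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w]


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, train, rng):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = (n, c, h, w)
        xc = x[:, :, : h2 * 2, : w2 * 2]
        win = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h2, w2, 4
        )
        self._idx = win.argmax(axis=-1)
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, c, h2, w2, 4), dtype=grad.dtype)
        np.put_along_axis(dwin, self._idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        dx[:, :, : h2 * 2, : w2 * 2] = (
            dwin.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.W = w.astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    probs: np.ndarray, y: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean weighted CE loss and its gradient w.r.t. the logits.

    With all weights equal to one this is exactly the unweighted loss.
    """
    n, k = probs.shape
    w = np.ones(n) if class_weights is None else np.asarray(class_weights)[y]
    eps = 1e-12
    loss = float((w * -np.log(probs[np.arange(n), y] + eps)).sum() / n)
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / n)[:, None]
    return loss, grad


class Network:
    """A feed-forward stack ending in logits; softmax applied on request."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def dtype(self) -> np.dtype:
        for p in self.params:
            return p.dtype
        return np.dtype(np.float32)

    def cast(self, dtype) -> "Network":
        """In-place parameter dtype change (float64 for gradient verification)."""
        for layer in self.layers:
            for name in ("W", "b"):
                if hasattr(layer, name):
                    setattr(layer, name, getattr(layer, name).astype(dtype))
            if layer.params:
                layer.params = [getattr(layer, "W"), getattr(layer, "b")]
                layer.grads = [np.zeros_like(p) for p in layer.params]
        return self

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng(0)
        out = np.ascontiguousarray(x, dtype=self.dtype)
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != len(self.params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(self.params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


class SGD:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-2):
        self.params = params
        self.lr = lr

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g in zip(self.params, grads):
            p -= self.lr * g
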
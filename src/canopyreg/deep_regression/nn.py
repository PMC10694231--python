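"""Minimal numpy neural-network engine: layers, backprop, Adam.

Only what the desk-scale CNN backbones need: 2-D convolution (im2col),
ReLU, global average pooling, dense layers and a softmax output map, with
per-parameter trainability flags so training phases can freeze scopes.
Tensors are NCHW float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Layer", "Conv2d", "ReLU", "GlobalAvgPool", "Dense", "Softmax", "Sequential", "Adam"]


class Param:
    """A learnable tensor with its gradient and a trainability flag."""

    def __init__(self, value: np.ndarray, name: str):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.trainable = True

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    scope: str = ""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out_h = (h + 2 * pad - kh) // stride + 1
    out_w = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, out_h, out_w), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * out_h : stride, j : j + stride * out_w : stride]
    return cols.reshape(n, c * kh * kw, out_h * out_w), (out_h, out_w)


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    out_h = (h + 2 * pad - kh) // stride + 1
    out_w = (w + 2 * pad - kw) // stride + 1
    dcols = dcols.reshape(n, c, kh, kw, out_h, out_w)
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * out_h : stride, j : j + stride * out_w : stride] += dcols[:, :, i, j]
    return dx[:, :, pad : pad + h, pad : pad + w] if pad else dx


class Conv2d(Layer):
    def __init__(self, in_c: int, out_c: int, k: int = 3, stride: int = 1, pad: int = 1,
                 scope: str = "", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_c * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_c, in_c, k, k))
        self.w = Param(w, f"{scope}.w")
        self.b = Param(np.zeros(out_c), f"{scope}.b")
        self.k, self.stride, self.pad = k, stride, pad
        self.scope = scope
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        cols, (oh, ow) = _im2col(x, self.k, self.k, self.stride, self.pad)
        wmat = self.w.value.reshape(self.w.value.shape[0], -1)
        out = np.matmul(wmat, cols) + self.b.value[None, :, None]
        self._cache = (x.shape, cols)
        return out.reshape(x.shape[0], -1, oh, ow)

    def backward(self, dout):
        x_shape, cols = self._cache
        n, oc, oh, ow = dout.shape
        dflat = dout.reshape(n, oc, oh * ow)
        self.w.grad += np.matmul(dflat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(
            self.w.value.shape
        )
        self.b.grad += dflat.sum(axis=(0, 2))
        wmat = self.w.value.reshape(oc, -1)
        dcols = np.matmul(wmat.T, dflat)
        return _col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, scope: str = "", rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / in_f), (in_f, out_f)), f"{scope}.w")
        self.b = Param(np.zeros(out_f), f"{scope}.b")
        self.scope = scope

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class Softmax(Layer):
    """Row-wise softmax with the exact Jacobian-vector backward pass."""

    def forward(self, x, train=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._s = e / e.sum(axis=1, keepdims=True)
        return self._s

    def backward(self, dout):
        s = self._s
        return s * (dout - (dout * s).sum(axis=1, keepdims=True))


class Sequential:
    """A feed-forward stack with scope-based freezing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def scopes(self) -> list[str]:
        seen: dict[str, None] = {}
        for layer in self.layers:
            if layer.params():
                seen.setdefault(layer.scope, None)
        return list(seen)

    def set_trainable(self, scopes: set[str] | None) -> None:
        """Freeze every parameter outside ``scopes`` (None = train all)."""
        for layer in self.layers:
            flag = scopes is None or layer.scope in scopes
            for p in layer.params():
                p.trainable = flag

    def checksum(self, scope: str | None = None) -> float:
        total = 0.0
        for layer in self.layers:
            if scope is not None and layer.scope != scope:
                continue
            for p in layer.params():
                total += float(np.abs(p.value).sum())
        return total

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v


class Adam:
    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if not p.trainable:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
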
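"""A compact deterministic layer framework with explicit backpropagation.

Layers cache the activations of their latest forward pass and consume them
in ``backward``; a forward must therefore be paired with its backward
before the next forward through the same module.  Parameter gradients
accumulate across backward calls until ``zero_grad`` — that is what lets a
training step combine gradients from several loss streams (trait MSE,
domain-adversarial) into one optimizer update.

Everything is float64 numpy, seeded through an explicit Generator, so runs
are reproducible bit-for-bit on one thread.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Sequential",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Flatten",
    "GradientReversal",
    "Adam",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Module:
    """Base class: collects parameters from attributes recursively."""

    training: bool = True

    def params(self) -> list[Param]:
        out: list[Param] = []
        for value in self.__dict__.values():
            if isinstance(value, Param):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.params())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(state):
            raise ValueError("state/parameter count mismatch")
        for p, s in zip(own, state):
            if p.data.shape != s.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.data[...] = s


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        self.W = Param(he_normal(rng, (in_dim, out_dim), in_dim), "linear.W")
        self.b = Param(np.zeros(out_dim), "linear.b")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.W.data.shape[0]:
            raise ValueError(
                f"Linear expects (B, {self.W.data.shape[0]}), got {x.shape}"
            )
        self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.data.T


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = x.shape[2], x.shape[3]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    cols = np.empty((B, C, kh, kw, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * Ho : stride,
                                 j : j + stride * Wo : stride]
    return cols.reshape(B, C * kh * kw, Ho * Wo), (Ho, Wo)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    B, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    cols = cols.reshape(B, C, kh, kw, Ho, Wo)
    xp = np.zeros((B, C, Hp, Wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + stride * Ho : stride,
               j : j + stride * Wo : stride] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0, bias: bool = False) -> None:
        fan_in = cin * k * k
        self.W = Param(he_normal(rng, (cout, cin * k * k), fan_in), "conv.W")
        self.b = Param(np.zeros(cout), "conv.b") if bias else None
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.pad = stride, pad
        self._cols = None
        self._x_shape = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.cin:
            raise ValueError(f"Conv2d expects (B, {self.cin}, H, W), got {x.shape}")
        cols, (Ho, Wo) = _im2col(x, self.k, self.k, self.stride, self.pad)
        self._cols, self._x_shape = cols, x.shape
        out = np.matmul(self.W.data[None], cols)  # (B, cout, L) via batched BLAS
        if self.b is not None:
            out += self.b.data[None, :, None]
        return out.reshape(x.shape[0], self.cout, Ho, Wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B = grad.shape[0]
        g = grad.reshape(B, self.cout, -1)
        self.W.grad += np.tensordot(g, self._cols, axes=([0, 2], [0, 2]))
        if self.b is not None:
            self.b.grad += g.sum(axis=(0, 2))
        dcols = np.matmul(self.W.data.T[None], g)
        return _col2im(dcols, self._x_shape, self.k, self.k, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        if not self.training:
            return g * inv[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3))[None, :, None, None] / m
        gx_sum = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None] / m
        return inv[None, :, None, None] * (g - gsum - xhat * gx_sum)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Module):
    def __init__(self, k: int, stride: int, pad: int = 0) -> None:
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (Ho, Wo) = _im2col(x, self.k, self.k, self.stride, self.pad)
        B, C = x.shape[0], x.shape[1]
        win = cols.reshape(B, C, self.k * self.k, Ho * Wo)
        # padding contributes zeros; spectra-derived activations are >= 0
        # post-ReLU so zero padding never wins spuriously in practice
        self._argmax = win.argmax(axis=2)
        self._x_shape = x.shape
        out = np.take_along_axis(win, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]
        return out.reshape(B, C, Ho, Wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, Ho, Wo = grad.shape
        win = np.zeros((B, C, self.k * self.k, Ho * Wo), dtype=grad.dtype)
        np.put_along_axis(
            win, self._argmax[:, :, None, :], grad.reshape(B, C, 1, -1), axis=2
        )
        cols = win.reshape(B, C * self.k * self.k, Ho * Wo)
        return _col2im(cols, self._x_shape, self.k, self.k, self.stride, self.pad)


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (H * W)


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class GradientReversal(Module):
    """Identity in the forward pass; scales gradients by -lambda backward.

    The canonical adversarial-training primitive: a domain classifier
    downstream minimizes its loss while the encoder upstream receives the
    negated gradient, learning domain-confusing features.
    """

    def __init__(self, lambda_grl: float = 0.3) -> None:
        if lambda_grl < 0:
            raise ValueError("lambda_grl must be >= 0")
        self.lambda_grl = float(lambda_grl)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return -self.lambda_grl * grad


class Adam:
    """Adam with optional per-step learning-rate override."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
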
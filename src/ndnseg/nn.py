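"""Minimal 3-D convolutional network engine in numpy.

Layers operate on channel-last activations ``(B, X, Y, Z, C)`` and
implement both a forward pass and an analytic backward pass; gradients are
verified against finite differences in the test suite.  The engine covers
exactly what the segmentation network needs: dilated 3-D convolution,
batch normalization, ReLU/sigmoid, 2x2x2 max pooling, nearest-neighbor
upsampling, dense layers and global average pooling for channel attention,
plus the Adam optimizer with L2 weight decay.

Convolutions are evaluated as one matrix product per kernel tap (27 for a
3x3x3 kernel): for tap offset ``d`` the padded input shifted by ``r*d`` is
flattened to ``(B*N, C_in)`` and multiplied by that tap's ``(C_in, C_out)``
weight slice.  This keeps memory at one activation copy and hands all the
arithmetic to BLAS.
"""

from __future__ import annotations

import math

import numpy as np

DTYPE = np.float64


class Param:
    """A trainable array with its gradient accumulator.

    ``decay`` marks parameters subject to L2 regularization (convolution and
    dense weights; biases and normalization parameters are exempt).
    """

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: forward/backward pair over batched activations.

    ``__call__`` runs inference and accepts either a batched ``(B,X,Y,Z,C)``
    array or a single ``(X,Y,Z,C)`` grid (a batch axis is added and removed
    transparently), matching the tensor-function contract used by the
    network-specification layer.
    """

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return []

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 4:
            return self.forward(x[None], train=False)[0]
        return self.forward(x, train=False)

    @property
    def n_params(self) -> int:
        return count_parameters(self)


def count_parameters(module: Module) -> int:
    """Total number of trainable scalars in a module."""
    return sum(p.size for p in module.parameters())


def zero_gradients(module: Module) -> None:
    for p in module.parameters():
        p.grad[...] = 0.0


class Conv3d(Module):
    """Dilated 3-D convolution with symmetric zero padding (shape-preserving).

    Weight layout ``(K, K, K, C_in, C_out)``; He-normal initialization.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        if kernel % 2 != 1 or kernel < 1:
            raise ValueError(f"kernel must be odd and positive, got {kernel}")
        if dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        rng = np.random.default_rng(rng)
        fan_in = kernel**3 * c_in
        scale = math.sqrt(2.0 / fan_in)
        self.kernel = kernel
        self.dilation = dilation
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(
            rng.normal(0.0, scale, size=(kernel, kernel, kernel, c_in, c_out)),
            decay=True,
            name=f"{name}.weight",
        )
        self.bias = Param(np.zeros(c_out), decay=False, name=f"{name}.bias")
        self._cache: np.ndarray | None = None

    @property
    def pad(self) -> int:
        return self.dilation * (self.kernel - 1) // 2

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, X, Y, Z, _ = x.shape
        p, r, K = self.pad, self.dilation, self.kernel
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x
        out = np.zeros((b, X, Y, Z, self.c_out), dtype=DTYPE)
        flat = out.reshape(-1, self.c_out)
        for dx in range(K):
            for dy in range(K):
                for dz in range(K):
                    sl = xp[:, dx * r : dx * r + X, dy * r : dy * r + Y, dz * r : dz * r + Z, :]
                    flat += sl.reshape(-1, self.c_in) @ self.weight.value[dx, dy, dz]
        out += self.bias.value
        if train:
            self._cache = xp
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._cache
        if xp is None:
            raise RuntimeError("backward called without a training forward pass")
        b, X, Y, Z, _ = grad.shape
        p, r, K = self.pad, self.dilation, self.kernel
        gflat = grad.reshape(-1, self.c_out)
        self.bias.grad += gflat.sum(axis=0)
        gxp = np.zeros_like(xp)
        for dx in range(K):
            for dy in range(K):
                for dz in range(K):
                    sl = xp[:, dx * r : dx * r + X, dy * r : dy * r + Y, dz * r : dz * r + Z, :]
                    self.weight.grad[dx, dy, dz] += sl.reshape(-1, self.c_in).T @ gflat
                    gxp[:, dx * r : dx * r + X, dy * r : dy * r + Y, dz * r : dz * r + Z, :] += (
                        gflat @ self.weight.value[dx, dy, dz].T
                    ).reshape(grad.shape[:4] + (self.c_in,))
        self._cache = None
        if p:
            return gxp[:, p:-p, p:-p, p:-p, :]
        return gxp

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]


class BatchNorm(Module):
    """Per-channel batch normalization over batch and spatial axes.

    Running statistics (exponential moving average, momentum 0.9) are used
    at inference so predictions are deterministic.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9, name: str = "bn"):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels), decay=False, name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels), decay=False, name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._cache = (xhat, inv, axes, x.size // x.shape[-1])
            return self.gamma.value * xhat + self.beta.value
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma.value * (x - self.running_mean) * inv + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, axes, n = self._cache
        self._cache = None
        self.beta.grad += grad.sum(axis=axes)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        g = grad * self.gamma.value
        return inv * (g - g.mean(axis=axes) - xhat * (g * xhat).mean(axis=axes))

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return x * mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class Dense(Module):
    """Fully connected layer on ``(B, C)`` vectors (used by channel attention)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None, name: str = "dense"):
        rng = np.random.default_rng(rng)
        scale = math.sqrt(2.0 / c_in)
        self.weight = Param(rng.normal(0.0, scale, size=(c_in, c_out)), decay=True, name=f"{name}.weight")
        self.bias = Param(np.zeros(c_out), decay=False, name=f"{name}.bias")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]


class MaxPool2(Module):
    """2x2x2 max pooling; spatial axes must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, X, Y, Z, c = x.shape
        if X % 2 or Y % 2 or Z % 2:
            raise ValueError(f"max pooling needs even spatial axes, got {(X, Y, Z)}")
        win = x.reshape(b, X // 2, 2, Y // 2, 2, Z // 2, 2, c)
        win = win.transpose(0, 1, 3, 5, 2, 4, 6, 7).reshape(b, X // 2, Y // 2, Z // 2, 8, c)
        idx = win.argmax(axis=4)
        out = np.take_along_axis(win, idx[:, :, :, :, None, :], axis=4)[:, :, :, :, 0, :]
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, X, Y, Z, c = self._in_shape
        win = np.zeros((b, X // 2, Y // 2, Z // 2, 8, c), dtype=DTYPE)
        np.put_along_axis(win, self._idx[:, :, :, :, None, :], grad[:, :, :, :, None, :], axis=4)
        win = win.reshape(b, X // 2, Y // 2, Z // 2, 2, 2, 2, c).transpose(0, 1, 4, 2, 5, 3, 6, 7)
        return win.reshape(b, X, Y, Z, c)


class UpsampleNearest2(Module):
    """Nearest-neighbor doubling of all three spatial axes."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, X, Y, Z, c = grad.shape
        return (
            grad.reshape(b, X // 2, 2, Y // 2, 2, Z // 2, 2, c).sum(axis=(2, 4, 6))
        )


class GlobalAvgPool(Module):
    """Spatial mean per channel: (B, X, Y, Z, C) -> (B, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, X, Y, Z, c = self._shape
        return np.broadcast_to(grad[:, None, None, None, :], self._shape) / (X * Y * Z)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adaptive moment estimation with L2 weight decay on flagged parameters."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def get_state(module: Module) -> dict:
    """Serializable network state: parameter values plus BN running stats."""
    state: dict = {"params": [p.value.copy() for p in module.parameters()], "running": []}
    for bn in _iter_batchnorms(module):
        state["running"].append((bn.running_mean.copy(), bn.running_var.copy()))
    return state


def set_state(module: Module, state: dict) -> None:
    params = module.parameters()
    if len(params) != len(state["params"]):
        raise ValueError("state does not match module parameterization")
    for p, v in zip(params, state["params"]):
        p.value[...] = v
    for bn, (mean, var) in zip(_iter_batchnorms(module), state["running"]):
        bn.running_mean[...] = mean
        bn.running_var[...] = var


def _iter_batchnorms(module: Module):
    if isinstance(module, BatchNorm):
        yield module
    for attr in vars(module).values():
        if isinstance(attr, Module) and attr is not module:
            yield from _iter_batchnorms(attr)
        elif isinstance(attr, (list, tuple)):
            for item in attr:
                if isinstance(item, Module):
                    yield from _iter_batchnorms(item)
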
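"""Neural-network building blocks and the Adam optimizer.

Layers hold :class:`~mhnet.autodiff.Tensor` parameters and follow a
torch-like Module convention (``parameters()``, ``train()``/``eval()``)
without any external dependency.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d

__all__ = [
    "Module",
    "Linear",
    "MLP",
    "BatchNorm",
    "Dropout",
    "Conv1dLayer",
    "Adam",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: parameter discovery by attribute walk, train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def _set_mode(self, training: bool):
        self.training = training
        for value in vars(self).values():
            for m in _collect_modules(value):
                m._set_mode(training)

    def train(self):
        self._set_mode(True)
        return self

    def eval(self):
        self._set_mode(False)
        return self

    def modules(self):
        """This module and all transitively nested submodules."""
        yield self
        for value in vars(self).values():
            for m in _collect_modules(value):
                yield from m.modules()

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the module state (parameters + buffers)."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            arrays.extend(m._buffers())
        return arrays

    def _buffers(self) -> list[np.ndarray]:
        return []


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def _collect_modules(value):
    if isinstance(value, Module):
        yield value
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect_modules(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect_modules(v)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(glorot_uniform(rng, d_in, d_out), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; identity in eval mode or at rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.random(x.shape) < keep
        return x * (mask / keep)


class MLP(Module):
    """Fully connected stack with ReLU on hidden layers, linear output."""

    def __init__(
        self,
        dims: list[int],
        rng: np.random.Generator,
        dropout: float = 0.0,
    ):
        super().__init__()
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output dims")
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.dropout = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = self.dropout(layer(x).relu())
        return self.layers[-1](x)


class BatchNorm(Module):
    """Batch normalization per feature (last axis), statistics over all
    leading axes (batch and, for node-feature matrices, nodes).

    At initialization the running statistics are mean 0 / variance 1, so the
    layer is the identity in eval mode until trained.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            x_hat = (x - mu) / (var + self.eps).sqrt()
        else:
            x_hat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return x_hat * self.gamma + self.beta

    def _buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]


class Conv1dLayer(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        if kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        fan_in = in_channels * kernel_size
        self.weight = Tensor(
            glorot_uniform(
                rng, fan_in, out_channels, shape=(out_channels, in_channels, kernel_size)
            ),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
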
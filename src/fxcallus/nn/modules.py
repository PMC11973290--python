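"""Layer abstractions over the autodiff tensor: parameter containers, linear
and convolutional layers, normalization, and a recursive state dict."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Parameter", "Module", "Linear", "Conv2d", "LayerNorm", "BatchNorm2d", "Sequential"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: children and parameters discovered from instance attributes."""

    def __init__(self) -> None:
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    @staticmethod
    def _walk(name: str, val, kind):
        """Yield (name, item) for every `kind` instance in val, descending nested lists."""
        if isinstance(val, kind) and not (kind is Module and isinstance(val, Parameter)):
            yield name, val
        elif isinstance(val, (list, tuple)):
            for i, item in enumerate(val):
                yield from Module._walk(f"{name}.{i}", item, kind)

    def children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                continue
            yield from self._walk(name, val, Module)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Module) and not isinstance(val, Parameter):
                continue
            yield from ((prefix + n, p) for n, p in self._walk(name, val, Parameter))
        for cname, child in self.children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self.children():
            yield from child.named_buffers(prefix + cname + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                buf[...] = value
            else:
                if params[key].shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: {params[key].shape} vs {value.shape}")
                params[key].data = np.asarray(value, dtype=np.float64)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    bound = math.sqrt(1.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, in_features, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        depthwise: bool = False,
        bias: bool = True,
    ):
        super().__init__()
        self.stride, self.padding, self.dilation, self.depthwise = stride, padding, dilation, depthwise
        k = kernel_size
        if depthwise:
            if out_channels != in_channels:
                raise ValueError("depthwise convolution requires out_channels == in_channels")
            self.weight = Parameter(_kaiming(rng, k * k, (in_channels, 1, k, k)))
        else:
            self.weight = Parameter(_kaiming(rng, in_channels * k * k, (out_channels, in_channels, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding, dilation=self.dilation, depthwise=self.depthwise,
        )


class LayerNorm(Module):
    """Normalizes the channel axis (axis 1) of (B, C, ...) feature maps."""

    def __init__(self, num_channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        shape = (1, -1) + (1,) * (len(x.shape) - 2)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class BatchNorm2d(Module):
    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.9):
        super().__init__()
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))
        self.running_mean = np.zeros(num_channels)
        self.running_var = np.ones(num_channels)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu.data.ravel()
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xc = x - mu
        xhat = xc * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)
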
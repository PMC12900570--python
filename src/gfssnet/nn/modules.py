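"""Module/parameter containers and common layers."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .ops3d import conv3d
from .tensor import Tensor

__all__ = ["Parameter", "Module", "Linear", "Conv3d", "ChannelLayerNorm"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Lightweight container: parameters are discovered by attribute walk."""

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        yield from self._walk(seen)

    def _walk(self, seen: set[int]) -> Iterator[Parameter]:
        for value in vars(self).values():
            if isinstance(value, Parameter):
                if id(value) not in seen:
                    seen.add(id(value))
                    yield value
            elif isinstance(value, Module):
                yield from value._walk(seen)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item._walk(seen)
                    elif isinstance(item, Parameter) and id(item) not in seen:
                        seen.add(id(item))
                        yield item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            path = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(path)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.shape}")
            p.data[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, bound, size=shape)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(_kaiming(rng, (in_features, out_features),
                                         in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, *, stride: int = 1,
                 dilation: int = 1, groups: int = 1, bias: bool = True):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same-padding)")
        k = kernel_size
        fan_in = (in_channels // groups) * k ** 3
        self.weight = Parameter(_kaiming(
            rng, (out_channels, in_channels // groups, k, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride, self.dilation, self.groups = stride, dilation, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride,
                      dilation=self.dilation, groups=self.groups)


class ChannelLayerNorm(Module):
    """LayerNorm over the channel axis of (B, C, D, H, W), per voxel."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1)))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=1, keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta
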
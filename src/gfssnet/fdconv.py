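"""Frequency dynamic convolution.

Three cooperating parts: a depthwise sigmoid-gated modulation that
rescales each voxel of each channel into (0, 1) before convolution; a
per-sample attention head (global pooling, two pointwise layers, softmax)
that produces a probability vector over N parallel kernels; and the fused
convolution Y = sum_i alpha_i (W_i * X_mod) + b with a shared bias.  Since
alpha is constant per sample the kernels are blended first and a single
convolution is run per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Module, Parameter, Tensor, as_tensor, concatenate, conv3d,
                 global_avg_pool3d)
from .nn.modules import Linear, _kaiming

__all__ = ["FDConvConfig", "frequency_modulate", "FDConv"]


@dataclass(frozen=True)
class FDConvConfig:
    in_channels: int
    out_channels: int
    kernel_size: int = 3
    n_kernels: int = 4
    attention_reduction: int = 4

    def __post_init__(self):
        if self.n_kernels < 1:
            raise ValueError("n_kernels must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if self.attention_reduction < 1:
            raise ValueError("attention_reduction must be >= 1")


def frequency_modulate(X, depthwise_kernel, bias=None) -> Tensor:
    """X * sigmoid(depthwise_conv(X)); one filter per channel."""
    X = as_tensor(X)
    depthwise_kernel = as_tensor(depthwise_kernel)
    C = X.shape[1]
    if depthwise_kernel.shape[0] != C or depthwise_kernel.shape[1] != 1:
        raise ValueError(
            f"depthwise kernel must be ({C}, 1, k, k, k), "
            f"got {depthwise_kernel.shape}")
    gate = conv3d(X, depthwise_kernel, bias, groups=C).sigmoid()
    return X * gate


class FDConv(Module):
    def __init__(self, cfg: FDConvConfig, rng: np.random.Generator):
        self.cfg = cfg
        k, ci, co, n = (cfg.kernel_size, cfg.in_channels, cfg.out_channels,
                        cfg.n_kernels)
        fan_in = ci * k ** 3
        self.kernels = Parameter(_kaiming(rng, (n, co, ci, k, k, k), fan_in))
        self.bias = Parameter(np.zeros(co))
        self.dw_kernel = Parameter(
            _kaiming(rng, (ci, 1, k, k, k), k ** 3) * 0.1)
        self.dw_bias = Parameter(np.zeros(ci))
        hidden = max(1, ci // cfg.attention_reduction)
        self.attn_fc1 = Linear(ci, hidden, rng)
        self.attn_fc2 = Linear(hidden, n, rng)

    def attention_weights(self, X) -> Tensor:
        """Per-sample probability vector over the N kernels: global pooling
        -> reduce -> rectify -> expand -> softmax."""
        X = as_tensor(X)
        pooled = global_avg_pool3d(X)                    # (B, C)
        return self.attn_fc2(self.attn_fc1(pooled).relu()).softmax(axis=-1)

    def forward(self, X, *, modulate: bool = True,
                alpha: np.ndarray | None = None) -> Tensor:
        X = as_tensor(X)
        if X.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, "
                f"got {X.shape[1]}")
        Xm = frequency_modulate(X, self.dw_kernel, self.dw_bias) \
            if modulate else X
        a = self.attention_weights(X) if alpha is None \
            else as_tensor(np.asarray(alpha, dtype=np.float32))
        n = self.cfg.n_kernels
        flat = self.kernels.reshape(n, -1)               # (N, co*ci*k^3)
        blended = a @ flat                               # (B, co*ci*k^3)
        outs = []
        for b in range(X.shape[0]):  # one fused conv per sample
            wk = blended[b].reshape(self.kernels.shape[1:])
            outs.append(conv3d(Xm[b:b + 1], wk, self.bias))
        return outs[0] if len(outs) == 1 else concatenate(outs, axis=0)
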
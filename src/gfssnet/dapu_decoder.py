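"""Depth-aware progressive upsampling decoder stage.

Per stage: slice-importance attention (mean-pool over the in-plane axes,
channel squeeze/excite per slice, sigmoid, broadcast multiply), a
multi-scale dilated boundary branch, a x2 trilinear upsample + convolution,
concat-fusion with the encoder skip, and a structure-preserving convolution
with a residual.  Four chained stages restore full resolution from the
bottleneck.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (ChannelLayerNorm, Conv3d, Linear, Module, Tensor,
                 as_tensor, concatenate, interpolate)

__all__ = ["DAPUConfig", "depth_pool", "DepthAttention", "depth_enhance",
           "BoundaryBranch", "DAPUStage"]


@dataclass(frozen=True)
class DAPUConfig:
    in_channels: int
    out_channels: int
    dilation_rates: tuple[int, ...] = (1, 2, 4)
    reduction: int = 4

    def __post_init__(self):
        if any(r <= 0 for r in self.dilation_rates):
            raise ValueError("dilation rates must be positive")
        if len(set(self.dilation_rates)) != len(self.dilation_rates):
            raise ValueError("dilation rates must be distinct")


def depth_pool(X) -> Tensor:
    """(B, C, D, H, W) -> (B, C, D): mean over the in-plane axes."""
    return as_tensor(X).mean(axis=(3, 4))


class DepthAttention(Module):
    """A_d = sigmoid(W2 relu(W1 F_depth + b1) + b2), acting on the channel
    axis independently per slice; values in (0, 1)."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, F_depth) -> Tensor:
        F_depth = as_tensor(F_depth)              # (B, C, D)
        h = F_depth.moveaxis(1, 2)                # (B, D, C)
        h = self.fc2(self.fc1(h).relu()).sigmoid()
        return h.moveaxis(2, 1)                   # (B, C, D)


def depth_enhance(X, A_d) -> Tensor:
    """X * A_d with A_d broadcast along the in-plane axes."""
    X, A_d = as_tensor(X), as_tensor(A_d)
    if A_d.shape != X.shape[:3]:
        raise ValueError(
            f"depth attention shape {A_d.shape} does not match "
            f"feature (batch, channel, depth) {X.shape[:3]}")
    return X * A_d.reshape(A_d.shape + (1, 1))


class BoundaryBranch(Module):
    """Parallel dilated convolutions, concatenated and fused pointwise."""

    def __init__(self, channels: int, out_channels: int,
                 rng: np.random.Generator,
                 dilation_rates: tuple[int, ...] = (1, 2, 4)):
        self.convs = [Conv3d(channels, channels, 3, rng, dilation=r)
                      for r in dilation_rates]
        self.fuse = Conv3d(channels * len(dilation_rates), out_channels, 1,
                           rng)

    def forward(self, X) -> Tensor:
        X = as_tensor(X)
        return self.fuse(concatenate([c(X) for c in self.convs], axis=1))


class DAPUStage(Module):
    def __init__(self, cfg: DAPUConfig, rng: np.random.Generator,
                 skip_channels: int | None = None):
        self.cfg = cfg
        skip_channels = cfg.out_channels if skip_channels is None \
            else skip_channels
        self.attn = DepthAttention(cfg.in_channels, rng, cfg.reduction)
        self.boundary = BoundaryBranch(cfg.in_channels, cfg.out_channels,
                                       rng, cfg.dilation_rates)
        self.up_conv = Conv3d(cfg.in_channels, cfg.out_channels, 3, rng)
        self.fuse = Conv3d(2 * cfg.out_channels + skip_channels,
                           cfg.out_channels, 1, rng)
        self.norm = ChannelLayerNorm(cfg.out_channels)
        self.structure = Conv3d(cfg.out_channels, cfg.out_channels, 3, rng)

    def forward(self, X, skip) -> Tensor:
        X, skip = as_tensor(X), as_tensor(skip)
        target = tuple(skip.shape[2:])
        if tuple(2 * s for s in X.shape[2:]) != target:
            raise ValueError(
                f"skip spatial dims {target} must be twice the input "
                f"dims {tuple(X.shape[2:])}")
        enhanced = depth_enhance(X, self.attn(depth_pool(X)))
        up = self.up_conv(interpolate(enhanced, target))
        boundary = interpolate(self.boundary(enhanced), target)
        fused = self.norm(self.fuse(concatenate([up, boundary, skip], axis=1)))
        return self.structure(fused) + fused
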
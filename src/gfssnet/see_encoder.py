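"""Spatial enhancement encoder: four hierarchical stages, each fusing a
frequency-dynamic-convolution path with a multi-directional state-space
path (channel concat + pointwise conv), with a residual around the fused
feature and strided downsampling between stages.  One independent encoder
instance serves each modality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fdconv import FDConv, FDConvConfig
from .nn import ChannelLayerNorm, Conv3d, Module, Tensor, as_tensor, concatenate
from .td_mamba import ALL_DIRECTIONS, TDMamba

__all__ = ["EncoderConfig", "SEEStage", "SEEEncoder"]


@dataclass(frozen=True)
class EncoderConfig:
    stage_channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    d_state: tuple[int, int, int, int] = (8, 8, 16, 16)
    d_conv: tuple[int, int, int, int] = (3, 3, 5, 5)
    n_kernels: int = 4
    attention_reduction: int = 4
    use_mamba: bool = True          # ablation: pure-FDConv stages when False
    directions: tuple = ALL_DIRECTIONS

    def __post_init__(self):
        if len(self.stage_channels) != 4:
            raise ValueError("the encoder has exactly four stages")
        if any(a >= b for a, b in zip(self.stage_channels,
                                      self.stage_channels[1:])):
            raise ValueError("stage channels must be strictly increasing")


class SEEStage(Module):
    def __init__(self, in_channels: int, out_channels: int,
                 cfg: EncoderConfig, stage: int, rng: np.random.Generator):
        self.fd = FDConv(FDConvConfig(
            in_channels, out_channels, n_kernels=cfg.n_kernels,
            attention_reduction=cfg.attention_reduction), rng)
        self.mamba = TDMamba(
            in_channels, rng, d_state=cfg.d_state[stage],
            d_conv=cfg.d_conv[stage],
            directions=cfg.directions) if cfg.use_mamba else None
        fused_in = out_channels + (in_channels if self.mamba else 0)
        self.fuse = Conv3d(fused_in, out_channels, 1, rng)
        self.res_proj = Conv3d(in_channels, out_channels, 1, rng, bias=False)
        self.norm = ChannelLayerNorm(out_channels)  # keeps stage scales bounded
        self.down = Conv3d(out_channels, out_channels, 3, rng, stride=2)

    def pre_downsample(self, X: Tensor) -> Tensor:
        branches = [self.fd(X)]
        if self.mamba is not None:
            branches.append(self.mamba(X))
        fused = self.fuse(concatenate(branches, axis=1)) \
            if len(branches) > 1 else self.fuse(branches[0])
        return self.norm(fused + self.res_proj(X))

    def forward(self, X: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (skip at stage resolution, downsampled output)."""
        X = as_tensor(X)
        if min(X.shape[2:]) < 2:
            raise ValueError(
                f"spatial dims {X.shape[2:]} too small to downsample")
        skip = self.pre_downsample(X)
        return skip, self.down(skip)


class SEEEncoder(Module):
    """Single-modality encoder returning four skips plus the bottleneck."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator,
                 in_channels: int = 1):
        self.cfg = cfg
        self.in_channels = in_channels
        chans = (in_channels,) + cfg.stage_channels
        self.stages = [SEEStage(chans[s], chans[s + 1], cfg, s, rng)
                       for s in range(4)]

    def forward(self, X) -> tuple[list[Tensor], Tensor]:
        X = as_tensor(X)
        if X.ndim != 5:
            raise ValueError("expected a (B, C, D, H, W) input")
        if X.shape[1] != self.in_channels:
            raise ValueError(
                f"this encoder takes {self.in_channels}-channel input, "
                f"got {X.shape[1]} channels")
        skips = []
        for stage in self.stages:
            skip, X = stage(X)
            skips.append(skip)
        return skips, X
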
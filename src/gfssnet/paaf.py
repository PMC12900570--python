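"""Position-aware attention fusion at the bottleneck.

Each modality's bottleneck feature is context-enhanced by a
multi-directional scan block followed by a channel gate
(LayerNorm(F_rot) * sigmoid(W_g F_rot)); the two enhanced maps are
decomposed channel-by-channel and each (t1_c, t2_c) pair is compressed to
a single channel by a grouped pointwise convolution; finally an enhanced
position attention derives a sigmoid spatial weight map from axis-wise
global pooling descriptors and rescales the fused map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (ChannelLayerNorm, Conv3d, Linear, Module, Tensor, as_tensor,
                 stack)
from .td_mamba import ALL_DIRECTIONS, TDMamba

__all__ = ["PAAFConfig", "RotationalEnhance", "ChannelDecomposeFuse",
           "EnhancedPositionAttention", "PAAF"]


@dataclass(frozen=True)
class PAAFConfig:
    channels: int
    reduction: int = 4
    d_state: int = 16
    d_conv: int = 3

    def __post_init__(self):
        if self.channels <= 0:
            raise ValueError("channels must be positive")


class RotationalEnhance(Module):
    """F -> LayerNorm(F_rot) * sigmoid(W_g F_rot), F_rot from a
    three-directional scan block with its own weights."""

    def __init__(self, cfg: PAAFConfig, rng: np.random.Generator):
        self.rot = TDMamba(cfg.channels, rng, d_state=cfg.d_state,
                           d_conv=cfg.d_conv, directions=ALL_DIRECTIONS)
        self.norm = ChannelLayerNorm(cfg.channels)
        self.gate = Conv3d(cfg.channels, cfg.channels, 1, rng, bias=False)

    def enhance(self, F_rot: Tensor) -> Tensor:
        """The gating identity, split out so it can be oracle-tested for a
        given F_rot."""
        return self.norm(F_rot) * self.gate(F_rot).sigmoid()

    def forward(self, F) -> Tensor:
        return self.enhance(self.rot(as_tensor(F)))


class ChannelDecomposeFuse(Module):
    """Compress each cross-modal channel pair to one channel with a
    per-channel pointwise convolution (grouped, group = channel)."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.channels = channels
        self.compress = Conv3d(2 * channels, channels, 1, rng,
                               groups=channels)

    def forward(self, F_t1, F_t2) -> Tensor:
        F_t1, F_t2 = as_tensor(F_t1), as_tensor(F_t2)
        if F_t1.shape != F_t2.shape:
            raise ValueError(
                f"modality shape mismatch: {F_t1.shape} vs {F_t2.shape}")
        B, C = F_t1.shape[0], F_t1.shape[1]
        # interleave channels as (t1_0, t2_0, t1_1, t2_1, ...)
        inter = stack([F_t1, F_t2], axis=2).reshape(
            (B, 2 * C) + tuple(F_t1.shape[2:]))
        return self.compress(inter)


class EnhancedPositionAttention(Module):
    """Sigmoid spatial weights from per-axis global pooling descriptors."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4):
        hidden = max(1, channels // reduction)
        self.proj = [  # one bottleneck per axis descriptor
            (Linear(channels, hidden, rng), Linear(hidden, channels, rng))
            for _ in range(3)]

    def weight_map(self, F: Tensor) -> Tensor:
        F = as_tensor(F)
        logits = None
        pool_axes = [(3, 4), (2, 4), (2, 3)]  # keep D, keep H, keep W
        for i, (axes, (fc1, fc2)) in enumerate(zip(pool_axes, self.proj)):
            desc = F.mean(axis=axes)                 # (B, C, L)
            h = fc2(fc1(desc.moveaxis(1, 2)).relu()).moveaxis(2, 1)
            shape = [h.shape[0], h.shape[1], 1, 1, 1]
            shape[2 + i] = h.shape[2]
            h = h.reshape(tuple(shape))              # broadcastable
            logits = h if logits is None else logits + h
        ones = F * 0.0 + 1.0
        return (logits * ones).sigmoid()             # (B, C, D, H, W)

    def forward(self, F) -> Tensor:
        F = as_tensor(F)
        return self.weight_map(F) * F

    # parameter discovery for the list of tuples
    def _walk(self, seen):
        for fc1, fc2 in self.proj:
            yield from fc1._walk(seen)
            yield from fc2._walk(seen)

    def named_parameters(self, prefix: str = ""):
        for i, (fc1, fc2) in enumerate(self.proj):
            p = f"{prefix}.proj.{i}" if prefix else f"proj.{i}"
            yield from fc1.named_parameters(p + ".0")
            yield from fc2.named_parameters(p + ".1")


class PAAF(Module):
    def __init__(self, cfg: PAAFConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.enhance_t1 = RotationalEnhance(cfg, rng)
        self.enhance_t2 = RotationalEnhance(cfg, rng)
        self.fuse = ChannelDecomposeFuse(cfg.channels, rng)
        self.epa = EnhancedPositionAttention(cfg.channels, rng,
                                             cfg.reduction)

    def forward(self, F_t1, F_t2) -> Tensor:
        e1 = self.enhance_t1(F_t1)
        e2 = self.enhance_t2(F_t2)
        return self.epa(self.fuse(e1, e2))
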
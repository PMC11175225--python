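"""Convolutional block attention (CBAM): channel gating then spatial gating.

Channel attention pools the feature map globally (average and max), pushes
both descriptors through a shared two-layer bottleneck MLP, sums the logits
and squashes with a sigmoid — one weight in (0, 1) per channel.  Spatial
attention reduces the (already channel-gated) map across channels to a
2-channel mean/max image, convolves with a wide kernel and squashes — one
weight per pixel.  The channel-then-spatial order is fixed; the refinement
is a strict contraction (every weight < 1) and therefore never increases
any activation magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor


@dataclass
class AttentionMaps:
    """Channel and spatial gate values for one refinement call."""

    channel_weights: np.ndarray  # (N, C), each in (0, 1)
    spatial_weights: np.ndarray  # (N, 1, H, W), each in (0, 1)


class ChannelAttention(nn.Module):
    """Shared-MLP channel gate; ``reduction`` is the bottleneck ratio r."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator,
                 bias: bool = False):
        super().__init__()
        if reduction >= channels:
            raise ValueError(
                f"reduction {reduction} must be smaller than channel count "
                f"{channels} (bottleneck needs >= 1 unit)")
        hidden = channels // reduction
        self.fc1 = nn.Linear(channels, hidden, rng, bias=bias)
        self.fc2 = nn.Linear(hidden, channels, rng, bias=bias)

    def logits(self, x: Tensor) -> Tensor:
        avg = self.fc2(F.relu(self.fc1(F.global_avg_pool(x))))
        mx = self.fc2(F.relu(self.fc1(F.global_max_pool(x))))
        return avg + mx

    def forward(self, x: Tensor) -> Tensor:
        """Per-channel weights, shape (N, C)."""
        return F.sigmoid(self.logits(x))


class SpatialAttention(nn.Module):
    """Mean/max channel reduction followed by a k×k conv gate (k odd)."""

    def __init__(self, rng: np.random.Generator, kernel_size: int = 7):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError(f"spatial attention kernel must be odd, "
                             f"got {kernel_size}")
        self.conv = nn.Conv2d(2, 1, kernel_size, rng)

    def forward(self, x: Tensor) -> Tensor:
        """Per-pixel weights, shape (N, 1, H, W)."""
        return F.sigmoid(self.conv(F.channel_mean_max(x)))


class CBAM(nn.Module):
    """Sequential channel → spatial refinement, drop-in on any feature map."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4, spatial_kernel: int = 7):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng)
        self.spatial = SpatialAttention(rng, spatial_kernel)

    def forward(self, x: Tensor) -> Tensor:
        cw = self.channel(x)                       # (N, C)
        n, c = cw.shape
        gated = x * cw.reshape(n, c, 1, 1)
        sw = self.spatial(gated)                   # (N, 1, H, W)
        return gated * sw

    def attention_maps(self, x: Tensor) -> AttentionMaps:
        """The two gate fields for inspection (no gradient tracking)."""
        cw = self.channel(x.detach())
        n, c = cw.shape
        gated = x.detach() * cw.reshape(n, c, 1, 1)
        sw = self.spatial(gated)
        return AttentionMaps(channel_weights=cw.data.copy(),
                             spatial_weights=sw.data.copy())


def cbam_refine(f: Tensor, module: CBAM) -> Tensor:
    """Functional alias: apply ``module`` to feature stack ``f``."""
    return module(f)
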
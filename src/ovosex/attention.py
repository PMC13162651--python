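"""Shared attention operators.

Two gating blocks are used at several points in the network:

* :class:`SpatialAttention` — the spatial half of a CBAM block: channel-wise
  mean and max maps are concatenated, passed through a 3x3 convolution and a
  sigmoid, and the resulting [B,1,H,W] mask rescales the input.
* :class:`ChannelAttention` — a squeeze-and-excitation branch: global average
  pooling followed by a two-layer bottleneck MLP (C -> C/r -> C) and a
  sigmoid, producing a per-channel gain in (0,1).

Both are shape-preserving and purely attenuating (gain < 1), so they can be
inserted anywhere without altering downstream geometry.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Module, Tensor


class SpatialAttention(Module):
    """CBAM-style spatial gate: sigmoid(conv3x3(cat(mean_c, max_c))) * x.

    The 3x3 kernel (padding 1) maps the two pooled maps to a single-channel
    mask whose values lie strictly in (0,1) for finite inputs.
    """

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, 3, padding=1, bias=True, rng=rng)

    def mask(self, x: Tensor) -> Tensor:
        mean_map = x.mean(axis=1, keepdims=True)
        max_map = x.max(axis=1, keepdims=True)
        pooled = nn.cat([mean_map, max_map], axis=1)
        return nn.sigmoid(self.conv(pooled))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.mask(x)


class ChannelAttention(Module):
    """Squeeze-and-excitation channel gate with reduction ratio ``r``."""

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(
                f"channel attention requires C divisible by reduction: "
                f"C={channels}, r={reduction}")
        hidden = channels // reduction
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def scales(self, x: Tensor) -> Tensor:
        pooled = nn.global_avg_pool(x)              # [B,C]
        return nn.sigmoid(self.fc2(nn.relu(self.fc1(pooled))))

    def forward(self, x: Tensor) -> Tensor:
        s = self.scales(x)
        B, C = s.shape
        return x * s.reshape(B, C, 1, 1)
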
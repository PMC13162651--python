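"""Multi-Scale Adaptive Attention Fusion (MSAAF) block.

Vessel networks are slender and strongly oriented along the horizontal and
vertical axes, features that an isotropic 3x3 kernel captures inefficiently.
The MSAAF block screens deep features through three parallel branches on the
same input:

* **directional** — a 1x3 and a 3x1 convolution (an asymmetric split of a
  3x3 kernel: 6C^2 weights instead of 9C^2, a 33% reduction) are summed and
  recalibrated by sigmoid(1x1 conv);
* **spatial** — CBAM-style spatial attention (see :mod:`ovosex.attention`);
* **channel** — squeeze-and-excitation channel attention.

The branch outputs are fused with free learnable scalars, each initialised
to 0.1 so no branch dominates early training::

    out = x + alpha * F_direction + beta * F_space + gamma * F_channel

The residual keeps the block an exact identity-plus-perturbation: fusion is
linear in (alpha, beta, gamma).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .attention import ChannelAttention, SpatialAttention
from .nn import Module, Parameter, Tensor

#: initial value of each fusion weight
FUSION_INIT = 0.1


class DirectionalBranch(Module):
    """Horizontal (1x3) + vertical (3x1) convolutions with 1x1 recalibration.

    The two asymmetric kernels run in parallel on the same input and are
    summed before the recalibration gate. Convolutions carry no bias, so the
    asymmetric pair accounts for exactly 6C^2 weights; the 1x1 recalibration
    adds a separate C^2 (+C bias).
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv_h = nn.Conv2d(channels, channels, (1, 3), padding=(0, 1),
                                bias=False, rng=rng)
        self.conv_v = nn.Conv2d(channels, channels, (3, 1), padding=(1, 0),
                                bias=False, rng=rng)
        self.recal = nn.Conv2d(channels, channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        summed = self.conv_h(x) + self.conv_v(x)
        gate = nn.sigmoid(self.recal(summed))
        return summed * gate


class MSAAFModule(Module):
    """Three-branch adaptive fusion with learnable scalar weights."""

    def __init__(self, channels: int, se_reduction: int = 4,
                 fusion_init: float = FUSION_INIT, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.channels = channels
        self.direction = DirectionalBranch(channels, rng=rng)
        self.space = SpatialAttention(rng=rng)
        self.channel = ChannelAttention(channels, reduction=se_reduction, rng=rng)
        self.alpha = Parameter(np.float32(fusion_init))
        self.beta = Parameter(np.float32(fusion_init))
        self.gamma = Parameter(np.float32(fusion_init))

    @property
    def fusion_weights(self) -> tuple[float, float, float]:
        return (float(self.alpha.data), float(self.beta.data), float(self.gamma.data))

    def forward(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[1] != self.channels:
            raise ValueError(f"MSAAF built for C={self.channels}, got C={x.shape[1]}")
        f_dir = self.direction(x)
        f_space = self.space(x)
        f_chan = self.channel(x)
        return x + self.alpha * f_dir + self.beta * f_space + self.gamma * f_chan
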
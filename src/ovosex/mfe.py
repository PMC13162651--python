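"""Micro Feature Enhancement (MFE) block.

Early-incubation vessel features are thin, low-contrast and locally
concentrated, so they are easily drowned out by shell texture and
illumination noise. The MFE block enhances them region by region:

1. the feature map [B,C,H,W] is split into non-overlapping PxP patches,
   giving a patch tensor [B, N, Dp, C] with N = (H/P)(W/P), Dp = P^2;
2. the channel mean of each patch yields a pure spatial region descriptor
   [B, N, Dp];
3. a linear encoder -> layer norm -> linear decoder lifts the descriptor
   back to the channel dimension: Y = LayerNorm(X W_e^T + b_e) W_d^T + b_d;
4. each region vector v_i is sharpened by v_i' = v_i (*) softmax(v_i), scored
   against a global learnable prompt vector by cosine similarity S_i,
   sparsely masked by M_i = max(0, S_i), and reconstructed through a shared
   learnable matrix: f_i = (v_i' * M_i) W_trans — regions anti-aligned with
   the prompt are silenced exactly;
5. the gated region vectors are placed on the region grid [B,C,H/P,W/P],
   refined by spatial attention, expanded to each region's PxP footprint by
   nearest-neighbour replication, and added residually to the input.

The residual path guarantees the block degrades to the identity when the
enhancement is gated to zero, and output shape always equals input shape.
"""

from __future__ import annotations

import logging

import numpy as np

from . import nn
from .attention import SpatialAttention
from .nn import Module, Parameter, Tensor

logger = logging.getLogger(__name__)

#: numerical floor for the cosine-similarity denominator
COSINE_EPS = 1e-8


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def split_into_patches(x, patch_size: int) -> Tensor:
    """Rearrange [B,C,H,W] into the patch tensor [B, N, P^2, C].

    The rearrangement is lossless: :func:`merge_patches` is its exact
    inverse. Raises ``ValueError`` when P does not divide H and W.
    """
    x = _as_tensor(x)
    B, C, H, W = x.shape
    P = patch_size
    if H % P or W % P:
        raise ValueError(f"patch size must divide the feature map: H={H}, W={W}, P={P}")
    hp, wp = H // P, W // P
    out = x.reshape(B, C, hp, P, wp, P)
    out = out.transpose(0, 2, 4, 3, 5, 1)            # [B,hp,wp,P,P,C]
    return out.reshape(B, hp * wp, P * P, C)


def merge_patches(patches, height: int, width: int, patch_size: int) -> Tensor:
    """Inverse of :func:`split_into_patches`: [B,N,P^2,C] -> [B,C,H,W]."""
    patches = _as_tensor(patches)
    B, N, Dp, C = patches.shape
    P = patch_size
    hp, wp = height // P, width // P
    if N != hp * wp or Dp != P * P:
        raise ValueError(f"patch tensor {patches.shape} does not tile {height}x{width} with P={P}")
    out = patches.reshape(B, hp, wp, P, P, C)
    out = out.transpose(0, 5, 1, 3, 2, 4)            # [B,C,hp,P,wp,P]
    return out.reshape(B, C, height, width)


def channel_mean(patches) -> Tensor:
    """Region descriptor: mean over the channel axis, [B,N,Dp,C] -> [B,N,Dp]."""
    return _as_tensor(patches).mean(axis=3)


class RegionEncoderDecoder(Module):
    """Linear encode -> layer norm (latent axis) -> linear decode.

    Maps the low-dimensional spatial descriptor [B,N,Dp] to region features
    [B,N,C], restoring the channel dimension of the insertion point.
    """

    def __init__(self, patch_dim: int, latent_dim: int, channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.encoder = nn.Linear(patch_dim, latent_dim, rng=rng)
        self.norm = nn.LayerNorm(latent_dim)
        self.decoder = nn.Linear(latent_dim, channels, rng=rng)

    def forward(self, desc) -> Tensor:
        return self.decoder(self.norm(self.encoder(_as_tensor(desc))))


class PromptGate(Module):
    """Prompt-guided sparse gating of region features.

    A single learnable prompt vector of length C scores every region by
    cosine similarity; regions with non-positive similarity contribute
    nothing. ``W_trans`` is one shared CxC reconstruction matrix.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.prompt = Parameter(nn.he_normal(rng, (channels,), fan_in=channels))
        self.w_trans = Parameter(nn.he_normal(rng, (channels, channels), fan_in=channels))

    def forward(self, v) -> Tensor:
        v = _as_tensor(v)                            # [B,N,C]
        v_enh = v * nn.softmax(v, axis=-1)
        dot = (v_enh * self.prompt).sum(axis=-1)     # [B,N]
        v_norm = (v_enh * v_enh).sum(axis=-1).sqrt()
        p_norm = (self.prompt * self.prompt).sum(axis=-1).sqrt()
        degenerate = (v_norm.data < COSINE_EPS) | (p_norm.data < COSINE_EPS)
        if degenerate.any():
            logger.warning("prompt gate: %d region(s) with ~zero norm suppressed",
                           int(degenerate.sum()))
        sim = dot / (v_norm * p_norm + COSINE_EPS)
        mask = nn.relu(sim)                          # M_i in [0, 1]
        B, N, C = v.shape
        gated = v_enh * mask.reshape(B, N, 1)
        return gated @ self.w_trans


class MFEModule(Module):
    """Full micro-feature-enhancement pipeline with residual connection."""

    def __init__(self, channels: int, patch_size: int = 2, latent_dim: int = 16,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.patch_size = patch_size
        self.channels = channels
        self.coder = RegionEncoderDecoder(patch_size * patch_size, latent_dim,
                                          channels, rng=rng)
        self.gate = PromptGate(channels, rng=rng)
        self.spatial = SpatialAttention(rng=rng)

    def forward(self, x) -> Tensor:
        x = _as_tensor(x)
        B, C, H, W = x.shape
        if C != self.channels:
            raise ValueError(f"MFE built for C={self.channels}, got C={C}")
        P = self.patch_size
        patches = split_into_patches(x, P)
        desc = channel_mean(patches)
        region = self.coder(desc)                    # [B,N,C]
        gated = self.gate(region)
        hp, wp = H // P, W // P
        grid = gated.reshape(B, hp, wp, C).transpose(0, 3, 1, 2)
        attended = self.spatial(grid)
        enhanced = nn.upsample_nearest(attended, P)
        return x + enhanced
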
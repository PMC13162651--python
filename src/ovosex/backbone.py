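"""Lightweight convolutional-Transformer backbone for candled-egg sexing.

The network follows the MobileViT-V3 recipe: a convolutional stem,
inverted-residual (MobileNetV2-style) stages, and three hybrid stages whose
MobileViT blocks unfold the feature map into 2x2 patches, run a small
Transformer over patch positions, fold back, and fuse with the local
representation through a 1x1 convolution plus residual.

Two optional enhancement blocks target weak vessel features:

* the :class:`~ovosex.mfe.MFEModule` sits inside the Stage-3 hybrid block,
  immediately after the 1x1 patch-embedding projection, operating on the
  projected [B,d,H,W] map;
* the :class:`~ovosex.msaaf.MSAAFModule` sits on the Stage-4 output.

Both preserve their insertion shape, so the improved network is the
baseline graph plus two drop-in blocks, and parameter counts are additive.

The shipped default profile (`PROFILES["paper"]`) is calibrated so the
two-class baseline lands at ~2.74 M parameters; the exact width of the
variant behind that budget is not published, so the profile is this
package's own calibration (see docs/methods.md). FLOPs are reported under
a multiply-accumulate x 2 convention covering convolutions and matrix
multiplications.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Sequence

import numpy as np

from . import nn
from .mfe import MFEModule
from .msaaf import MSAAFModule
from .nn import Module, Tensor

#: total spatial downsampling factor of the backbone
DOWNSAMPLE = 32


class ConfigurationError(ValueError):
    pass


@dataclasses.dataclass
class ModelConfig:
    """Architecture and enhancement-module hyperparameters.

    ``stage_channels`` are the output channels of the stem and the five
    stages; ``transformer_dims``/``depths`` configure the three hybrid
    stages (Stages 3-5).
    """

    num_classes: int = 2
    input_size: int = 224
    width_multiplier: float = 1.0
    stage_channels: Sequence[int] = (16, 32, 48, 64, 80, 96)
    transformer_dims: Sequence[int] = (96, 120, 144)
    transformer_depths: Sequence[int] = (2, 4, 3)
    num_heads: int = 4
    ffn_mult: float = 2.0
    expand_ratio: int = 4
    last_conv_channels: int = 384
    vit_patch_size: int = 2
    mfe_enabled: bool = False
    msaaf_enabled: bool = False
    mfe_patch_size: int = 2
    mfe_latent_dim: int = 16
    se_reduction: int = 4
    fusion_init: float = 0.1
    seed: int = 0

    def scaled_channels(self) -> list[int]:
        def r8(v: float) -> int:
            return max(8, int(round(v / 8)) * 8)
        return [r8(c * self.width_multiplier) for c in self.stage_channels]

    def scaled_dims(self) -> list[int]:
        h = self.num_heads

        def rh(v: float) -> int:
            return max(h, int(round(v * self.width_multiplier / h)) * h)
        return [rh(d) for d in self.transformer_dims]

    def validate(self) -> None:
        if self.num_classes < 2:
            raise ConfigurationError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.input_size % DOWNSAMPLE:
            raise ConfigurationError(
                f"input_size {self.input_size} is not divisible by the backbone's "
                f"total downsampling factor {DOWNSAMPLE} (stage 5 stride)")
        stage3_side = self.input_size // 8
        if stage3_side % self.mfe_patch_size:
            raise ConfigurationError(
                f"mfe_patch_size {self.mfe_patch_size} does not divide the Stage-3 "
                f"feature side {stage3_side}")
        if len(self.stage_channels) != 6:
            raise ConfigurationError("stage_channels must list stem + 5 stages")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_channels"] = list(d["stage_channels"])
        d["transformer_dims"] = list(d["transformer_dims"])
        d["transformer_depths"] = list(d["transformer_depths"])
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


#: named architecture profiles: "paper" is calibrated so the two-class
#: baseline lands at ~2.74 M parameters; "desk" is a narrow profile for
#: CPU-scale experiments.
PROFILES: dict[str, dict] = {
    "paper": {
        "stage_channels": (24, 48, 64, 88, 112, 136),
        "transformer_dims": (132, 164, 200),
    },
    "desk": {
        "input_size": 64,
        "stage_channels": (8, 16, 24, 32, 40, 48),
        "transformer_dims": (32, 40, 48),
        "transformer_depths": (1, 1, 1),
        "last_conv_channels": 96,
        "mfe_latent_dim": 8,
    },
}


def profile_config(name: str = "paper", **overrides) -> ModelConfig:
    if name not in PROFILES:
        raise ConfigurationError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
    kwargs = dict(PROFILES[name])
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


class ConvBNAct(Module):
    def __init__(self, cin, cout, k, stride=1, padding=0, groups=1, act=True, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, padding=padding,
                              groups=groups, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return nn.silu(y) if self.act else y


class InvertedResidual(Module):
    """MobileNetV2 block: 1x1 expand, 3x3 depthwise, 1x1 project."""

    def __init__(self, cin, cout, stride=1, expand=4, rng=None):
        super().__init__()
        hidden = cin * expand
        self.expand = ConvBNAct(cin, hidden, 1, rng=rng)
        self.dw = ConvBNAct(hidden, hidden, 3, stride=stride, padding=1,
                            groups=hidden, rng=rng)
        self.project = ConvBNAct(hidden, cout, 1, act=False, rng=rng)
        self.use_res = stride == 1 and cin == cout

    def forward(self, x):
        y = self.project(self.dw(self.expand(x)))
        return x + y if self.use_res else y


class TransformerEncoder(Module):
    """Pre-norm Transformer layer: LN-MHSA-residual, LN-FFN-residual."""

    def __init__(self, dim, heads, ffn_dim, rng=None):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.qkv = nn.Linear(dim, 3 * dim, rng=rng)
        self.proj = nn.Linear(dim, dim, rng=rng)
        self.norm2 = nn.LayerNorm(dim)
        self.ffn1 = nn.Linear(dim, ffn_dim, rng=rng)
        self.ffn2 = nn.Linear(ffn_dim, dim, rng=rng)
        self.heads = heads
        self.dim = dim

    def attend(self, x: Tensor) -> Tensor:
        S, N, d = x.shape
        h = self.heads
        dh = d // h
        qkv = self.qkv(x).reshape(S, N, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = (qkv.reshape(3 * S * h, N, dh)[i * S * h:(i + 1) * S * h]
                   for i in range(3))
        # per-head scaled dot-product attention over patch positions
        att = nn.softmax((q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh)), axis=-1)
        out = (att @ v).reshape(S, h, N, dh).transpose(0, 2, 1, 3).reshape(S, N, d)
        return self.proj(out)

    def forward(self, x):
        x = x + self.attend(self.norm1(x))
        return x + self.ffn2(nn.silu(self.ffn1(self.norm2(x))))


def _pad_to_multiple(x: Tensor, mult: int) -> tuple[Tensor, int, int]:
    """Zero-pad bottom/right so H and W are divisible by ``mult``."""
    B, C, H, W = x.shape
    ph = (-H) % mult
    pw = (-W) % mult
    if not (ph or pw):
        return x, H, W
    data = np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw)))

    def backward(g):
        if x.requires_grad:
            x._accum(g[:, :, :H, :W])

    return x._wrap(data, (x,), backward), H, W


class MobileViTBlock(Module):
    """Hybrid block: depthwise local rep, patch Transformer, 1x1 fusion.

    The 1x1 projection after the local representation is the block's
    patch-embedding step; when ``mfe`` is supplied it enhances that
    projected map before unfolding.
    """

    def __init__(self, channels, dim, depth, heads, ffn_mult, patch_size=2,
                 mfe: MFEModule | None = None, rng=None):
        super().__init__()
        self.local_dw = ConvBNAct(channels, channels, 3, padding=1,
                                  groups=channels, rng=rng)
        self.embed = nn.Conv2d(channels, dim, 1, bias=False, rng=rng)
        self.transformer = nn.Sequential(
            [TransformerEncoder(dim, heads, int(dim * ffn_mult), rng=rng)
             for _ in range(depth)])
        self.post_norm = nn.LayerNorm(dim)
        self.proj = ConvBNAct(dim, channels, 1, rng=rng)
        self.fusion = nn.Conv2d(dim + channels, channels, 1, bias=False, rng=rng)
        self.fusion_bn = nn.BatchNorm2d(channels)
        self.patch_size = patch_size
        self.dim = dim
        self.mfe = mfe if mfe is not None else nn.Identity()

    def _unfold(self, x: Tensor):
        P = self.patch_size
        x, H, W = _pad_to_multiple(x, P)
        B, d, Hp, Wp = x.shape
        hp, wp = Hp // P, Wp // P
        seq = x.reshape(B, d, hp, P, wp, P).transpose(0, 3, 5, 2, 4, 1)
        return seq.reshape(B * P * P, hp * wp, d), (B, d, Hp, Wp, H, W)

    def _fold(self, seq: Tensor, meta):
        B, d, Hp, Wp, H, W = meta
        P = self.patch_size
        hp, wp = Hp // P, Wp // P
        x = seq.reshape(B, P, P, hp, wp, d).transpose(0, 5, 3, 1, 4, 2)
        x = x.reshape(B, d, Hp, Wp)
        if (Hp, Wp) != (H, W):
            data = x.data[:, :, :H, :W]

            def backward(g):
                if x.requires_grad:
                    gp = np.zeros((B, d, Hp, Wp), dtype=np.float32)
                    gp[:, :, :H, :W] = g
                    x._accum(gp)

            return x._wrap(data, (x,), backward)
        return x

    def forward(self, x):
        local = self.embed(self.local_dw(x))          # patch embedding, [B,d,H,W]
        local = self.mfe(local)
        seq, meta = self._unfold(local)
        seq = self.post_norm(self.transformer(seq))
        glob = self.proj(self._fold(seq, meta))       # back to C channels
        fused = self.fusion_bn(self.fusion(nn.cat([local, glob], axis=1)))
        return x + fused


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class Network(Module):
    """Baseline or improved backbone, per the flags in :class:`ModelConfig`."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.scaled_channels()
        dims = config.scaled_dims()
        depths = list(config.transformer_depths)
        e = config.expand_ratio

        self.stem = ConvBNAct(3, ch[0], 3, stride=2, padding=1, rng=rng)
        self.stage1 = nn.Sequential([InvertedResidual(ch[0], ch[1], 1, e, rng=rng)])
        self.stage2 = nn.Sequential([
            InvertedResidual(ch[1], ch[2], 2, e, rng=rng),
            InvertedResidual(ch[2], ch[2], 1, e, rng=rng),
            InvertedResidual(ch[2], ch[2], 1, e, rng=rng)])

        mfe = None
        if config.mfe_enabled:
            mfe = MFEModule(dims[0], patch_size=config.mfe_patch_size,
                            latent_dim=config.mfe_latent_dim, seed=config.seed)
        # owned (and registered) by the Stage-3 hybrid block; keep a handle only
        object.__setattr__(self, "mfe", mfe)

        def hybrid(cin, cout, dim, depth, mfe_block=None):
            return nn.Sequential([
                InvertedResidual(cin, cout, 2, e, rng=rng),
                MobileViTBlock(cout, dim, depth, config.num_heads,
                               config.ffn_mult, config.vit_patch_size,
                               mfe=mfe_block, rng=rng)])

        self.stage3 = hybrid(ch[2], ch[3], dims[0], depths[0], mfe_block=mfe)
        self.stage4 = hybrid(ch[3], ch[4], dims[1], depths[1])
        self.msaaf = (MSAAFModule(ch[4], se_reduction=config.se_reduction,
                                  fusion_init=config.fusion_init, seed=config.seed)
                      if config.msaaf_enabled else nn.Identity())
        self.stage5 = hybrid(ch[4], ch[5], dims[2], depths[2])
        self.head_conv = ConvBNAct(ch[5], config.last_conv_channels, 1, rng=rng)
        self.classifier = nn.Linear(config.last_conv_channels, config.num_classes,
                                    rng=rng)
        self._feature_cache: Tensor | None = None

    def forward(self, x, record_features: bool = False) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        y = self.stem(x)
        y = self.stage1(y)
        y = self.stage2(y)
        y = self.stage3(y)
        y = self.stage4(y)
        y = self.msaaf(y)
        y = self.stage5(y)
        y = self.head_conv(y)
        if record_features:
            y.requires_grad = True   # retain grad for activation mapping
            self._feature_cache = y
        pooled = nn.global_avg_pool(y)
        return self.classifier(pooled)

    # -- reporting ----------------------------------------------------------
    def stage_summary(self, input_size: int | None = None) -> list[dict]:
        """Per-stage output shape and parameter count (probe forward, eval)."""
        size = input_size or self.config.input_size
        was_training = self.training
        self.eval()
        x = Tensor(np.zeros((1, 3, size, size), dtype=np.float32))
        rows = []
        y = x
        for name in ["stem", "stage1", "stage2", "stage3", "stage4", "msaaf",
                     "stage5", "head_conv"]:
            mod = getattr(self, name)
            y = mod(y)
            rows.append({"layer": name, "output_shape": list(y.shape),
                         "params": mod.num_parameters()})
        pooled = nn.global_avg_pool(y)
        logits = self.classifier(pooled)
        rows.append({"layer": "classifier", "output_shape": list(logits.shape),
                     "params": self.classifier.num_parameters()})
        self.train(was_training)
        return rows

    def summary_text(self) -> str:
        rows = self.stage_summary()
        lines = [f"{'layer':<12}{'output shape':<22}{'params':>10}"]
        for r in rows:
            lines.append(f"{r['layer']:<12}{str(tuple(r['output_shape'])):<22}"
                         f"{r['params']:>10,}")
        lines.append(f"{'total':<34}{self.num_parameters():>10,}")
        return "\n".join(lines)


def build_baseline(config: ModelConfig) -> Network:
    """Backbone without enhancement blocks (flags must be off)."""
    if config.mfe_enabled or config.msaaf_enabled:
        raise ConfigurationError("build_baseline requires mfe_enabled=msaaf_enabled=False")
    return Network(config)


def build_improved(config: ModelConfig) -> Network:
    """Backbone with MFE (Stage-3 patch embedding) and/or MSAAF (Stage-4 out)."""
    return Network(config)


def count_parameters(network: Module) -> int:
    return network.num_parameters()


def count_flops(network: Network, input_size: int | None = None,
                batch: int = 1) -> int:
    """Forward-pass FLOPs (MAC x 2 over convs and matmuls), per ``batch``."""
    size = input_size or network.config.input_size
    was_training = network.training
    network.eval()
    x = np.zeros((batch, 3, size, size), dtype=np.float32)
    with nn.flop_counting() as state:
        network(x)
        total = nn.flops_counted(state)
    network.train(was_training)
    return total


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(network: Network, path) -> None:
    """Single-file weights container with an embedded config echo."""
    meta = json.dumps({"config": network.config.to_dict(),
                       "config_hash": network.config.hash()})
    bn_state = {}
    for i, m in enumerate(network.modules()):
        if isinstance(m, nn.BatchNorm2d):
            bn_state[f"bn{i}.mean"] = m.running_mean
            bn_state[f"bn{i}.var"] = m.running_var
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **network.state_dict(), **bn_state)


def load_checkpoint(path) -> Network:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    config = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in meta["config"].items()})
    if config.hash() != meta["config_hash"]:
        raise ValueError("checkpoint config hash mismatch")
    net = Network(config)
    bn_keys = {k: v for k, v in arrays.items() if k.startswith("bn")}
    net.load_state_dict({k: v for k, v in arrays.items() if not k.startswith("bn")})
    for i, m in enumerate(net.modules()):
        if isinstance(m, nn.BatchNorm2d):
            m.running_mean = bn_keys[f"bn{i}.mean"].copy()
            m.running_var = bn_keys[f"bn{i}.var"].copy()
    return net
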
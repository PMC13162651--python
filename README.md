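# ovosex

Early, non-destructive sex identification of chicken embryos from
transmission-candling images, at day 4 of incubation — before the
chorioallantoic membrane obscures the vasculature and well before
nociception develops. The motivating problem is the culling of day-old male
layer chicks: classifying eggs by sex in ovo lets hatcheries remove male
eggs early, which several countries now require.

Day-4 vessels are thin, low-contrast and easily drowned by shell texture
and illumination noise, so this is a weak-target, fine-grained
classification task. `ovosex` implements a lightweight convolutional–
Transformer backbone (MobileViT-V3-style) with two vessel-focused
enhancement blocks, plus everything needed to train and evaluate it without
access to proprietary hatchery data:

- **MFE (micro feature enhancement)** — inserted after the Stage-3 patch
  embedding. Feature maps are split into non-overlapping P×P patches
  (P = 2, so each flattened patch has spatial dimension Dp = 4), reduced to
  channel-mean region descriptors, lifted back to channel space by a linear
  encoder → LayerNorm → linear decoder
  (Y = LayerNorm(X Wₑᵀ + bₑ) W_dᵀ + b_d), then gated region-by-region: each
  region vector vᵢ is sharpened to vᵢ′ = vᵢ ⊙ softmax(vᵢ), scored against a
  global learnable prompt vector by cosine similarity Sᵢ, masked by
  Mᵢ = max(0, Sᵢ), and reconstructed through a shared C×C matrix
  (fᵢ = (vᵢ′·Mᵢ) W_trans). Spatial attention and a residual connection
  finish the block.
- **MSAAF (multi-scale adaptive attention fusion)** — inserted after
  Stage 4. Three parallel branches on the same input: a directional branch
  of 1×3 + 3×1 asymmetric convolutions (6C² weights instead of 9C², a 33%
  saving) with sigmoid 1×1 recalibration; CBAM-style spatial attention; and
  squeeze-and-excitation channel attention. Outputs fuse as
  x + α·F_dir + β·F_space + γ·F_chan with free scalars α, β, γ initialised
  to 0.1.
- a **synthetic candled-egg generator** (bright shell-textured ellipse,
  recursive branching vessel trees with class-dependent density and
  orientation statistics, ground-truth vessel masks, four quality strata),
- the **preprocessing pipeline** (ellipse-fit background removal,
  conditional CLAHE, resize to the model input, [0,1] scaling) and the
  eight-operation seeded augmentation applied to the training split only,
- **training/ablation/evaluation** harnesses with AdamW, cosine decay,
  leakage auditing, confusion metrics with Cohen's κ, ROC/PR curves,
  per-quality-stratum accuracy and Grad-CAM activation-focus ratios.

No deep-learning framework is required: the package carries its own small
reverse-mode autodiff engine on numpy (`ovosex.nn`).

## Worked example

```python
import numpy as np
from ovosex import (GeneratorParams, render_egg, locate_egg_ellipse,
                    profile_config, build_baseline, build_improved,
                    count_parameters, count_flops)

sample = render_egg(GeneratorParams(image_size=128, class_effect=1.0),
                    seed=42, label="F")
fit = locate_egg_ellipse(sample.image)
print(f"label={sample.label}  vessel_pixels={int(sample.vessel_mask.sum())}")
print(f"egg centre=({fit.center[0]:.1f}, {fit.center[1]:.1f})  "
      f"semi-axes=({fit.a:.1f}, {fit.b:.1f})")

baseline = build_baseline(profile_config("paper"))
improved = build_improved(profile_config("paper", mfe_enabled=True,
                                         msaaf_enabled=True))
pb, pi = count_parameters(baseline), count_parameters(improved)
fb, fi = count_flops(baseline, 224), count_flops(improved, 224)
print(f"baseline: {pb/1e6:.2f} M params, {fb/1e6:.0f} M FLOPs")
print(f"improved: {pi/1e6:.2f} M params (+{100*(pi-pb)/pb:.1f}%), "
      f"{fi/1e6:.0f} M FLOPs (+{100*(fi-fb)/fb:.1f}%)")
```

prints

```
label=F  vessel_pixels=609
egg centre=(67.6, 56.5)  semi-axes=(49.1, 34.7)
baseline: 2.73 M params, 2401 M FLOPs
improved: 2.84 M params (+4.2%), 2443 M FLOPs (+1.8%)
```

The rendered female egg carries 609 vessel pixels (females receive denser,
more horizontally anisotropic trees when the class-effect knob is up); the
ellipse fit recovers the egg geometry used for background removal. The
default "paper" profile is calibrated to a ~2.74 M-parameter two-class
baseline; adding both enhancement blocks costs 4.2% parameters and 1.8%
FLOPs (FLOPs are multiply–accumulate × 2 over convolutions and matmuls).

A shell workflow covering the same ground:

```bash
ovosex generate --out data/ --preset desk --seed 1
ovosex train    --data data/ --out run/ --preset desk --seed 1 --improved
ovosex evaluate --checkpoint run/model.npz --data data/ --out eval/ --seed 1
ovosex ablate   --data data/ --out ablation/ --preset desk --seed 1
```

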
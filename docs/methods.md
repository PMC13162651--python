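# Methods

## Task and model

Day-4 candling images show a bright egg disc on a dark background crossed
by a thin vascular tree; the sexes differ only in subtle vessel statistics.
The classifier is a MobileViT-V3-style hybrid: a strided convolutional
stem, two inverted-residual (MobileNetV2) stages, then three hybrid stages
whose blocks compute a depthwise local representation, project it to a
transformer width d (the patch embedding), unfold the map into 2×2
patches, run a small pre-norm Transformer across patch positions, fold
back, and fuse local and global paths through a 1×1 convolution with a
residual. Odd-sized maps are zero-padded to the patch multiple before
unfolding and cropped after folding.

Two enhancement blocks target weak vessels:

**Micro feature enhancement (MFE)**, inside the Stage-3 hybrid block
immediately after the 1×1 patch-embedding projection. The projected
[B,d,H,W] map is split into non-overlapping P×P patches (P = 2), giving
patch tensors [B, N, Dp, d] with N = (H/P)(W/P) and Dp = P² = 4; the
channel mean yields a purely spatial region descriptor; a linear encoder,
layer normalisation over the latent axis and a linear decoder lift it back
to d channels (the formula is followed literally — no extra nonlinearity
inside the coder, see "open choices"); a prompt gate sharpens each region
(vᵢ ⊙ softmax(vᵢ) over the channel axis), scores it against a single
learnable prompt vector by cosine similarity (denominator stabilised with
ε = 1e-8; zero-norm regions are defined to score 0 and are logged), clips
the score at 0 into a sparse mask, and reconstructs through one shared d×d
matrix. Gated region vectors are laid out on the region grid
[B,d,H/P,W/P], refined by spatial attention, expanded to each region's P×P
footprint by nearest-neighbour replication, and added residually to the
block input. The residual makes the block an exact identity whenever the
gate or decoder silences the enhancement path.

**Multi-scale adaptive attention fusion (MSAAF)**, on the Stage-4 output.
Three branches act in parallel on the same input: (i) directional — 1×3
and 3×1 convolutions (no bias; 6C² weights versus 9C² for a square 3×3
kernel) summed and then recalibrated by sigmoid(1×1 conv); (ii) CBAM-style
spatial attention (channel mean/max pooling → 3×3 conv → sigmoid mask, the
kernel size kept at 3×3 as specified for this architecture rather than
CBAM's 7×7); (iii) squeeze-and-excitation channel attention (GAP → C→C/r →
ReLU → C/r→C → sigmoid, r = 4 because Stage-4 widths are small). Fusion is
x + α·F_dir + β·F_space + γ·F_chan with free scalars initialised to 0.1,
so the output is linear in (α, β, γ) and the residual integrity is exact.

## Architecture profiles

The published parameter budget (2.74 M baseline) does not come with a
stated width configuration, so the default "paper" profile is this
package's own calibration: stage channels (24, 48, 64, 88, 112, 136),
transformer dims (132, 164, 200) with depths (2, 4, 3), 4 heads, FFN
multiplier 2, expansion 4, final 1×1 width 384. That yields 2.727 M
parameters for two classes; with both blocks, 2.841 M (+4.19%). FLOPs are
counted as multiply–accumulate × 2 over convolutions and matrix
multiplications (pointwise ops and bias adds ignored); under this
convention the baseline costs 2 401 M at 224² and the improved model
+1.75%. Counting conventions differ between tools, so the overhead ratios,
not the absolute FLOPs, are the meaningful figures.

The "desk" profile (stem 8, stages up to 48 channels, transformer dims
32/40/48, depth 1 each, 64-px inputs, ~132 k parameters with both blocks)
exists so that complete train/evaluate cycles run in minutes on one CPU;
all reported desk-scale results use it.

## Training protocol

AdamW (decoupled weight decay 0.01 — the decay value is not part of the
published protocol), batch size 32, cosine learning-rate decay, all
randomness descending from one root seed. The "paper" preset keeps the
published settings (100 epochs, initial lr 1e-4), which presume
ImageNet-pretrained initialisation; pretrained weights are out of scope
here, so the desk preset — which always starts from random initialisation —
uses lr 1e-3 and 10 epochs, without which a small model barely moves in
that budget. A validation fraction (default 10%) carved from the training
split drives best-checkpoint selection (ties resolved toward the earlier
epoch); the desk smoke benchmark sets it to 0 to use the full stated
training-set size. An access audit in the data loader aborts training if a
test-split sample is ever requested for a training batch, and augmentation
refuses test-split inputs outright.

## Synthetic data: what it emulates and what it does not

The generator renders, per sample: an ellipse with jittered geometry
(semi-axes 0.33–0.40 / 0.24–0.31 of the image side, rotation ±0.35 rad),
interior transmission glow with low-frequency shell texture, a recursive
branching vessel tree (4 trunks, depth 4, branch probability 0.85,
thickness 2.4 px decaying ×0.8 per level) drawn dark and recorded in a
ground-truth mask, sensor noise, and 8-bit quantisation. The sex signal is
set at generation time: at class effect e, females get trunk density
×(1+0.35e) and a pull of strength 0.6e toward horizontal growth; males the
mirror image. At e = 0 the class distributions are identical — the null
control trains to chance. Four quality strata mirror line conditions:
identity ("normal"), gain/offset shifts ("low-or-over-exposed"), bright
disc occluders ("bubble"), Gaussian blur ("blurry"); masks are never
altered by degradation. The default composition encodes the hatchery-scale
arithmetic: 4011 acquired, 160 unhatched excluded (unhatched samples never
receive a split), 1889 F + 1962 M, test fraction 0.2 applied as
floor(0.2 × 3851) = 770, test strata 420/120/130/100. The split is simple
random, not class-stratified.

What the generator does **not** emulate: real embryo anatomy (air cell,
embryo body, yolk shadow), breed- and shell-colour variability,
illumination non-uniformity beyond a radial glow, or the actual — unknown —
form of the sex signal in real vasculature. Passing tests therefore
demonstrate that the architecture, optimisation and evaluation machinery
work and that the model can exploit density/orientation vessel statistics;
they say nothing about accuracy on real hatchery data.

## Preprocessing and augmentation choices

Egg localisation: Otsu threshold → largest connected component → contour →
algebraic ellipse fit (moments-based fallback for degenerate contours);
deterministic. The fitted mask is dilated by 2 px before masking so
boundary egg pixels survive. "Limited adaptive contrast enhancement" is
CLAHE (normalised clip limit 0.02, 8×8 tiles), triggered only when the
interior mean < 80/255 or the interior p90–p10 spread < 30/255 — the
trigger thresholds are configuration defaults, since no operating point is
published. Grey images are replicated to three channels. Augmentation
draws each of the eight operations independently with probability 1/2:
flips, rotation ±15°, translation ±10% (zero fill, consistent with the
black background), Gaussian blur σ ∈ [0.5, 1.2], brightness ±15%, Gaussian
noise σ ∈ [0.005, 0.02], contrast ±15% about the mean.

## Evaluation

Female is the positive class everywhere (TP = females predicted female);
this choice is load-bearing for precision/recall and average precision.
Cohen's κ uses marginal-product expected agreement. Ratios with zero
denominators are reported as `None` with an `undefined` flag, never
silently zeroed. ROC is a threshold sweep with trapezoidal area — equal to
the pairwise concordance probability with ties counted ½ — and AP is
step-integrated (modern convention, not 11-point interpolation). The
activation-focus diagnostic computes Grad-CAM on the final feature stage
(the layer choice is a configuration default) and reports mean activation
over vessel-mask pixels divided by mean activation over in-egg background;
a zero background mean is flagged infinite.

## Numerical and design notes

- The autodiff engine is float32 throughout; convolution uses im2col with
  grouped einsum; softmax and cross-entropy are max-shifted for stability;
  layer norm uses ε = 1e-5.
- The softmax in the region-sharpening step runs over the channel axis —
  the only axis of a region vector.
- Directional-branch recalibration applies after the horizontal/vertical
  sum (the parallel-sum reading keeps the 6C² accounting clean); the 1×1
  recalibration's C² weights are accounted separately from the asymmetric
  pair.
- Prompt and reconstruction matrices use He initialisation with fan-in = C
  and a recorded seed.
- Checkpoints store weights, batch-norm running statistics and a config
  echo with hash verification; resuming mid-run with optimiser state is
  not supported — training runs are cheap enough at desk scale to restart.
- Problem sizes for the shipped experiments (600/200 smoke benchmark at
  64-px inputs, 120/80 null control, 128-px rendering) were chosen so a
  full cycle completes in minutes on a single CPU core.

## Open choices

- The encode/decode formula shows no activation function despite being
  described as a nonlinear mapping; it is implemented exactly as written
  (layer normalisation is the only nonlinearity). If a rectifier were
  intended inside the coder, adding one after the norm is a one-line
  change.
- Whether the MFE spatial attention was meant to run at full resolution or
  on the region grid is unspecified; it runs at region-grid resolution
  here, which is the only reading consistent with per-region gating, with
  nearest-neighbour expansion before the residual.
- The real test split's per-class composition within quality strata is
  unpublished; the fixture assigns exact stratum counts to the test split
  and proportional strata elsewhere.

## Known limitations

- No pretrained initialisation: results at the published protocol
  (lr 1e-4, 100 epochs) are not meaningful from random init and are not
  claimed.
- Real-data headline figures (92.26% accuracy, AUC 0.968, subset
  accuracies, activation ratios 7.82/4.35) belong to a private dataset and
  are not reproduced; the desk-scale numbers in `results/acceptance.json`
  are properties of the synthetic benchmark only.
- The desk-scale Grad-CAM focus ratio is reported as computed; a tiny
  model trained for minutes need not focus on vessels, and values near or
  below 1 are an honest outcome of that regime.
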
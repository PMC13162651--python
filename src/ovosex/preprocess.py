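"""Image standardisation and training-time augmentation.

Standardisation mirrors a fixed acquisition geometry: the egg is the single
bright connected region on a dark background, so it is located by Otsu
thresholding, largest-component selection and an algebraic ellipse fit to
the component contour. Pixels outside the fitted ellipse are zeroed,
contrast-limited adaptive histogram equalisation (CLAHE) is applied only to
low-brightness / low-contrast images, and the result is resized to the
model input size and scaled to [0, 1] with the grey channel replicated to
three channels.

Augmentation draws from exactly eight operations — horizontal flip,
vertical flip, rotation (+-15 deg), translation (+-10%), Gaussian blur,
brightness (+-15%), Gaussian noise, contrast variation — each applied
independently with probability 0.5, fully determined by the seed, and
refused outright for test-split samples.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, measure, transform

__all__ = [
    "EllipseFit", "NoEggFoundError", "AugmentationError", "PreprocessConfig",
    "locate_egg_ellipse", "standardize", "augment", "standardize_sample",
    "draw_augment_params", "apply_augment",
]


class NoEggFoundError(ValueError):
    pass


class AugmentationError(RuntimeError):
    pass


@dataclasses.dataclass
class PreprocessConfig:
    output_size: int = 224
    # CLAHE trigger thresholds on the egg interior, in [0,1] units
    mean_threshold: float = 80.0 / 255.0
    contrast_threshold: float = 30.0 / 255.0   # p90 - p10 spread
    clahe_clip: float = 0.02                   # normalised clip limit
    clahe_tiles: int = 8
    mask_margin_px: float = 2.0                # safety dilation of the fitted ellipse
    min_region_fraction: float = 0.05


@dataclasses.dataclass
class EllipseFit:
    """Fitted egg boundary: centre (x, y), semi-axes a >= b, rotation (rad)."""

    center: tuple[float, float]
    a: float
    b: float
    rotation: float

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise ValueError(f"ellipse requires a >= b > 0, got a={self.a}, b={self.b}")

    def mask(self, shape: tuple[int, int], margin: float = 0.0) -> np.ndarray:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
        cx, cy = self.center
        ct, st = np.cos(self.rotation), np.sin(self.rotation)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        return (xr / (self.a + margin)) ** 2 + (yr / (self.b + margin)) ** 2 <= 1.0


def _to_gray01(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim == 3 and arr.shape[0] == 3:        # [3,H,W] tensor layout
        arr = arr.mean(axis=0)
    elif arr.ndim == 3:                            # [H,W,3]
        arr = arr.mean(axis=2)
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def locate_egg_ellipse(img, config: PreprocessConfig | None = None) -> EllipseFit:
    """Fit an ellipse to the largest bright connected component's contour.

    Deterministic for a fixed image. Raises :class:`NoEggFoundError` when no
    bright region covers at least ``min_region_fraction`` of the pixels.
    """
    config = config or PreprocessConfig()
    gray = _to_gray01(img)
    if gray.max() - gray.min() < 1e-6:
        raise NoEggFoundError("no egg found: image has no contrast")
    from skimage.filters import threshold_otsu
    binary = gray > threshold_otsu(gray)
    labels, n = ndi.label(binary)
    if n == 0:
        raise NoEggFoundError("no egg found: no bright region")
    sizes = ndi.sum_labels(np.ones_like(gray), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < config.min_region_fraction * gray.size:
        raise NoEggFoundError(
            f"no egg found: largest bright region covers "
            f"{sizes[best - 1] / gray.size:.1%} < {config.min_region_fraction:.0%}")
    component = ndi.binary_fill_holes(labels == best)
    contours = measure.find_contours(component.astype(float), 0.5)
    points = max(contours, key=len)                # (row, col)
    xy = points[:, ::-1]                           # to (x, y)
    model = measure.EllipseModel.from_estimate(xy)
    if model:
        (cx, cy), (a, b), theta = model.center, model.axis_lengths, model.theta
        if a < b:
            a, b, theta = b, a, theta + np.pi / 2
    else:                                          # degenerate contour: moments fallback
        props = measure.regionprops(component.astype(int))[0]
        cy, cx = props.centroid
        a, b = props.major_axis_length / 2, props.minor_axis_length / 2
        theta = -props.orientation + np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2
    return EllipseFit(center=(float(cx), float(cy)), a=float(a), b=float(b),
                      rotation=float(theta))


def standardize(img, fit: EllipseFit,
                config: PreprocessConfig | None = None) -> np.ndarray:
    """Mask background, conditionally enhance, resize; returns [3,S,S] in [0,1]."""
    config = config or PreprocessConfig()
    gray = _to_gray01(img)
    egg = fit.mask(gray.shape, margin=config.mask_margin_px)
    interior = gray[egg]
    if interior.size:
        mean = float(interior.mean())
        contrast = float(np.percentile(interior, 90) - np.percentile(interior, 10))
        if mean < config.mean_threshold or contrast < config.contrast_threshold:
            kernel = max(8, gray.shape[0] // config.clahe_tiles)
            gray = exposure.equalize_adapthist(
                np.clip(gray, 0, 1), kernel_size=kernel, clip_limit=config.clahe_clip)
    gray = gray * egg
    if gray.shape != (config.output_size, config.output_size):
        gray = transform.resize(gray, (config.output_size, config.output_size),
                                anti_aliasing=True, preserve_range=True)
        # resampling can bleed across the mask edge; re-zero the background
        small_egg = transform.resize(egg.astype(float),
                                     (config.output_size, config.output_size),
                                     anti_aliasing=False) > 0.5
        gray = gray * small_egg
    gray = np.clip(gray, 0.0, 1.0).astype(np.float32)
    return np.repeat(gray[None], 3, axis=0)


def standardize_sample(img, config: PreprocessConfig | None = None) -> np.ndarray:
    """Locate the egg and standardise in one call."""
    return standardize(img, locate_egg_ellipse(img, config), config)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

ROTATION_DEG = 15.0
TRANSLATE_FRAC = 0.10
BRIGHTNESS_FRAC = 0.15
CONTRAST_FRAC = 0.15


def draw_augment_params(rng: np.random.Generator) -> dict:
    """Draw one augmentation configuration from the eight listed operations.

    Each operation is applied independently with probability 1/2 and its
    parameter sampled within the stated range; absent keys mean "skip".
    """
    params = {}
    if rng.random() < 0.5:
        params["hflip"] = True
    if rng.random() < 0.5:
        params["vflip"] = True
    if rng.random() < 0.5:
        params["rotation_deg"] = rng.uniform(-ROTATION_DEG, ROTATION_DEG)
    if rng.random() < 0.5:
        params["translate"] = (rng.uniform(-TRANSLATE_FRAC, TRANSLATE_FRAC),
                               rng.uniform(-TRANSLATE_FRAC, TRANSLATE_FRAC))
    if rng.random() < 0.5:
        params["blur_sigma"] = rng.uniform(0.5, 1.2)
    if rng.random() < 0.5:
        params["brightness"] = rng.uniform(1 - BRIGHTNESS_FRAC, 1 + BRIGHTNESS_FRAC)
    if rng.random() < 0.5:
        params["noise_sigma"] = rng.uniform(0.005, 0.02)
        params["noise_seed"] = int(rng.integers(0, 2**31 - 1))
    if rng.random() < 0.5:
        params["contrast"] = rng.uniform(1 - CONTRAST_FRAC, 1 + CONTRAST_FRAC)
    return params


def apply_augment(chan: np.ndarray, params: dict) -> np.ndarray:
    """Apply a drawn augmentation configuration to one [H,W] channel."""
    chan = chan.astype(np.float64)
    if params.get("hflip"):
        chan = chan[:, ::-1]
    if params.get("vflip"):
        chan = chan[::-1, :]
    if "rotation_deg" in params:
        chan = transform.rotate(chan, params["rotation_deg"],
                                mode="constant", cval=0.0)
    if "translate" in params:
        S = chan.shape[0]
        dx, dy = params["translate"]
        chan = ndi.shift(chan, (dy * S, dx * S), order=1, mode="constant", cval=0.0)
    if "blur_sigma" in params:
        chan = ndi.gaussian_filter(chan, params["blur_sigma"])
    if "brightness" in params:
        chan = chan * params["brightness"]
    if "noise_sigma" in params:
        noise_rng = np.random.default_rng(params["noise_seed"])
        chan = chan + noise_rng.normal(0, params["noise_sigma"], chan.shape)
    if "contrast" in params:
        chan = (chan - chan.mean()) * params["contrast"] + chan.mean()
    return np.clip(chan, 0.0, 1.0)


def augment(img: np.ndarray, seed: int, split: str = "train") -> np.ndarray:
    """Seeded random augmentation of a standardised [3,S,S] image.

    Only training samples may be augmented; passing ``split='test'`` raises
    :class:`AugmentationError`. The same seed always yields bit-identical
    output, and labels/quality tags are untouched (they live in the
    manifest, not the pixels).
    """
    if split != "train":
        raise AugmentationError(
            f"augmentation is restricted to the training split (got split={split!r})")
    rng = np.random.default_rng(seed)
    x = np.asarray(img, dtype=np.float32)
    chan = apply_augment(x[0], draw_augment_params(rng))
    return np.repeat(chan[None].astype(np.float32), 3, axis=0)
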
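"""Synthetic candled-egg image generator with ground-truth vessel masks.

No public dataset of day-4 transmission-candling embryo images exists, so
this module renders a controllable stand-in: a bright, shell-textured
elliptical egg on a near-black background, carrying a recursive branching
vessel tree drawn as thin dark curves. Every sample records its vessel
mask, sex label, hatched flag, quality stratum and generation seed.

The sex signal is injected at generation time (never post-hoc) as two small
class-dependent shifts, scaled by a single ``class_effect`` knob in [0,1]:

* **vessel density** — females receive proportionally more trunk vessels,
  males fewer;
* **orientation anisotropy** — female trees are pulled toward horizontal
  growth, male trees toward vertical.

At ``class_effect = 0`` the two classes are drawn from identical
distributions. Four quality strata mirror the degradations seen on a real
candling line: ``normal``, ``low-or-over-exposed``, ``bubble`` (bright disc
occluders) and ``blurry``.

The default, hatchery-scale dataset composition: 4011
acquired samples of which 160 unhatched are excluded, leaving 1889 female +
1962 male hatched samples; a 20% held-out split of 3851 gives 770 test /
3081 train, and the test set carries quality strata of 420/120/130/100.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

__all__ = [
    "GeneratorParams", "EggSample", "DatasetComposition", "PAPER_COMPOSITION",
    "STRATA", "render_egg", "degrade", "generate_dataset", "split_dataset",
    "feather_sex_label", "consensus_label", "generate_arrays",
]

#: quality strata in reporting order
STRATA = ("normal", "low-or-over-exposed", "bubble", "blurry")

#: feathering threshold: wing must exceed coverts by MORE than this (mm)
FEATHER_THRESHOLD_MM = 2.00


@dataclasses.dataclass
class GeneratorParams:
    """Rendering parameters; defaults emulate day-4 candling imagery."""

    image_size: int = 256
    # ellipse geometry as fractions of image size
    semi_major_range: tuple[float, float] = (0.33, 0.40)
    semi_minor_range: tuple[float, float] = (0.24, 0.31)
    rotation_range: tuple[float, float] = (-0.35, 0.35)
    center_jitter: float = 0.03
    # vessel tree
    base_trunks: int = 4
    branch_depth: int = 4
    branch_prob: float = 0.85
    branch_spread: float = 0.9        # radians between child branches
    step_frac: float = 0.045          # segment step length / image size
    wiggle: float = 0.25              # per-step angular jitter (rad)
    thickness_px: float = 2.4
    thickness_decay: float = 0.8
    vessel_contrast: float = 0.35
    # class signal
    class_effect: float = 0.6
    density_shift: float = 0.35       # relative trunk-count shift at effect 1
    anisotropy: float = 0.6           # orientation pull strength at effect 1
    # appearance
    interior_brightness: float = 0.55
    glow: float = 0.25
    shell_texture_amp: float = 0.06
    background_level: float = 0.02
    noise_sigma: float = 0.012

    def validate(self) -> None:
        a_min = self.semi_major_range[0] * self.image_size
        b_min = self.semi_minor_range[0] * self.image_size
        if min(a_min, b_min) < 10:
            raise ValueError(
                f"degenerate egg geometry: semi-axis {min(a_min, b_min):.1f} px < 10 px")


@dataclasses.dataclass
class EggSample:
    image: np.ndarray                 # uint8 [H,W]
    vessel_mask: np.ndarray           # bool  [H,W]
    label: str                        # 'F' | 'M'
    hatched: bool
    quality: str
    seed: int


@dataclasses.dataclass
class DatasetComposition:
    """Per-class / per-stratum sample counts for one generated dataset."""

    females: int
    males: int
    unhatched: int = 0
    test_fraction: float = 0.2
    test_strata: tuple[int, int, int, int] | None = None

    @property
    def hatched(self) -> int:
        return self.females + self.males

    @property
    def total(self) -> int:
        return self.hatched + self.unhatched

    def validate(self) -> None:
        if min(self.females, self.males, self.unhatched) < 0:
            raise ValueError("composition counts must be non-negative")
        if self.test_strata is not None:
            n_test = int(self.test_fraction * self.hatched)
            if sum(self.test_strata) != n_test:
                raise ValueError(
                    f"test strata sum {sum(self.test_strata)} != test size "
                    f"{n_test} (= floor({self.test_fraction} x {self.hatched}))")


#: the hatchery-scale fixture: 4011 total, 160 unhatched, 1889 F + 1962 M,
#: test strata 420/120/130/100
PAPER_COMPOSITION = DatasetComposition(
    females=1889, males=1962, unhatched=160,
    test_fraction=0.2, test_strata=(420, 120, 130, 100))


# ---------------------------------------------------------------------------
# Label rules
# ---------------------------------------------------------------------------


def feather_sex_label(wing_mm: float, covert_mm: float) -> str:
    """Fast/slow-feathering sexing: F iff wing exceeds coverts by > 2.00 mm.

    The inequality is strict: a difference of exactly 2.00 mm is judged
    slow-feathering (male).
    """
    if wing_mm < 0 or covert_mm < 0:
        raise ValueError(f"feather lengths must be non-negative: {wing_mm}, {covert_mm}")
    return "F" if (wing_mm - covert_mm) > FEATHER_THRESHOLD_MM else "M"


def consensus_label(a: str, b: str) -> str:
    """Dual-annotator consensus: the common label, else 'excluded'."""
    return a if a == b else "excluded"


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    field = rng.standard_normal((size, size))
    field = ndi.gaussian_filter(field, sigma)
    return field / (np.abs(field).max() + 1e-9)


def _grow_tree(rng, params: GeneratorParams, interior, cx, cy, label: str):
    """Random recursive branching walk; returns line segments per depth."""
    S = params.image_size
    effect = params.class_effect
    sign = 1.0 if label == "F" else -1.0
    trunks = max(1, int(round(params.base_trunks * (1.0 + sign * params.density_shift * effect))))
    pref = 0.0 if label == "F" else math.pi / 2      # preferred growth axis
    pull = params.anisotropy * effect
    step = params.step_frac * S
    segments: dict[int, list] = {d: [] for d in range(params.branch_depth + 1)}

    # embryo focus: vessel origin near the egg centre
    ox = cx + rng.normal(0, 0.04 * S)
    oy = cy + rng.normal(0, 0.04 * S)

    stack = [(ox, oy, rng.uniform(0, 2 * math.pi), 0) for _ in range(trunks)]
    while stack:
        x, y, ang, depth = stack.pop()
        n_steps = int(rng.integers(4, 9))
        alive = True
        for _ in range(n_steps):
            ang += rng.normal(0, params.wiggle)
            # pull toward the class-preferred axis (period pi: axis, not direction)
            ang += 0.5 * pull * math.sin(2.0 * (pref - ang))
            nx, ny = x + step * math.cos(ang), y + step * math.sin(ang)
            if not interior(nx, ny):
                alive = False
                break
            segments[depth].append((x, y, nx, ny))
            x, y = nx, ny
        if alive and depth < params.branch_depth:
            for s in (-1.0, 1.0):
                if rng.random() < params.branch_prob:
                    child = ang + s * params.branch_spread * rng.uniform(0.5, 1.1)
                    stack.append((x, y, child, depth + 1))
    return segments


def _rasterize(segments: dict, params: GeneratorParams) -> np.ndarray:
    S = params.image_size
    mask = np.zeros((S, S), dtype=bool)
    for depth, segs in segments.items():
        if not segs:
            continue
        level = np.zeros((S, S), dtype=bool)
        for x0, y0, x1, y1 in segs:
            rr, cc = draw_line(int(round(y0)), int(round(x0)),
                               int(round(y1)), int(round(x1)))
            ok = (rr >= 0) & (rr < S) & (cc >= 0) & (cc < S)
            level[rr[ok], cc[ok]] = True
        t = params.thickness_px * params.thickness_decay ** depth
        r = int(round(t / 2))
        if r >= 1:
            level = ndi.binary_dilation(level, iterations=r)
        mask |= level
    return mask


def render_egg(params: GeneratorParams, seed: int, label: str | None = None,
               hatched: bool = True) -> EggSample:
    """Render one candled egg; deterministic for a fixed (params, seed)."""
    params.validate()
    rng = np.random.default_rng(seed)
    S = params.image_size
    if label is None:
        label = "F" if rng.random() < 0.5 else "M"

    a = rng.uniform(*params.semi_major_range) * S
    b = rng.uniform(*params.semi_minor_range) * S
    a, b = max(a, b), min(a, b)
    rot = rng.uniform(*params.rotation_range)
    cx = S / 2 + rng.normal(0, params.center_jitter * S)
    cy = S / 2 + rng.normal(0, params.center_jitter * S)

    yy, xx = np.mgrid[0:S, 0:S].astype(np.float64)
    ct, st = math.cos(rot), math.sin(rot)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    r2 = (xr / a) ** 2 + (yr / b) ** 2
    interior_mask = r2 <= 1.0

    def interior(px, py):
        prx = (px - cx) * ct + (py - cy) * st
        pry = -(px - cx) * st + (py - cy) * ct
        return (prx / a) ** 2 + (pry / b) ** 2 <= 0.92   # keep vessels off the rim

    img = np.full((S, S), params.background_level, dtype=np.float64)
    glow = params.interior_brightness + params.glow * (1.0 - r2)
    img[interior_mask] = glow[interior_mask]
    img += params.shell_texture_amp * _smooth_noise(rng, S, S / 32) * interior_mask

    segments = _grow_tree(rng, params, interior, cx, cy, label)
    vessel = _rasterize(segments, params) & interior_mask
    soft = ndi.gaussian_filter(vessel.astype(np.float64), 0.6)
    img -= params.vessel_contrast * soft

    img += rng.normal(0, params.noise_sigma, (S, S))
    img = np.clip(img, 0.0, 1.0)
    return EggSample(image=(img * 255).round().astype(np.uint8),
                     vessel_mask=vessel, label=label, hatched=hatched,
                     quality="normal", seed=int(seed))


def degrade(sample: EggSample, stratum: str, seed: int) -> EggSample:
    """Apply one quality stratum's corruption; vessel mask is unchanged."""
    if stratum not in STRATA:
        raise ValueError(f"unknown quality stratum {stratum!r}; expected one of {STRATA}")
    if stratum == "normal":
        return dataclasses.replace(sample, quality="normal")
    rng = np.random.default_rng(seed)
    img = sample.image.astype(np.float64) / 255.0
    if stratum == "low-or-over-exposed":
        if rng.random() < 0.5:
            img = img * rng.uniform(0.40, 0.60)                 # under-exposed
        else:
            img = img * rng.uniform(1.6, 2.0) + rng.uniform(0.05, 0.15)
    elif stratum == "bubble":
        S = img.shape[0]
        bright = np.argwhere(img > 0.35)
        n_bubbles = int(rng.integers(1, 4))
        yy, xx = np.mgrid[0:S, 0:S]
        for _ in range(n_bubbles):
            cy, cx = bright[rng.integers(len(bright))]
            r = rng.uniform(0.03, 0.07) * S
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            img[disc] = rng.uniform(0.85, 0.98)
    elif stratum == "blurry":
        img = ndi.gaussian_filter(img, rng.uniform(1.5, 2.5))
    img = np.clip(img, 0.0, 1.0)
    return dataclasses.replace(sample, image=(img * 255).round().astype(np.uint8),
                               quality=stratum)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def split_dataset(manifest: pd.DataFrame, test_fraction: float,
                  seed: int) -> pd.DataFrame:
    """Assign a train/test split to hatched samples only.

    Test size is floor(test_fraction x N_hatched); assignment is a seeded
    random permutation, disjoint and exhaustive over hatched rows. Unhatched
    rows are marked ``excluded`` and never enter a split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0,1), got {test_fraction}")
    manifest = manifest.copy()
    hatched_idx = manifest.index[manifest["hatched"].astype(bool)].to_numpy()
    n_test = int(test_fraction * len(hatched_idx))
    order = np.random.default_rng(seed).permutation(len(hatched_idx))
    manifest["split"] = "excluded"
    manifest.loc[hatched_idx[order[:n_test]], "split"] = "test"
    manifest.loc[hatched_idx[order[n_test:]], "split"] = "train"
    return manifest


def _assign_strata(manifest: pd.DataFrame, comp: DatasetComposition,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Exact stratum counts in the test split; proportional elsewhere."""
    manifest = manifest.copy()
    manifest["quality"] = "normal"
    test_idx = manifest.index[manifest["split"] == "test"].to_numpy()
    counts = comp.test_strata or (len(test_idx), 0, 0, 0)
    order = rng.permutation(len(test_idx))
    pos = 0
    for stratum, n in zip(STRATA, counts):
        manifest.loc[test_idx[order[pos:pos + n]], "quality"] = stratum
        pos += n
    probs = np.asarray(counts, dtype=float)
    probs = probs / probs.sum() if probs.sum() else np.array([1.0, 0, 0, 0])
    other_idx = manifest.index[manifest["split"] != "test"]
    manifest.loc[other_idx, "quality"] = rng.choice(STRATA, size=len(other_idx), p=probs)
    return manifest


def generate_dataset(params: GeneratorParams,
                     composition: DatasetComposition = PAPER_COMPOSITION,
                     seed: int = 0, out_dir=None,
                     manifest_only: bool = False) -> pd.DataFrame:
    """Build a dataset manifest (and optionally render + write its images).

    Returns a manifest with columns ``path, label, hatched, quality, split,
    sample_seed``. With ``manifest_only=True`` no pixels are rendered —
    useful for bookkeeping checks at hatchery scale. Otherwise images and
    vessel masks are written as PNGs under ``out_dir``.
    """
    composition.validate()
    rng = np.random.default_rng(seed)
    rows = []
    labels = ["F"] * composition.females + ["M"] * composition.males
    hatched_flags = [True] * composition.hatched + [False] * composition.unhatched
    # unhatched eggs still get a generated (unverifiable) ground-truth sex
    labels += ["F" if rng.random() < 0.5 else "M" for _ in range(composition.unhatched)]
    order = rng.permutation(composition.total)
    sample_seeds = rng.integers(0, 2**31 - 1, size=composition.total)
    for i, j in enumerate(order):
        rows.append({"path": f"egg_{i:05d}.png", "label": labels[j],
                     "hatched": bool(hatched_flags[j]),
                     "sample_seed": int(sample_seeds[i])})
    manifest = pd.DataFrame(rows)
    manifest = split_dataset(manifest, composition.test_fraction, seed=seed + 1)
    manifest = _assign_strata(manifest, composition, rng)

    if not manifest_only:
        if out_dir is None:
            raise ValueError("out_dir is required unless manifest_only=True")
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)
        from PIL import Image
        for row in manifest.itertuples():
            sample = render_egg(params, row.sample_seed, label=row.label,
                                hatched=row.hatched)
            sample = degrade(sample, row.quality, seed=row.sample_seed + 1)
            Image.fromarray(sample.image).save(out_dir / "images" / row.path)
            Image.fromarray(sample.vessel_mask.astype(np.uint8) * 255).save(
                out_dir / "masks" / row.path)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def generate_arrays(n_per_class: int, params: GeneratorParams, seed: int,
                    strata: bool = False):
    """In-memory balanced sample list for experiments and tests."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2 * n_per_class)
    samples = []
    for i, s in enumerate(seeds):
        label = "F" if i < n_per_class else "M"
        sample = render_egg(params, int(s), label=label)
        if strata:
            stratum = STRATA[int(rng.integers(0, 4))]
            sample = degrade(sample, stratum, seed=int(s) + 1)
        samples.append(sample)
    order = rng.permutation(len(samples))
    return [samples[i] for i in order]
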
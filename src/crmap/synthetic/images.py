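"""Synthetic 7-class "modality-like" image generator.

Each class has a class-consistent discriminative structure at a known,
randomized location, embedded in background clutter shared by all classes.
The structure's footprint is returned as a ground-truth boolean mask so
localization claims can be tested without human annotation.

Class recipes (grayscale, pixels in [0, 1]):

0. elliptical ring with interior blobs (CT-like)
1. two concentric ellipses, bright shell around a darker core (MRI-like)
2. bright sector/fan radiating from a top apex (ultrasound-like)
3. bright rounded frame with two dark side-by-side lobes (chest-X-ray-like)
4. random bright speckles on a dark field (fluorescence-like)
5. large dim disc with a small bright off-center disc whose side is
   randomized (fundus-like; the mask is the small disc only)
6. two perpendicular axis lines plus a polyline (statistical-graph-like)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from PIL import Image

from ..errors import InvalidInputError

__all__ = [
    "CLASS_NAMES",
    "SyntheticImage",
    "GeneratorConfig",
    "Dataset",
    "generate_class_image",
    "generate_dataset",
]

CLASS_NAMES = (
    "ct_like",
    "mri_like",
    "ultrasound_like",
    "xray_like",
    "fluorescence_like",
    "fundus_like",
    "graph_like",
)

NUM_CLASSES = len(CLASS_NAMES)

#: ground-truth mask must occupy this fraction range of the image
MASK_AREA_RANGE = (0.02, 0.60)

SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class SyntheticImage:
    """One generated image with its label and ground-truth object mask."""

    pixels: np.ndarray
    class_label: int
    object_mask: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        mask = np.asarray(self.object_mask, dtype=bool)
        if px.ndim != 2 or px.shape != mask.shape:
            raise InvalidInputError("pixels and mask must be same-shape 2-D arrays")
        if px.min() < 0 or px.max() > 1:
            raise InvalidInputError("pixels must lie in [0, 1]")
        if not 0 <= self.class_label < NUM_CLASSES:
            raise InvalidInputError(f"class_label must be in [0, {NUM_CLASSES})")
        area = mask.mean()
        lo, hi = MASK_AREA_RANGE
        if not lo <= area <= hi:
            raise InvalidInputError(
                f"mask area fraction {area:.4f} outside [{lo}, {hi}]"
            )
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "object_mask", mask)


@dataclass(frozen=True)
class GeneratorConfig:
    """Dataset recipe: per-split class counts, image size, clutter level and
    train-time augmentation ranges (degrees / pixels)."""

    images_per_class: dict = field(
        default_factory=lambda: {"train": 30, "val": 8, "test": 20}
    )
    image_size: int = 64
    noise: float = 0.05
    rotation_range: float = 5.0
    shift_range: int = 3
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(s not in SPLITS for s in self.images_per_class):
            raise InvalidInputError(f"splits must be a subset of {SPLITS}")
        if any(n < 0 for n in self.images_per_class.values()):
            raise InvalidInputError("per-split counts must be non-negative")
        if sum(self.images_per_class.values()) == 0:
            raise InvalidInputError("at least one image must be requested")
        if self.image_size < 32:
            raise InvalidInputError("image_size must be >= 32")


# ---------------------------------------------------------------------------
# drawing primitives


def _grid(size: int):
    return np.ogrid[0:size, 0:size]


def _disc(size: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = _grid(size)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _ellipse(size: int, cy: float, cx: float, ry: float, rx: float, angle: float = 0.0) -> np.ndarray:
    yy, xx = _grid(size)
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    ey = dy * ca - dx * sa
    ex = dy * sa + dx * ca
    return (ey / ry) ** 2 + (ex / rx) ** 2 <= 1.0


def _line(size: int, r0: float, c0: float, r1: float, c1: float) -> np.ndarray:
    """1-pixel line rasterized by dense sampling."""
    n = int(max(abs(r1 - r0), abs(c1 - c0)) * 2) + 2
    rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, size - 1)
    cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, size - 1)
    canvas = np.zeros((size, size), dtype=bool)
    canvas[rr, cc] = True
    return canvas


def _clutter(size: int, rng: np.random.Generator):
    """Background clutter common to every class.

    Includes one large dim disc in every image so a plain disc carries no
    class information: class 5 is then identified only by the small bright
    disc it places inside that shared body, not by a disc shape.  Returns
    the clutter layer and the dim disc's ``(cy, cx, r)``.
    """
    out = np.zeros((size, size))
    cy, cx = rng.uniform(0.40, 0.60, size=2) * size
    r = rng.uniform(0.24, 0.34) * size
    out[_disc(size, cy, cx, r)] += rng.uniform(0.12, 0.20)
    for _ in range(rng.integers(2, 5)):
        by, bx = rng.uniform(4, size - 4, size=2)
        out[_disc(size, by, bx, rng.uniform(0.05, 0.11) * size)] += rng.uniform(0.04, 0.10)
    return out, (cy, cx, r)


# ---------------------------------------------------------------------------
# class recipes (each returns foreground layer and object mask)


def _recipe_ct(size, rng):
    t = size
    cy = 0.5 * t + rng.uniform(-3, 3)
    cx = 0.5 * t + rng.uniform(-3, 3)
    ry = rng.uniform(0.26, 0.33) * t
    rx = rng.uniform(0.31, 0.40) * t
    outer = _ellipse(size, cy, cx, ry, rx)
    inner = _ellipse(size, cy, cx, 0.74 * ry, 0.74 * rx)
    fg = np.zeros((size, size))
    fg[outer & ~inner] = 0.78
    for _ in range(rng.integers(3, 6)):
        by = cy + rng.uniform(-0.4, 0.4) * ry
        bx = cx + rng.uniform(-0.4, 0.4) * rx
        fg[_disc(size, by, bx, rng.uniform(0.03, 0.06) * t)] = rng.uniform(0.45, 0.65)
    return fg, outer


def _recipe_mri(size, rng):
    t = size
    cy = 0.5 * t + rng.uniform(-3, 3)
    cx = 0.5 * t + rng.uniform(-3, 3)
    ry = rng.uniform(0.26, 0.32) * t
    rx = rng.uniform(0.19, 0.24) * t
    ang = rng.uniform(-0.25, 0.25)
    outer = _ellipse(size, cy, cx, ry, rx, ang)
    core = _ellipse(size, cy, cx, 0.60 * ry, 0.60 * rx, ang)
    fg = np.zeros((size, size))
    fg[outer] = 0.70
    fg[core] = 0.30
    # ventricle-like dark slits inside the core
    for s in (-1, 1):
        fg[_ellipse(size, cy, cx + s * 0.22 * rx, 0.32 * ry, 0.12 * rx, ang)] = 0.10
    return fg, outer


def _recipe_ultrasound(size, rng):
    t = size
    ay = rng.uniform(1, 4)
    ax = 0.5 * t + rng.uniform(-4, 4)
    half = np.deg2rad(rng.uniform(24, 34))
    tilt = np.deg2rad(rng.uniform(-10, 10))
    radius = rng.uniform(0.58, 0.75) * t
    yy, xx = _grid(size)
    dy, dx = yy - ay, xx - ax
    rr = np.hypot(dy, dx)
    ang = np.arctan2(dx, dy)  # 0 points straight down the rows
    sector = (rr <= radius) & (rr >= 0.08 * t) & (np.abs(ang - tilt) <= half)
    fg = np.zeros((size, size))
    speckle = rng.uniform(0.35, 0.85, size=(size, size))
    fg[sector] = speckle[sector]
    mask = ndimage.binary_dilation(sector, iterations=3)
    return fg, mask


def _recipe_xray(size, rng):
    t = size
    r0 = int(0.14 * t + rng.uniform(-2, 2))
    r1 = int(0.86 * t + rng.uniform(-2, 2))
    c0 = int(0.20 * t + rng.uniform(-2, 2))
    c1 = int(0.80 * t + rng.uniform(-2, 2))
    frame = np.zeros((size, size), dtype=bool)
    frame[r0:r1, c0:c1] = True
    # round the corners
    frame &= _ellipse(size, (r0 + r1) / 2, (c0 + c1) / 2, 0.62 * (r1 - r0), 0.62 * (c1 - c0))
    fg = np.zeros((size, size))
    fg[frame] = 0.72
    lobe_ry = 0.22 * t
    lobe_rx = 0.12 * t
    lcy = (r0 + r1) / 2 + rng.uniform(-1.5, 1.5)
    for s in (-1, 1):
        lcx = (c0 + c1) / 2 + s * 0.16 * t + rng.uniform(-1.5, 1.5)
        fg[_ellipse(size, lcy, lcx, lobe_ry, lobe_rx) & frame] = 0.18
    return fg, frame


def _recipe_fluorescence(size, rng):
    t = size
    fg = np.zeros((size, size))
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(rng.integers(5, 10)):
        cy, cx = rng.uniform(5, size - 5, size=2)
        r = rng.uniform(2.0, 4.0) * t / 64
        spot = _disc(size, cy, cx, r)
        fg[spot] = rng.uniform(0.72, 1.0)
        mask |= spot
    # generous halo: localization is judged at coarse feature-map resolution
    mask = ndimage.binary_dilation(mask, iterations=3)
    return fg, mask


def _recipe_fundus(size, rng, body):
    """Only the small bright disc is drawn; the dim fundus body is the
    clutter disc every class already has, so the bright disc alone is
    discriminative (its side is randomized)."""
    t = size
    cy, cx, r = body
    side = rng.choice([-1, 1])  # optic-disc analogue lands on either half
    sy = cy + rng.uniform(-0.25, 0.25) * r
    sx = cx + side * rng.uniform(0.45, 0.65) * r
    small = _disc(size, sy, sx, rng.uniform(0.088, 0.10) * t)
    fg = np.zeros((size, size))
    fg[small] = 0.95
    mask = ndimage.binary_dilation(small, iterations=3)
    return fg, mask


def _recipe_graph(size, rng):
    t = size
    x0 = int(rng.uniform(0.09, 0.16) * t)
    y0 = int(rng.uniform(0.84, 0.91) * t)
    lines = _line(size, int(0.08 * t), x0, y0, x0) | _line(size, y0, x0, y0, int(0.92 * t))
    n_pts = 6
    cols = np.linspace(x0 + 3, 0.9 * t, n_pts)
    rows = rng.uniform(0.12 * t, y0 - 3, size=n_pts)
    for i in range(n_pts - 1):
        lines |= _line(size, rows[i], cols[i], rows[i + 1], cols[i + 1])
    fg = np.zeros((size, size))
    mask = ndimage.binary_dilation(lines, iterations=4)
    fg[ndimage.binary_dilation(lines, iterations=1)] = 0.85
    return fg, mask


_RECIPES = (
    _recipe_ct,
    _recipe_mri,
    _recipe_ultrasound,
    _recipe_xray,
    _recipe_fluorescence,
    _recipe_fundus,
    _recipe_graph,
)


def generate_class_image(
    class_label: int, seed: int, size: int = 64, noise: float = 0.05
) -> SyntheticImage:
    """Deterministically generate one image for ``(class_label, seed)``."""
    if not 0 <= int(class_label) < NUM_CLASSES:
        raise IndexError(f"class label {class_label} out of range [0, {NUM_CLASSES})")
    rng = np.random.default_rng([int(seed), int(class_label), 911])
    clutter, body = _clutter(size, rng)
    base = rng.uniform(0.05, 0.10) + clutter
    recipe = _RECIPES[int(class_label)]
    if recipe is _recipe_fundus:
        fg, mask = recipe(size, rng, body)
    else:
        fg, mask = recipe(size, rng)
    pixels = np.where(fg > 0, fg, base)
    pixels = pixels + rng.normal(0.0, noise, size=(size, size))
    pixels = np.clip(pixels, 0.0, 1.0)
    return SyntheticImage(pixels, int(class_label), mask, int(seed))


def _augment(
    img: SyntheticImage, rng: np.random.Generator, rotation_range: float, shift_range: int
) -> SyntheticImage:
    """Small random rotation and shift, applied identically to pixels and mask."""
    angle = rng.uniform(-rotation_range, rotation_range)
    dy, dx = rng.integers(-shift_range, shift_range + 1, size=2)
    px = ndimage.rotate(img.pixels, angle, reshape=False, order=1, mode="nearest")
    px = ndimage.shift(px, (dy, dx), order=1, mode="nearest")
    mask = ndimage.rotate(img.object_mask.astype(float), angle, reshape=False, order=0, mode="nearest")
    mask = ndimage.shift(mask, (dy, dx), order=0, mode="nearest") > 0.5
    return SyntheticImage(np.clip(px, 0, 1), img.class_label, mask, img.seed)


@dataclass
class Dataset:
    """In-memory dataset with named splits and a reproducible manifest."""

    splits: dict
    config: GeneratorConfig

    def manifest(self) -> pd.DataFrame:
        rows = []
        for split, images in self.splits.items():
            for img in images:
                rows.append(
                    {
                        "path": f"{split}/class{img.class_label}_seed{img.seed}.png",
                        "class": img.class_label,
                        "split": split,
                        "seed": img.seed,
                    }
                )
        return pd.DataFrame(rows, columns=["path", "class", "split", "seed"])

    def save(self, out_dir) -> Path:
        """Write PNGs plus ``manifest.csv``; returns the manifest path."""
        out = Path(out_dir)
        for split, images in self.splits.items():
            (out / split).mkdir(parents=True, exist_ok=True)
            for img in images:
                arr = (img.pixels * 255).round().astype(np.uint8)
                Image.fromarray(arr, mode="L").save(
                    out / split / f"class{img.class_label}_seed{img.seed}.png"
                )
                np.savetxt(
                    out / split / f"class{img.class_label}_seed{img.seed}_mask.txt",
                    img.object_mask.astype(int), fmt="%d",
                )
        manifest_path = out / "manifest.csv"
        self.manifest().to_csv(manifest_path, index=False)
        return manifest_path


def generate_dataset(cfg: GeneratorConfig) -> Dataset:
    """Generate disjoint train/val/test splits from one master seed.

    Per-image seeds are derived from ``(master_seed, split, class, index)``
    so no image can appear in two splits.  Train images additionally receive
    a small random rotation and shift.
    """
    aug_rng = np.random.default_rng([cfg.master_seed, 7919])
    splits: dict[str, list[SyntheticImage]] = {}
    for split_idx, split in enumerate(SPLITS):
        n = cfg.images_per_class.get(split, 0)
        images = []
        for c in range(NUM_CLASSES):
            for i in range(n):
                seed = (
                    cfg.master_seed * 1_000_003
                    + split_idx * 100_000
                    + c * 10_000
                    + i
                )
                img = generate_class_image(c, seed, size=cfg.image_size, noise=cfg.noise)
                if split == "train":
                    img = _augment(img, aug_rng, cfg.rotation_range, cfg.shift_range)
                images.append(img)
        splits[split] = images
    return Dataset(splits=splits, config=cfg)
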
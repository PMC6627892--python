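"""Heatmap post-processing: normalization, thresholding, upsampling, overlays
and class-level ROI bounding boxes.

The rendering pipeline is: normalize the raw map at feature-map resolution,
upsample to input resolution, threshold relative to the max.  Relative
thresholds make every product invariant to positive rescaling of the raw map
(and hence to the GAP sum-vs-mean convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Union

import numpy as np
from PIL import Image
from skimage.transform import resize

from .errors import ContractViolationError, EmptyROIError, InvalidInputError
from .mapping import ActivationMap, AverageMap

__all__ = [
    "NormalizedMap",
    "ROIMask",
    "BoundingBox",
    "normalize_map",
    "threshold_map",
    "upsample_map",
    "render_overlay",
    "class_roi_bbox",
    "save_grayscale_png",
    "save_mask_png",
    "save_heatmap_png",
    "save_rgb_png",
]


@dataclass(frozen=True)
class NormalizedMap:
    """A saliency map rescaled to ``[0, 1]``.

    Max value is 1 unless the map is identically zero.  Rendered to
    ``[0, 255]`` only at PNG-writing time.
    """

    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError(f"map must be 2-D, got shape {arr.shape}")
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise InvalidInputError("normalized values must lie in [0, 1]")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ROIMask:
    """Boolean mask of pixels exceeding a fraction of the map maximum."""

    values: np.ndarray
    threshold_fraction: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=bool)
        if arr.ndim != 2:
            raise InvalidInputError(f"mask must be 2-D, got shape {arr.shape}")
        object.__setattr__(self, "values", arr)

    @property
    def resolution(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def pixel_count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with 0-based inclusive pixel coordinates."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise InvalidInputError("bounding box must have min <= max on both axes")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min + 1

    @property
    def width(self) -> int:
        return self.col_max - self.col_min + 1

    def as_dict(self) -> dict:
        return {
            "row_min": self.row_min,
            "row_max": self.row_max,
            "col_min": self.col_min,
            "col_max": self.col_max,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict())


MapLike = Union[ActivationMap, AverageMap, NormalizedMap]


def _map_values_and_method(m: MapLike) -> tuple[np.ndarray, str]:
    if isinstance(m, (ActivationMap, AverageMap, NormalizedMap)):
        return m.values, m.method
    raise InvalidInputError(f"expected a map object, got {type(m).__name__}")


def normalize_map(m: MapLike) -> NormalizedMap:
    """Rescale a map to ``[0, 1]`` by its maximum.

    CAM maps may carry negative values; those are clipped to 0 first since
    only high-score regions are displayed.  CRM/Grad-CAM maps are already
    non-negative so clipping is a no-op and max- and min-max-normalization
    coincide.  An identically-zero map is returned unchanged (no division).
    Idempotent.
    """
    values, method = _map_values_and_method(m)
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("map values must be finite")
    clipped = np.maximum(values, 0.0)
    peak = clipped.max() if clipped.size else 0.0
    if peak > 0:
        clipped = clipped / peak
    return NormalizedMap(clipped, method=method)


def threshold_map(nm: NormalizedMap, fraction: float = 0.2) -> ROIMask:
    """Mask of pixels *strictly* above ``fraction`` of the max score.

    The paper-style display rule "above 20% of the max" with ``fraction``
    in the open interval (0, 1); ties at exactly the threshold are excluded.
    """
    fraction = float(fraction)
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"threshold fraction must be in (0, 1), got {fraction}")
    return ROIMask(nm.values > fraction, threshold_fraction=fraction)


def upsample_map(
    nm: NormalizedMap, target: tuple[int, int], mode: str = "bilinear"
) -> NormalizedMap:
    """Interpolate a normalized map up to ``target = (height, width)``.

    ``mode`` is ``"bilinear"`` (default) or ``"nearest"``.  Output values are
    clipped to the input's [min, max] so interpolation can neither overshoot
    nor leave [0, 1]; constant maps stay constant.
    """
    th, tw = int(target[0]), int(target[1])
    if th < nm.shape[0] or tw < nm.shape[1]:
        raise ValueError(
            f"target {target} smaller than source {nm.shape}; only upsampling is supported"
        )
    if (th, tw) == nm.shape:
        return NormalizedMap(nm.values.copy(), method=nm.method)
    if mode == "bilinear":
        order = 1
    elif mode == "nearest":
        order = 0
    else:
        raise ValueError(f"unknown upsample mode {mode!r}")
    out = resize(
        nm.values, (th, tw), order=order, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    out = np.clip(out, nm.values.min(), nm.values.max())
    return NormalizedMap(out, method=nm.method)


def _jet_rgb(values: np.ndarray) -> np.ndarray:
    """Map [0,1] values through a jet-style colormap to uint8 RGB."""
    import matplotlib

    cmap = matplotlib.colormaps["jet"]
    rgba = cmap(np.clip(values, 0.0, 1.0))
    return (rgba[..., :3] * 255).round().astype(np.uint8)


def _as_rgb_uint8(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = (np.clip(img.astype(float), 0.0, 1.0) * 255).round().astype(np.uint8)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError(f"expected grayscale or RGB image, got shape {img.shape}")
    return img


def render_overlay(
    image: np.ndarray,
    nm: NormalizedMap,
    threshold: float = 0.2,
    alpha: float = 0.45,
) -> np.ndarray:
    """Alpha-blend a color-mapped heatmap (red = high) over the input image.

    ``image`` is grayscale or RGB, float in [0, 1] or uint8, at the same
    resolution as ``nm``.  Pixels at or below ``threshold`` stay fully
    transparent (the input shows through unchanged).  Returns uint8 RGB.
    """
    base = _as_rgb_uint8(image)
    if base.shape[:2] != nm.shape:
        raise ContractViolationError(
            f"image resolution {base.shape[:2]} does not match map {nm.shape}; "
            "upsample the map first"
        )
    heat = _jet_rgb(nm.values)
    hot = nm.values > threshold
    blended = base.astype(float)
    blended[hot] = (1 - alpha) * blended[hot] + alpha * heat[hot].astype(float)
    return blended.round().astype(np.uint8)


def class_roi_bbox(am: MapLike, fraction: float = 0.7) -> BoundingBox:
    """Tight box enclosing all pixels above ``fraction`` of the map maximum.

    One box per map; used for class-level ROIs at the 70%-of-max rule.
    Always contains the argmax pixel.
    """
    values, _ = _map_values_and_method(am)
    fraction = float(fraction)
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    peak = values.max()
    if peak <= 0:
        raise EmptyROIError("map has no positive values; ROI is empty")
    rows, cols = np.nonzero(values > fraction * peak)
    return BoundingBox(
        row_min=int(rows.min()), row_max=int(rows.max()),
        col_min=int(cols.min()), col_max=int(cols.max()),
    )


# ---------------------------------------------------------------------------
# PNG writers


def save_grayscale_png(path, values01: np.ndarray) -> None:
    """Write a [0,1] float map as an 8-bit grayscale PNG."""
    arr = (np.clip(np.asarray(values01, dtype=float), 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_mask_png(path, mask: ROIMask) -> None:
    """Write a boolean mask as a 0/255 single-channel PNG."""
    arr = np.where(mask.values, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_heatmap_png(path, nm: NormalizedMap) -> None:
    """Write a normalized map as a jet-colormapped RGB PNG."""
    Image.fromarray(_jet_rgb(nm.values), mode="RGB").save(path)


def save_rgb_png(path, rgb: np.ndarray) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(path)
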
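"""Quantitative comparison of mapping methods.

Two summaries are produced per (class, method) cell: the mean ROI size after
relative thresholding (pixel count and fraction of the image), and the pooled
distribution of normalized mapping scores (mean and population standard
deviation over all pixels of all maps).  Statistics are computed at
upsampled input resolution so pixel counts refer to input-image pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractViolationError, InvalidInputError
from .heatmap import NormalizedMap, ROIMask, normalize_map, threshold_map, upsample_map
from .mapping import (
    METHODS,
    compute_cam,
    compute_crm,
    compute_gradcam,
    gradcam_weights,
)
from .model_core import ModelAdapter, extract

__all__ = [
    "ROIStats",
    "ScoreDistribution",
    "roi_pixel_stats",
    "score_distribution",
    "compare_methods",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "class",
    "method",
    "n_images",
    "mean_pixels",
    "mean_ratio",
    "score_mean",
    "score_std",
]


@dataclass(frozen=True)
class ROIStats:
    method: str
    class_label: int
    mean_pixel_count: float
    mean_ratio: float
    n_images: int


@dataclass(frozen=True)
class ScoreDistribution:
    method: str
    class_label: int
    mean: float
    std: float
    n_values: int


def roi_pixel_stats(masks: Sequence[ROIMask], class_label: int, method: str) -> ROIStats:
    """Mean highlighted-pixel count over masks and its ratio to image area."""
    if len(masks) == 0:
        raise InvalidInputError("roi_pixel_stats needs at least one mask")
    resolution = masks[0].resolution
    for m in masks:
        if m.resolution != resolution:
            raise ContractViolationError(
                f"mixed mask resolutions: {m.resolution} vs {resolution}"
            )
    counts = np.array([m.pixel_count for m in masks], dtype=float)
    total = resolution[0] * resolution[1]
    mean_count = float(counts.mean())
    return ROIStats(
        method=method,
        class_label=int(class_label),
        mean_pixel_count=mean_count,
        mean_ratio=mean_count / total,
        n_images=len(masks),
    )


def score_distribution(
    maps: Sequence[NormalizedMap], class_label: int, method: str
) -> ScoreDistribution:
    """Pool all pixel values of all normalized maps; report mean and
    population standard deviation (ddof=0)."""
    if len(maps) == 0:
        raise InvalidInputError("score_distribution needs at least one map")
    pooled = np.concatenate([m.values.ravel() for m in maps])
    return ScoreDistribution(
        method=method,
        class_label=int(class_label),
        mean=float(pooled.mean()),
        std=float(pooled.std(ddof=0)),
        n_values=pooled.size,
    )


def maps_for_image(
    adapter: ModelAdapter,
    image: np.ndarray,
    methods: Sequence[str] = METHODS,
):
    """Compute the requested raw maps for one image.

    CAM and Grad-CAM target the predicted class; CRM aggregates all classes.
    Returns ``(maps_by_method, class_scores)``.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}, expected subset of {METHODS}")
    fm, head, scores = extract(adapter, image)
    c = scores.predicted_class
    out = {}
    for m in methods:
        if m == "CAM":
            out[m] = compute_cam(fm, head, c)
        elif m == "GradCAM":
            out[m] = compute_gradcam(fm, gradcam_weights(fm, c, head=head))
        else:
            out[m] = compute_crm(fm, head)
    return out, scores


def compare_methods(
    samples: Sequence[tuple[np.ndarray, int]],
    adapter: ModelAdapter,
    methods: Sequence[str] = METHODS,
    display_threshold: float = 0.2,
    upsample_mode: str = "bilinear",
) -> pd.DataFrame:
    """Per class x method report of ROI size and score-distribution summaries.

    ``samples`` is a sequence of ``(image, class_label)`` pairs.  Each raw map
    is normalized at feature-map resolution, upsampled to input resolution and
    thresholded at ``display_threshold`` of its max.  Deterministic given a
    fixed adapter and inputs.
    """
    if len(samples) == 0:
        raise InvalidInputError("compare_methods needs at least one image")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}, expected subset of {METHODS}")

    target = tuple(adapter.input_shape)
    per_cell_masks: dict[tuple[int, str], list[ROIMask]] = {}
    per_cell_maps: dict[tuple[int, str], list[NormalizedMap]] = {}
    for image, label in samples:
        raw_maps, _ = maps_for_image(adapter, image, methods)
        for method, am in raw_maps.items():
            nm = upsample_map(normalize_map(am), target, mode=upsample_mode)
            key = (int(label), method)
            per_cell_maps.setdefault(key, []).append(nm)
            per_cell_masks.setdefault(key, []).append(
                threshold_map(nm, display_threshold)
            )

    rows = []
    for (label, method) in sorted(per_cell_masks):
        roi = roi_pixel_stats(per_cell_masks[(label, method)], label, method)
        dist = score_distribution(per_cell_maps[(label, method)], label, method)
        rows.append(
            {
                "class": label,
                "method": method,
                "n_images": roi.n_images,
                "mean_pixels": roi.mean_pixel_count,
                "mean_ratio": roi.mean_ratio,
                "score_mean": dist.mean,
                "score_std": dist.std,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
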
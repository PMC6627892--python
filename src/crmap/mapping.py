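"""Saliency map computations: CAM, Grad-CAM and class-selective relevance (CRM).

CAM for class ``c`` is the dense-weight-weighted sum of last-conv feature
maps.  Grad-CAM weights each channel by the spatially summed gradient of the
class score and passes the result through ReLU; for a GAP head that gradient
weight is analytically identical to the dense weight column.  CRM scores each
spatial element by the total squared change it induces across *all* class
scores when it is removed (zeroed in every channel), making the map
class-discriminative without choosing a target class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence, Union

import numpy as np

from .errors import ContractViolationError, InvalidInputError
from .model_core import (
    DenseHead,
    FeatureMapStack,
    compute_class_scores,
)

__all__ = [
    "ActivationMap",
    "AverageMap",
    "GradientWeights",
    "compute_cam",
    "gradcam_weights",
    "compute_gradcam",
    "compute_crm",
    "brute_force_crm",
    "average_crm",
]

#: Canonical method names used in map provenance and reports.
METHODS = ("CAM", "GradCAM", "CRM")


@dataclass(frozen=True)
class ActivationMap:
    """A ``u x v`` saliency map plus provenance.

    ``target_class`` is a class index for CAM/Grad-CAM and the string
    ``"all"`` for CRM, which aggregates every output node.
    """

    values: np.ndarray
    method: str
    target_class: Union[int, str]
    image_id: Any = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError(f"map must be 2-D, got shape {arr.shape}")
        if self.method not in METHODS:
            raise InvalidInputError(f"unknown method {self.method!r}, expected one of {METHODS}")
        if self.method in ("GradCAM", "CRM") and np.any(arr < 0):
            raise InvalidInputError(f"{self.method} maps must be non-negative")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class AverageMap:
    """Class-level map: elementwise mean of several CRM maps of one class."""

    values: np.ndarray
    class_label: int
    n_images: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError(f"map must be 2-D, got shape {arr.shape}")
        if self.n_images < 1:
            raise InvalidInputError("n_images must be >= 1")
        if np.any(arr < 0):
            raise InvalidInputError("average CRM values must be non-negative")
        object.__setattr__(self, "values", arr)

    # class-level maps flow through the same rendering path as CRM maps
    @property
    def method(self) -> str:
        return "CRM"


@dataclass(frozen=True)
class GradientWeights:
    """Per-channel Grad-CAM weights ``alpha_k`` for one class."""

    alpha: np.ndarray
    class_index: int

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim != 1:
            raise InvalidInputError("alpha must be a 1-D vector")
        if not np.all(np.isfinite(a)):
            raise InvalidInputError("alpha must be finite")
        object.__setattr__(self, "alpha", a)


def _check_class_index(c: int, num_classes: int) -> int:
    c = int(c)
    if not 0 <= c < num_classes:
        raise IndexError(f"class index {c} out of range [0, {num_classes})")
    return c


def compute_cam(fm: FeatureMapStack, head: DenseHead, class_index: int) -> ActivationMap:
    """Class activation map ``M_c(x, y) = sum_k w_k^c * f_k(x, y)``.

    No ReLU and no bias; negative values are preserved.
    """
    if fm.num_channels != head.num_channels:
        raise ContractViolationError(
            f"channel mismatch: stack K={fm.num_channels}, head K={head.num_channels}"
        )
    c = _check_class_index(class_index, head.num_classes)
    values = fm.values @ head.weights[:, c]
    return ActivationMap(values, method="CAM", target_class=c, image_id=fm.image_id)


def gradcam_weights(
    fm: FeatureMapStack,
    class_index: int,
    head: DenseHead | None = None,
    gradients: np.ndarray | None = None,
) -> GradientWeights:
    """Grad-CAM channel weights ``alpha_k^c = sum_{x,y} dS_c / df_k(x, y)``.

    Two sources are accepted:

    * ``gradients`` — per-element gradients of shape ``(u, v, K)`` from a
      backward pass; alpha is their spatial sum.
    * ``head`` — analytic path for GAP heads, where
      ``dS_c/df_k(x, y) = w_k^c / (u*v)`` so the spatial sum collapses to the
      dense weight column: ``alpha_k^c = w_k^c`` exactly.
    """
    if gradients is not None:
        g = np.asarray(gradients, dtype=float)
        if g.shape != fm.values.shape:
            raise ContractViolationError(
                f"gradient array shape {g.shape} does not match feature stack "
                f"shape {fm.values.shape}"
            )
        alpha = g.sum(axis=(0, 1))
        return GradientWeights(alpha, class_index=int(class_index))
    if head is not None:
        c = _check_class_index(class_index, head.num_classes)
        if fm.num_channels != head.num_channels:
            raise ContractViolationError(
                f"channel mismatch: stack K={fm.num_channels}, head K={head.num_channels}"
            )
        return GradientWeights(head.weights[:, c].copy(), class_index=c)
    raise ContractViolationError("gradcam_weights needs either a head or a gradient array")


def compute_gradcam(
    fm: FeatureMapStack, alpha: GradientWeights, class_index: int | None = None
) -> ActivationMap:
    """Grad-CAM map ``ReLU(sum_k alpha_k * f_k(x, y))``; values are >= 0."""
    if alpha.alpha.shape[0] != fm.num_channels:
        raise ContractViolationError(
            f"alpha has length {alpha.alpha.shape[0]} but stack has K={fm.num_channels}"
        )
    c = alpha.class_index if class_index is None else int(class_index)
    values = np.maximum(fm.values @ alpha.alpha, 0.0)
    return ActivationMap(values, method="GradCAM", target_class=c, image_id=fm.image_id)


def compute_crm(fm: FeatureMapStack, head: DenseHead) -> ActivationMap:
    """Class-selective relevance map.

    Removing spatial element ``(l, m)`` zeroes ``f_k(l, m)`` in every channel
    while the GAP divisor stays ``u*v``; the relevance of the element is the
    sum over all ``N`` output nodes of the squared score change:

        ``R(l, m) = sum_c (S_c - S_c(l, m))^2
                  = sum_c (sum_k w_k^c f_k(l, m) / (u*v))^2``

    Biases cancel in the difference.  The closed form above is what this
    function evaluates; :func:`brute_force_crm` realizes the literal
    remove-and-rescore procedure and is used as its oracle in tests.
    """
    if fm.num_channels != head.num_channels:
        raise ContractViolationError(
            f"channel mismatch: stack K={fm.num_channels}, head K={head.num_channels}"
        )
    uv = fm.u * fm.v
    per_class = (fm.values @ head.weights) / uv  # (u, v, N) score drops
    values = np.square(per_class).sum(axis=2)
    return ActivationMap(values, method="CRM", target_class="all", image_id=fm.image_id)


def brute_force_crm(fm: FeatureMapStack, head: DenseHead) -> ActivationMap:
    """Leave-one-element-out CRM oracle.

    Literally zeroes each spatial element across all channels, recomputes the
    GAP-head scores, and accumulates squared score differences over all
    classes.  O(u*v) forward recomputations; intended for tests.
    """
    base = compute_class_scores(fm, head).scores
    values = np.empty((fm.u, fm.v), dtype=float)
    for l in range(fm.u):
        for m in range(fm.v):
            perturbed = fm.values.copy()
            perturbed[l, m, :] = 0.0
            removed = compute_class_scores(
                FeatureMapStack(perturbed, image_id=fm.image_id), head
            ).scores
            values[l, m] = np.sum((base - removed) ** 2)
    return ActivationMap(values, method="CRM", target_class="all", image_id=fm.image_id)


def average_crm(
    maps: Sequence[ActivationMap],
    class_label: int,
    normalize_each: bool = False,
) -> AverageMap:
    """Class-level map: elementwise mean of CRM maps from one class.

    With ``normalize_each=True`` every map is scaled to ``[0, 1]`` by its max
    before averaging, giving each image equal weight regardless of its raw
    relevance magnitude; the default averages raw maps.
    """
    if len(maps) == 0:
        raise InvalidInputError("average_crm needs at least one map")
    shape = maps[0].shape
    for am in maps:
        if am.method != "CRM":
            raise ContractViolationError(f"average_crm accepts only CRM maps, got {am.method}")
        if am.shape != shape:
            raise ContractViolationError(f"mixed map sizes: {am.shape} vs {shape}")
    stack = np.stack([am.values for am in maps])
    if normalize_each:
        peaks = stack.max(axis=(1, 2), keepdims=True)
        stack = np.divide(stack, peaks, out=np.zeros_like(stack), where=peaks > 0)
    return AverageMap(stack.mean(axis=0), class_label=int(class_label), n_images=len(maps))
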
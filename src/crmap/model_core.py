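"""Adapter contract for GAP-head CNNs and the shared score computations.

Every mapping method in this package reads only two things from a trained
network: the feature maps of the last convolutional layer and the weights of
the single dense layer sitting on top of a global average pooling (GAP).
Networks of any framework can therefore be plugged in through
:class:`ModelAdapter`; the rest of the package never touches framework
objects.

Conventions
-----------
* Feature maps are stored ``(row, col, channel)``, 0-based, row-major.
* GAP uses the *mean* over spatial positions (divide by ``u * v``).  All
  relative/normalized heatmaps are invariant to this positive scale factor.
* Class scores are pre-activation logits (the inputs to softmax/sigmoid),
  including the dense-layer bias.  Biases cancel in every score *difference*
  the mapping module uses.
* Argmax ties are broken toward the lowest class index.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ContractViolationError, InvalidInputError, UnsupportedArchitectureError

__all__ = [
    "FeatureMapStack",
    "DenseHead",
    "ClassScores",
    "ModelAdapter",
    "global_average_pool",
    "compute_class_scores",
    "extract",
]


@dataclass(frozen=True)
class FeatureMapStack:
    """Activations ``f_k(x, y)`` of the last convolutional layer for one image.

    Parameters
    ----------
    values
        Real array of shape ``(u, v, K)``: ``u`` rows, ``v`` columns, ``K``
        channels.
    image_id
        Opaque identifier used for provenance in downstream maps.
    """

    values: np.ndarray
    image_id: Any = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 3:
            raise InvalidInputError(
                f"feature map stack must be 3-D (u, v, K), got shape {arr.shape}"
            )
        if min(arr.shape) < 1:
            raise InvalidInputError("u, v and K must all be >= 1")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("feature map activations must be finite")
        object.__setattr__(self, "values", arr)

    @property
    def u(self) -> int:
        return self.values.shape[0]

    @property
    def v(self) -> int:
        return self.values.shape[1]

    @property
    def num_channels(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class DenseHead:
    """GAP-to-output dense layer: weights ``w_k^c`` and per-class biases.

    ``weights`` has shape ``(K, N)`` (channel, class); ``biases`` has length
    ``N``.  These are the only trained parameters the mapping algorithms read.
    """

    weights: np.ndarray
    biases: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        b = np.asarray(self.biases, dtype=float)
        if w.ndim != 2:
            raise InvalidInputError(f"weights must be 2-D (K, N), got shape {w.shape}")
        if b.ndim != 1 or b.shape[0] != w.shape[1]:
            raise InvalidInputError(
                f"biases must be 1-D of length N={w.shape[1]}, got shape {b.shape}"
            )
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
            raise InvalidInputError("head parameters must be finite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "biases", b)

    @property
    def num_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def num_classes(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class ClassScores:
    """Pre-activation logits ``S_c`` for one image plus the argmax class."""

    scores: np.ndarray
    predicted_class: int = field(init=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1 or s.size < 1:
            raise InvalidInputError("scores must be a non-empty 1-D vector")
        if not np.all(np.isfinite(s)):
            raise InvalidInputError("scores must be finite")
        object.__setattr__(self, "scores", s)
        # np.argmax already returns the lowest index among ties
        object.__setattr__(self, "predicted_class", int(np.argmax(s)))

    @property
    def num_classes(self) -> int:
        return self.scores.shape[0]


class ModelAdapter(abc.ABC):
    """Behavior contract a CNN must satisfy to be mapped.

    The wrapped model head must be exactly conv -> GAP -> single dense layer;
    re-invoking any method on the same image must yield identical outputs.
    """

    @property
    @abc.abstractmethod
    def input_shape(self) -> tuple[int, int]:
        """Expected ``(height, width)`` of input images."""

    @abc.abstractmethod
    def feature_maps(self, image: np.ndarray) -> FeatureMapStack:
        """Return the last-conv feature maps for ``image``."""

    @abc.abstractmethod
    def dense_head(self) -> DenseHead:
        """Return the trained GAP-to-output dense layer."""

    @abc.abstractmethod
    def forward_scores(self, image: np.ndarray) -> np.ndarray:
        """Return the model's own forward-pass logits (length N)."""

    def score_gradients(self, image: np.ndarray, class_index: int) -> np.ndarray:
        """Gradients of ``S_c`` w.r.t. the last-conv feature maps, shape (u, v, K).

        Optional; adapters without a gradient path may leave this
        unimplemented, in which case Grad-CAM falls back to the analytic
        GAP-head weights.
        """
        raise NotImplementedError


def global_average_pool(fm: FeatureMapStack) -> np.ndarray:
    """Spatially average each feature map: component ``k`` is
    ``(1 / (u*v)) * sum_{x,y} f_k(x, y)``.

    Returns a vector of length ``K``.
    """
    if not isinstance(fm, FeatureMapStack):
        fm = FeatureMapStack(fm)
    return fm.values.mean(axis=(0, 1))


def compute_class_scores(fm: FeatureMapStack, head: DenseHead) -> ClassScores:
    """Logits as the weighted sum of pooled feature maps plus bias:
    ``S_c = sum_k w_k^c * GAP_k + b_c``.
    """
    if fm.num_channels != head.num_channels:
        raise ContractViolationError(
            f"feature stack has K={fm.num_channels} channels but head expects "
            f"K={head.num_channels}"
        )
    pooled = global_average_pool(fm)
    scores = pooled @ head.weights + head.biases
    return ClassScores(scores)


def extract(
    adapter: ModelAdapter, image: np.ndarray, rtol: float = 1e-5
) -> tuple[FeatureMapStack, DenseHead, ClassScores]:
    """Pull (feature maps, dense head, class scores) out of an adapter.

    Verifies the adapter really is GAP-headed: the scores recomputed from the
    extracted stack and head must match the adapter's own forward-pass logits
    within ``rtol`` relative tolerance, otherwise the architecture is
    rejected.
    """
    image = np.asarray(image, dtype=float)
    if image.shape[:2] != tuple(adapter.input_shape):
        raise InvalidInputError(
            f"image shape {image.shape[:2]} does not match adapter input "
            f"shape {tuple(adapter.input_shape)}"
        )
    fm = adapter.feature_maps(image)
    head = adapter.dense_head()
    if fm.num_channels != head.num_channels:
        raise UnsupportedArchitectureError(
            "adapter feature maps and dense head disagree on channel count; "
            "the head is not conv -> GAP -> dense"
        )
    scores = compute_class_scores(fm, head)
    own = np.asarray(adapter.forward_scores(image), dtype=float)
    scale = np.maximum(np.abs(own), 1.0)
    if not np.all(np.abs(scores.scores - own) <= rtol * scale):
        raise UnsupportedArchitectureError(
            "recomputed GAP-head scores disagree with the adapter's forward "
            "pass; the model head is not conv -> GAP -> dense"
        )
    return fm, head, scores
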
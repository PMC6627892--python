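"""Tiny GAP-head CNN in pure NumPy, trainable on one CPU in minutes.

The head is exactly conv -> ReLU -> global average pooling -> single dense
layer, i.e. the CAM-compatible shape the mapping algorithms require.  Layers
implement forward and backward by hand (im2col convolutions, max-pool,
softmax cross-entropy, Adam), keeping the fixture free of any deep-learning
framework dependency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ConfigurationError, InvalidInputError
from ..model_core import DenseHead, FeatureMapStack, ModelAdapter
from .images import NUM_CLASSES, Dataset

__all__ = [
    "TinyModelSpec",
    "TinyCNNAdapter",
    "build_tiny_cnn",
    "train_fixture_model",
]


@dataclass(frozen=True)
class TinyModelSpec:
    """Architecture knobs: 3x3 convs with 2x2 max-pool after each early
    block, optional extra 3x3 convs at full feature-map resolution, then a
    final 3x3 conv feeding GAP -> dense(num_classes)."""

    image_size: int = 64
    conv_channels: tuple = (8, 16)
    extra_channels: tuple = (32,)
    final_channels: int = 64
    num_classes: int = NUM_CLASSES

    @property
    def feature_map_size(self) -> int:
        return self.image_size // (2 ** len(self.conv_channels))

    def validate(self) -> None:
        if self.feature_map_size < 4:
            raise ConfigurationError(
                f"final feature maps would be {self.feature_map_size}x"
                f"{self.feature_map_size}; need at least 4x4 for spatially "
                "informative maps"
            )
        if self.image_size % (2 ** len(self.conv_channels)) != 0:
            raise ConfigurationError("image_size must be divisible by the pooling factor")


# ---------------------------------------------------------------------------
# layers (NCHW, stride-1 pad-1 3x3 convs)


def _windows3(x: np.ndarray) -> np.ndarray:
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    return sliding_window_view(xp, (3, 3), axis=(2, 3))


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self._cols = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols = _windows3(x)
        return (
            np.einsum("bchwij,ocij->bohw", self._cols, self.W, optimize=True)
            + self.b[:, None, None]
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("bchwij,bohw->ocij", self._cols, dy, optimize=True)
        self.db = dy.sum(axis=(0, 2, 3))
        dyw = _windows3(dy)
        wflip = self.W[:, :, ::-1, ::-1]
        return np.einsum("bohwij,ocij->bchw", dyw, wflip, optimize=True)

    def params(self):
        return [("W", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool2:
    def forward(self, x):
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        self._x = x
        self._y = y
        return y

    def backward(self, dy):
        b, c, h, w = self._x.shape
        ymax = np.repeat(np.repeat(self._y, 2, axis=2), 2, axis=3)
        mask = self._x == ymax
        # split gradient equally among tied maxima inside each window
        counts = (
            mask.reshape(b, c, h // 2, 2, w // 2, 2)
            .sum(axis=(3, 5), keepdims=True)
            .reshape(b, c, h // 2, 1, w // 2, 1)
        )
        counts = np.repeat(np.repeat(counts.reshape(b, c, h // 2, w // 2), 2, axis=2), 2, axis=3)
        dyx = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3)
        return dyx * mask / counts


class _TinyCNN:
    """conv/pool feature extractor + GAP + dense classifier."""

    def __init__(self, spec: TinyModelSpec, rng: np.random.Generator):
        spec.validate()
        self.spec = spec
        chans = [1, *spec.conv_channels]
        self.blocks = []
        for c_in, c_out in zip(chans[:-1], chans[1:]):
            self.blocks.append((_Conv3x3(c_in, c_out, rng), _ReLU(), _MaxPool2()))
        self.extra = []
        c_prev = chans[-1]
        for c_out in spec.extra_channels:
            self.extra.append((_Conv3x3(c_prev, c_out, rng), _ReLU()))
            c_prev = c_out
        self.final_conv = _Conv3x3(c_prev, spec.final_channels, rng)
        self.final_relu = _ReLU()
        self.Wd = rng.normal(
            0.0,
            np.sqrt(1.0 / spec.final_channels),
            size=(spec.final_channels, spec.num_classes),
        )
        self.bd = np.zeros(spec.num_classes)

    # -- forward -----------------------------------------------------------
    def features(self, x: np.ndarray) -> np.ndarray:
        for conv, relu, pool in self.blocks:
            x = pool.forward(relu.forward(conv.forward(x)))
        for conv, relu in self.extra:
            x = relu.forward(conv.forward(x))
        return self.final_relu.forward(self.final_conv.forward(x))

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.features(x)
        self._gap = f.mean(axis=(2, 3))
        self._fshape = f.shape
        return self._gap @ self.Wd + self.bd

    # -- backward ----------------------------------------------------------
    def backward(self, dlogits: np.ndarray) -> None:
        self.dWd = self._gap.T @ dlogits
        self.dbd = dlogits.sum(axis=0)
        dgap = dlogits @ self.Wd.T
        b, k, u, v = self._fshape
        df = np.broadcast_to(dgap[:, :, None, None], self._fshape) / (u * v)
        dx = self.final_conv.backward(self.final_relu.backward(df))
        for conv, relu in reversed(self.extra):
            dx = conv.backward(relu.backward(dx))
        for conv, relu, pool in reversed(self.blocks):
            dx = conv.backward(relu.backward(pool.backward(dx)))

    def param_grads(self):
        out = [(self, "Wd", "dWd"), (self, "bd", "dbd")]
        convs = self._all_convs()
        for conv in convs:
            out.append((conv, "W", "dW"))
            out.append((conv, "b", "db"))
        return out

    def _all_convs(self):
        return (
            [c for c, _, _ in self.blocks]
            + [c for c, _ in self.extra]
            + [self.final_conv]
        )


class _Adam:
    def __init__(self, param_grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pg = param_grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, p)) for o, p, _ in param_grads]
        self.v = [np.zeros_like(getattr(o, p)) for o, p, _ in param_grads]

    def step(self):
        self.t += 1
        for i, (obj, pname, gname) in enumerate(self.pg):
            g = getattr(obj, gname)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            setattr(
                obj, pname,
                getattr(obj, pname) - self.lr * mhat / (np.sqrt(vhat) + self.eps),
            )


def _softmax_ce(logits: np.ndarray, labels: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


# ---------------------------------------------------------------------------
# adapter


class TinyCNNAdapter(ModelAdapter):
    """ModelAdapter over the NumPy fixture CNN.

    Images are 2-D grayscale arrays in [0, 1] of the spec's input size.
    """

    def __init__(self, model: _TinyCNN):
        self._model = model

    @property
    def input_shape(self) -> tuple[int, int]:
        s = self._model.spec.image_size
        return (s, s)

    def _batchify(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float)
        if img.ndim == 3 and img.shape[2] == 1:
            img = img[:, :, 0]
        if img.shape != self.input_shape:
            raise InvalidInputError(
                f"expected image of shape {self.input_shape}, got {img.shape}"
            )
        return img[None, None, :, :]

    def feature_maps(self, image: np.ndarray) -> FeatureMapStack:
        f = self._model.features(self._batchify(image))[0]  # (K, u, v)
        return FeatureMapStack(np.transpose(f, (1, 2, 0)))

    def dense_head(self) -> DenseHead:
        return DenseHead(self._model.Wd.copy(), self._model.bd.copy())

    def forward_scores(self, image: np.ndarray) -> np.ndarray:
        return self._model.forward(self._batchify(image))[0]

    def score_gradients(self, image: np.ndarray, class_index: int) -> np.ndarray:
        """Backward pass of the GAP+dense head: dS_c/df_k(x,y) = w_k^c/(u*v)."""
        fm = self.feature_maps(image)
        w = self._model.Wd[:, int(class_index)]
        uv = fm.u * fm.v
        return np.broadcast_to(w / uv, fm.values.shape).copy()

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        m = self._model
        arrays = {"Wd": m.Wd, "bd": m.bd}
        for i, conv in enumerate(m._all_convs()):
            arrays[f"conv{i}_W"] = conv.W
            arrays[f"conv{i}_b"] = conv.b
        np.savez(
            path,
            image_size=m.spec.image_size,
            conv_channels=np.array(m.spec.conv_channels),
            extra_channels=np.array(m.spec.extra_channels),
            final_channels=m.spec.final_channels,
            num_classes=m.spec.num_classes,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TinyCNNAdapter":
        data = np.load(path)
        spec = TinyModelSpec(
            image_size=int(data["image_size"]),
            conv_channels=tuple(int(c) for c in data["conv_channels"]),
            extra_channels=tuple(int(c) for c in data["extra_channels"]),
            final_channels=int(data["final_channels"]),
            num_classes=int(data["num_classes"]),
        )
        model = _TinyCNN(spec, np.random.default_rng(0))
        for i, conv in enumerate(model._all_convs()):
            conv.W = data[f"conv{i}_W"]
            conv.b = data[f"conv{i}_b"]
        model.Wd = data["Wd"]
        model.bd = data["bd"]
        return cls(model)

    def export_head_csv(self, weights_path, biases_path) -> None:
        """Portable dump of the dense head so mapping can run model-free."""
        np.savetxt(weights_path, self._model.Wd, delimiter=",")
        np.savetxt(biases_path, self._model.bd[None, :], delimiter=",")


def build_tiny_cnn(spec: TinyModelSpec | None = None, seed: int = 0) -> TinyCNNAdapter:
    """Freshly initialized (untrained) fixture CNN satisfying the adapter contract."""
    spec = spec or TinyModelSpec()
    return TinyCNNAdapter(_TinyCNN(spec, np.random.default_rng([seed, 1234])))


def _split_arrays(dataset: Dataset, split: str):
    images = dataset.splits.get(split, [])
    if not images:
        return None, None
    x = np.stack([img.pixels for img in images])[:, None, :, :]
    y = np.array([img.class_label for img in images])
    return x, y


def _accuracy(model: _TinyCNN, x, y, batch: int = 64) -> float:
    preds = []
    for i in range(0, len(x), batch):
        preds.append(model.forward(x[i : i + batch]).argmax(axis=1))
    return float((np.concatenate(preds) == y).mean())


def train_fixture_model(
    dataset: Dataset,
    seed: int = 1,
    epochs: int = 40,
    lr: float = 2e-3,
    batch_size: int = 16,
    spec: TinyModelSpec | None = None,
) -> tuple[TinyCNNAdapter, dict]:
    """Train the fixture CNN; deterministic for a fixed seed.

    Initialization and the per-epoch shuffle both derive from ``seed``.
    Returns the adapter and a metrics dict with per-epoch losses and final
    split accuracies.
    """
    x_train, y_train = _split_arrays(dataset, "train")
    if x_train is None:
        raise InvalidInputError("dataset has no training images")
    spec = spec or TinyModelSpec(image_size=dataset.config.image_size)
    rng = np.random.default_rng([seed, 1234])
    model = _TinyCNN(spec, rng)
    opt = _Adam(model.param_grads(), lr=lr)

    losses = []
    n = len(x_train)
    for _ in range(int(epochs)):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            logits = model.forward(x_train[idx])
            loss, dlogits = _softmax_ce(logits, y_train[idx])
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)

    metrics = {"epoch_losses": losses, "epochs": int(epochs), "seed": int(seed)}
    for split in ("train", "val", "test"):
        x, y = _split_arrays(dataset, split)
        if x is not None:
            metrics[f"{split}_accuracy"] = _accuracy(model, x, y)
    return TinyCNNAdapter(model), metrics
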
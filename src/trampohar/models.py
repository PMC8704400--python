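"""Model zoo: the GAP CNN, its fully-connected and small-CNN baselines, the
variable-depth family, and the Random-Forest-on-features baseline.

The flagship network ("ours" in the reports) is a VGG16-style 1D CNN: five
convolution blocks with filter counts 16,16 | 32,32 | 64,64,64 | 128,128,128 |
128,128,128, a size-2 max pool after each block, then global average pooling
(GAP) and a softmax layer.  On the 192x1 flattened-window input the sequence
length halves at each pool (192 -> 96 -> 48 -> 24 -> 12 -> 6) and GAP leaves a
128-vector, so the only classifier parameters are the 128x6+6 of the softmax
layer — the point of replacing the fully-connected head.

Architectures are described by a backend-neutral :class:`ModelSpec` (a plain
layer list that serializes to JSON) and compiled to the numpy engine in
:mod:`trampohar._nn` for training.  Conventions not fixed by the printed
architecture are frozen here: kernel size 3 with same-padding, ReLU hidden
activations, pool size 2 / stride 2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import _nn
from .signal_core import LABEL_ORDER, N_CLASSES, Window, windows_to_arrays

logger = logging.getLogger("trampohar")

__all__ = [
    "LayerSpec", "ModelSpec", "TrainConfig", "FittedModel",
    "build_ours", "build_vgg16_fc", "build_simple_cnn", "build_depth_variant",
    "output_shapes", "count_params", "train", "train_rf", "FittedForest",
]


@dataclass(frozen=True)
class LayerSpec:
    kind: str                 # conv | maxpool | gap | flatten | dense | softmax
    units: int = 0            # filters (conv) or units (dense/softmax)
    size: int = 0             # kernel (conv) or pool size (maxpool)
    relu: bool = True         # hidden activation; ignored for pool/gap/flatten


@dataclass(frozen=True)
class ModelSpec:
    """Backend-neutral, JSON-serializable layer-by-layer description."""

    name: str
    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int]      # (sequence length, channels)
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if not self.layers or self.layers[-1].kind != "softmax":
            raise ValueError("last layer must be the softmax output")
        if self.layers[-1].units != self.n_classes:
            raise ValueError("softmax width must equal n_classes")
        output_shapes(self)  # raises if shapes do not chain

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "input_shape": list(self.input_shape),
                "n_classes": self.n_classes,
                "layers": [asdict(l) for l in self.layers],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(
            name=d["name"],
            layers=tuple(LayerSpec(**l) for l in d["layers"]),
            input_shape=tuple(d["input_shape"]),
            n_classes=d["n_classes"],
        )


def output_shapes(spec: ModelSpec) -> list[tuple[int, ...]]:
    """Propagate the input shape through the layer list.

    Sequence layers yield (length, channels); flattened layers yield (units,).
    """
    shape: tuple[int, ...] = spec.input_shape
    out: list[tuple[int, ...]] = []
    for layer in spec.layers:
        if layer.kind == "conv":
            if len(shape) != 2:
                raise ValueError("conv after flatten")
            shape = (shape[0], layer.units)           # same padding, stride 1
        elif layer.kind == "maxpool":
            if len(shape) != 2:
                raise ValueError("pool after flatten")
            shape = (shape[0] // layer.size, shape[1])
        elif layer.kind == "gap":
            if len(shape) != 2:
                raise ValueError("gap after flatten")
            shape = (shape[1],)
        elif layer.kind == "flatten":
            shape = (int(np.prod(shape)),)
        elif layer.kind in ("dense", "softmax"):
            if len(shape) != 1:
                raise ValueError("dense on sequence input; flatten or pool first")
            shape = (layer.units,)
        else:
            raise ValueError(f"unknown layer kind {layer.kind!r}")
        out.append(shape)
    return out


def count_params(spec: ModelSpec) -> int:
    total = 0
    shape: tuple[int, ...] = spec.input_shape
    for layer, out in zip(spec.layers, output_shapes(spec)):
        if layer.kind == "conv":
            total += layer.size * shape[1] * layer.units + layer.units
        elif layer.kind in ("dense", "softmax"):
            total += shape[0] * layer.units + layer.units
        shape = out
    return total


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

_OURS_BLOCKS = ((16, 16), (32, 32), (64, 64, 64), (128, 128, 128), (128, 128, 128))


def _extractor_layers(kernel: int = 3) -> list[LayerSpec]:
    layers: list[LayerSpec] = []
    for block in _OURS_BLOCKS:
        layers += [LayerSpec("conv", f, kernel) for f in block]
        layers.append(LayerSpec("maxpool", size=2))
    return layers


def build_ours(
    input_shape: tuple[int, int] = (192, 1), n_classes: int = N_CLASSES
) -> ModelSpec:
    """The 13-conv GAP network (five blocks, pool after each, GAP, softmax)."""
    layers = _extractor_layers() + [
        LayerSpec("gap"),
        LayerSpec("softmax", n_classes, relu=False),
    ]
    return ModelSpec("ours", tuple(layers), input_shape, n_classes)


def build_vgg16_fc(
    input_shape: tuple[int, int] = (192, 1),
    n_classes: int = N_CLASSES,
    fc_units: int = 128,
) -> ModelSpec:
    """Same feature extractor, but a flatten + two fully-connected layers head
    (the head widths are scaled to the 128-channel extractor)."""
    layers = _extractor_layers() + [
        LayerSpec("flatten"),
        LayerSpec("dense", fc_units),
        LayerSpec("dense", fc_units),
        LayerSpec("softmax", n_classes, relu=False),
    ]
    return ModelSpec("vgg16fc", tuple(layers), input_shape, n_classes)


def build_simple_cnn(
    input_shape: tuple[int, int] = (192, 1), n_classes: int = N_CLASSES
) -> ModelSpec:
    """A small three-conv reference network (a documented reconstruction:
    filters 32/64/128, kernel 3, one pool, dense head without GAP)."""
    layers = [
        LayerSpec("conv", 32, 3),
        LayerSpec("maxpool", size=2),
        LayerSpec("conv", 64, 3),
        LayerSpec("conv", 128, 3),
        LayerSpec("flatten"),
        LayerSpec("dense", 128),
        LayerSpec("softmax", n_classes, relu=False),
    ]
    return ModelSpec("simple", tuple(layers), input_shape, n_classes)


def build_depth_variant(
    n_conv: int, input_shape: tuple[int, int] = (192, 1), n_classes: int = N_CLASSES
) -> ModelSpec:
    """Depth-sweep family: conv layers in groups of three, 16 channels doubled
    every three layers, a size-2 pool after each completed group (none after a
    trailing partial group), GAP + softmax head."""
    if not 1 <= n_conv <= 19:
        raise ValueError(f"n_conv must be in 1..19, got {n_conv}")
    layers: list[LayerSpec] = []
    for i in range(n_conv):
        layers.append(LayerSpec("conv", 16 * 2 ** (i // 3), 3))
        if i % 3 == 2:
            layers.append(LayerSpec("maxpool", size=2))
    layers += [LayerSpec("gap"), LayerSpec("softmax", n_classes, relu=False)]
    return ModelSpec(f"depth:{n_conv}", tuple(layers), input_shape, n_classes)


def build(kind: str, n_classes: int = N_CLASSES) -> ModelSpec:
    """Build by CLI-style name: ours | vgg16fc | simple | depth:<k>."""
    if kind == "ours":
        return build_ours(n_classes=n_classes)
    if kind == "vgg16fc":
        return build_vgg16_fc(n_classes=n_classes)
    if kind == "simple":
        return build_simple_cnn(n_classes=n_classes)
    if kind.startswith("depth:"):
        return build_depth_variant(int(kind.split(":", 1)[1]), n_classes=n_classes)
    raise ValueError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol; defaults are the study protocol values."""

    learning_rate: float = 1.0e-3
    batch_size: int = 20
    epochs: int = 100
    seed: int = 0
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"

    def __post_init__(self) -> None:
        if self.optimizer != "adam" or self.loss != "categorical_crossentropy":
            raise ValueError("only adam + categorical cross-entropy are supported")


def _compile(spec: ModelSpec, seed: int) -> _nn.SequentialNet:
    layers: list[_nn._Layer] = []
    shape: tuple[int, ...] = spec.input_shape
    for layer, out in zip(spec.layers, output_shapes(spec)):
        if layer.kind == "conv":
            layers.append(_nn.Conv1D(shape[1], layer.units, layer.size, relu=layer.relu))
        elif layer.kind == "maxpool":
            layers.append(_nn.MaxPool1D(layer.size))
        elif layer.kind == "gap":
            layers.append(_nn.GlobalAvgPool1D())
        elif layer.kind == "flatten":
            layers.append(_nn.Flatten())
        elif layer.kind == "dense":
            layers.append(_nn.Dense(shape[0], layer.units, relu=layer.relu))
        else:  # softmax output: linear Dense; softmax applied by the loss
            layers.append(_nn.Dense(shape[0], layer.units, relu=False))
        shape = out
    return _nn.SequentialNet(layers, seed=seed)


class FittedModel:
    """A trained CNN plus its spec: predicts class indices in canonical order
    (ties broken toward the lowest index)."""

    def __init__(self, spec: ModelSpec, net: _nn.SequentialNet, history: list[float]):
        self.spec = spec
        self.net = net
        self.history = history

    @property
    def layout(self) -> str:
        return "flat" if self.spec.input_shape[1] == 1 else "multichannel"

    def _x(self, data: Sequence[Window] | np.ndarray) -> np.ndarray:
        if len(data) and isinstance(data[0], Window):
            x, _ = windows_to_arrays(data, layout=self.layout)
            return x
        return np.asarray(data, np.float32)

    def predict_proba(self, data: Sequence[Window] | np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self._x(data))

    def predict(self, data: Sequence[Window] | np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(data), axis=1)

    def n_params(self) -> int:
        return self.net.n_params()

    def clone(self) -> "FittedModel":
        m = FittedModel(self.spec, _compile(self.spec, seed=0), list(self.history))
        m.net.set_weights(self.net.get_weights())
        return m

    def continue_training(
        self,
        data: Sequence[Window] | tuple[np.ndarray, np.ndarray],
        config: TrainConfig,
        trainable: str = "all",
    ) -> "FittedModel":
        """Further training (fine-tuning) on new data; ``trainable='head'``
        updates only the softmax layer, leaving the extractor untouched."""
        x, y = _as_xy(data, self.layout)
        hist = self.net.fit(
            x, y, self.spec.n_classes,
            epochs=config.epochs, batch_size=config.batch_size,
            learning_rate=config.learning_rate, seed=config.seed,
            trainable=trainable,
        )
        self.history = self.history + hist
        return self

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "model_spec.json").write_text(self.spec.to_json())
        np.savez(directory / "weights.npz", *self.net.get_weights())

    @classmethod
    def load(cls, directory: str | Path) -> "FittedModel":
        directory = Path(directory)
        spec = ModelSpec.from_json((directory / "model_spec.json").read_text())
        net = _compile(spec, seed=0)
        with np.load(directory / "weights.npz") as z:
            net.set_weights([z[k] for k in z.files])
        return cls(spec, net, [])


def _as_xy(
    data: Sequence[Window] | tuple[np.ndarray, np.ndarray], layout: str
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple):
        return np.asarray(data[0], np.float32), np.asarray(data[1])
    return windows_to_arrays(data, layout=layout)


def train(
    spec: ModelSpec,
    data: Sequence[Window] | tuple[np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
) -> FittedModel:
    """Fit a CNN spec on labeled windows.

    Refuses to train when any of the spec's classes is absent from the labels
    (a fold with a missing class would silently never predict it).
    """
    layout = "flat" if spec.input_shape[1] == 1 else "multichannel"
    x, y = _as_xy(data, layout)
    present = set(np.unique(y).tolist())
    missing = sorted(set(range(spec.n_classes)) - present)
    if missing:
        names = [LABEL_ORDER[i].code if spec.n_classes == N_CLASSES else str(i)
                 for i in missing]
        raise ValueError(f"training data is missing class(es) {names}")
    net = _compile(spec, seed=config.seed)
    history = net.fit(
        x, y, spec.n_classes,
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate, seed=config.seed + 1,
        trainable="all",
    )
    logger.info(
        "trained %s: %d params, loss %.4f -> %.4f",
        spec.name, net.n_params(), history[0], history[-1],
    )
    return FittedModel(spec, net, history)


# ---------------------------------------------------------------------------
# Random-Forest baseline on hand-crafted features
# ---------------------------------------------------------------------------


class FittedForest:
    """Random Forest over the hand-crafted feature table."""

    def __init__(self, forest: RandomForestClassifier, feature_columns: list[str]):
        self.forest = forest
        self.feature_columns = feature_columns

    def predict(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            features = features[self.feature_columns].to_numpy()
        return self.forest.predict(features)

    def n_params(self) -> int:  # node count, for rough size comparisons
        return int(sum(t.tree_.node_count for t in self.forest.estimators_))


def train_rf(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray | None = None,
    seed: int = 0,
    n_estimators: int = 300,
) -> FittedForest:
    """Fit the RF baseline.  ``features`` may be the :func:`extract_table`
    DataFrame (labels taken from its ``label`` column) or a plain matrix with
    explicit integer ``labels``.  Refuses NaN features, naming the columns."""
    if isinstance(features, pd.DataFrame):
        meta = [c for c in ("subject_id", "set_index", "label") if c in features.columns]
        cols = [c for c in features.columns if c not in meta]
        if labels is None:
            if "label" not in features.columns:
                raise ValueError("no labels given and no 'label' column present")
            from .signal_core import MotionLabel

            labels = features["label"].map(lambda c: MotionLabel.from_code(c).index)
        bad = [c for c in cols if features[c].isna().any()]
        if bad:
            raise ValueError(f"NaN feature values in columns {bad}")
        x = features[cols].to_numpy()
    else:
        x = np.asarray(features, dtype=float)
        cols = [f"f{i}" for i in range(x.shape[1])]
        if labels is None:
            raise ValueError("labels are required with a plain feature matrix")
        if np.isnan(x).any():
            bad = [cols[i] for i in np.unique(np.nonzero(np.isnan(x))[1])]
            raise ValueError(f"NaN feature values in columns {bad}")
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes to fit the forest")
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    forest.fit(x, labels)
    return FittedForest(forest, cols)
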
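"""Image classifier for Fix-images, with Grad-CAM explainability.

The model is a compact three-block convolutional network (conv-ReLU-pool
twice, a third conv block, global average pooling, and a two-way linear
head) written on the numpy layers in :mod:`gazescreen.nnet`.  It consumes
the 224 x 224 RGB Fix-image, internally averages it down to 56 x 56 to keep
training cheap on cohort-sized datasets (tens of images), and outputs
class probabilities for {control, dyslexic} via softmax.  Because forward
and backward passes are hand-written, Grad-CAM saliency maps are computed
from the network's exact analytic gradients rather than a framework hook.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .fiximage import FixImage
from .nnet import (
    Adam,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2,
    ReLU,
    cross_entropy,
    softmax,
)

#: Fixed class order of the two output logits.
CLASS_ORDER = ("control", "dyslexic")


@dataclass(frozen=True)
class TrainConfig:
    """Fine-tuning hyperparameters; every source of randomness hangs off seed."""

    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 8
    seed: int = 0
    layers_trained: str = "all"  # "all" or "head_only"
    input_mean: tuple[float, float, float] = (0.5, 0.5, 0.5)
    input_std: tuple[float, float, float] = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.layers_trained not in ("all", "head_only"):
            raise ValueError("layers_trained must be 'all' or 'head_only'")


@dataclass(frozen=True)
class Prediction:
    """Per-recording probability of dyslexia and its thresholded label.

    The label is dyslexic iff ``p_dyslexic`` strictly exceeds the threshold;
    a probability exactly at the threshold stays control (the no-diagnosis
    default).
    """

    participant_id: str
    task_id: str
    p_dyslexic: float
    label: str
    threshold: float = 0.5


@dataclass
class SaliencyMap:
    """Unit-interval saliency raster at network input size."""

    values: np.ndarray
    target_class: str
    layer_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("saliency values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


class FixImageNet:
    """Compact two-class CNN over Fix-images (NCHW, 3 x 56 x 56 internal)."""

    input_size = 224
    working_size = 56

    def __init__(self, seed: int = 0, channels: tuple[int, int, int] = (8, 16, 32),
                 input_mean: Sequence[float] = (0.5, 0.5, 0.5),
                 input_std: Sequence[float] = (0.5, 0.5, 0.5)):
        rng = np.random.default_rng(seed)
        self.seed = seed
        self.channels = tuple(channels)
        self.input_mean = np.asarray(input_mean, dtype=np.float64)
        self.input_std = np.asarray(input_std, dtype=np.float64)
        c1, c2, c3 = self.channels
        self.layers: list[Layer] = [
            Conv2d(3, c1, rng), ReLU(), MaxPool2(),      # 56 -> 28
            Conv2d(c1, c2, rng), ReLU(), MaxPool2(),     # 28 -> 14
            Conv2d(c2, c3, rng), ReLU(),                 # 14 x 14 feature map
            GlobalAvgPool(),
            Linear(c3, len(CLASS_ORDER), rng),
        ]
        self.conv_layers = {"conv1": 0, "conv2": 3, "conv3": 6}
        self.head_index = len(self.layers) - 1

    # -- data path -------------------------------------------------------

    def preprocess(self, images) -> np.ndarray:
        """uint8 HWC rasters (FixImage or arrays) -> normalised NCHW floats."""
        if not isinstance(images, (list, tuple)):
            images = [images]
        arrays = [
            img.pixels if isinstance(img, FixImage) else np.asarray(img)
            for img in images
        ]
        batch = np.stack(arrays).astype(np.float64) / 255.0
        if batch.ndim != 4 or batch.shape[1:] != (self.input_size, self.input_size, 3):
            raise ValueError(
                f"expected rasters of shape ({self.input_size}, {self.input_size}, 3), "
                f"got {batch.shape[1:]}"
            )
        f = self.input_size // self.working_size
        n = batch.shape[0]
        batch = batch.reshape(n, self.working_size, f, self.working_size, f, 3)
        batch = batch.mean(axis=(2, 4))  # box-filter downsample
        batch = (batch - self.input_mean) / self.input_std
        return batch.transpose(0, 3, 1, 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dlogits: np.ndarray, capture: int | None = None) -> np.ndarray | None:
        """Backpropagate; optionally return the gradient at layer ``capture``'s output."""
        d = dlogits
        captured = None
        for i in range(len(self.layers) - 1, -1, -1):
            if capture is not None and i == capture:
                captured = d.copy()
            d = self.layers[i].backward(d)
        return captured

    def parameters(self, layers_trained: str = "all"):
        if layers_trained == "head_only":
            return self.layers[self.head_index].params()
        return [p for layer in self.layers for p in layer.params()]

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for name, value, _ in layer.params():
                arrays[f"layer{i}.{name}"] = value
        meta = json.dumps(
            dict(seed=self.seed, channels=list(self.channels),
                 input_mean=self.input_mean.tolist(),
                 input_std=self.input_std.tolist())
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "FixImageNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            model = cls(seed=meta["seed"], channels=tuple(meta["channels"]),
                        input_mean=meta["input_mean"], input_std=meta["input_std"])
            for i, layer in enumerate(model.layers):
                for name, value, _ in layer.params():
                    value[...] = data[f"layer{i}.{name}"]
        return model


def build_model(seed: int = 0, channels: tuple[int, int, int] = (8, 16, 32),
                config: TrainConfig | None = None) -> FixImageNet:
    """Construct the two-class Fix-image network with seeded initialisation."""
    if config is not None:
        return FixImageNet(seed=seed, channels=channels,
                           input_mean=config.input_mean, input_std=config.input_std)
    return FixImageNet(seed=seed, channels=channels)


def fine_tune(
    model: FixImageNet,
    images: Sequence,
    labels: Sequence[str],
    config: TrainConfig = TrainConfig(),
) -> tuple[FixImageNet, list[float]]:
    """Train the network with cross-entropy; returns the per-epoch loss trace.

    Data order is shuffled per epoch from ``config.seed``; with a fixed seed
    two runs on identical inputs produce identical weights and predictions.
    """
    classes = set(labels)
    if not classes.issubset(set(CLASS_ORDER)):
        raise ValueError(f"labels must be among {CLASS_ORDER}, got {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("training requires at least one image per class")
    x_all = model.preprocess(list(images))
    y_all = np.array([CLASS_ORDER.index(y) for y in labels])
    params = model.parameters(config.layers_trained)
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    trace: list[float] = []
    n = len(y_all)
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            logits = model.forward(x_all[idx])
            loss, dlogits = cross_entropy(logits, y_all[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return model, trace


def predict(model: FixImageNet, image, threshold: float = 0.5,
            participant_id: str | None = None, task_id: str | None = None) -> Prediction:
    """Probability of dyslexia for one Fix-image, thresholded to a label."""
    pid = participant_id or (image.participant_id if isinstance(image, FixImage) else "?")
    task = task_id or (image.task_id if isinstance(image, FixImage) else "?")
    x = model.preprocess(image)
    probs = softmax(model.forward(x))[0]
    p_dys = float(probs[CLASS_ORDER.index("dyslexic")])
    label = "dyslexic" if p_dys > threshold else "control"
    return Prediction(participant_id=pid, task_id=task,
                      p_dyslexic=p_dys, label=label, threshold=threshold)


def predict_batch(model: FixImageNet, images: Sequence,
                  threshold: float = 0.5) -> list[Prediction]:
    return [predict(model, img, threshold) for img in images]


def gradcam(model: FixImageNet, image, layer: str = "conv3",
            target_class: str = "dyslexic") -> SaliencyMap:
    """Gradient-weighted class activation map at a convolutional layer.

    Channel weights are the spatial means of the target logit's gradient
    w.r.t. the layer's activations; the weighted activation sum is
    rectified, bilinearly upsampled to the input size, and min-max
    normalised (a constant map degrades to all zeros).
    """
    if layer not in model.conv_layers:
        raise ValueError(
            f"{layer!r} is not a convolutional layer; choose from "
            f"{sorted(model.conv_layers)}"
        )
    if target_class not in CLASS_ORDER:
        raise ValueError(f"target_class must be one of {CLASS_ORDER}")
    idx = model.conv_layers[layer]
    x = model.preprocess(image)
    logits = model.forward(x)
    dlogits = np.zeros_like(logits)
    dlogits[0, CLASS_ORDER.index(target_class)] = 1.0
    d_act = model.backward(dlogits, capture=idx)
    act = model.layers[idx].activation
    weights = d_act.mean(axis=(2, 3))  # (1, C)
    cam = np.maximum((weights[:, :, None, None] * act).sum(axis=1), 0.0)[0]
    up = Image.fromarray(cam.astype(np.float32), mode="F").resize(
        (model.input_size, model.input_size), Image.Resampling.BILINEAR
    )
    values = np.asarray(up, dtype=np.float64)
    span = values.max() - values.min()
    if span <= 0:
        values = np.zeros_like(values)
    else:
        values = (values - values.min()) / span
    return SaliencyMap(values=values, target_class=target_class, layer_id=layer)


class FixImageCnnClassifier:
    """fit/predict adapter over FixImages for the evaluation harness."""

    def __init__(self, config: TrainConfig = TrainConfig(),
                 channels: tuple[int, int, int] = (8, 16, 32)):
        self.config = config
        self.channels = channels
        self.model: FixImageNet | None = None
        self.loss_trace: list[float] = []

    def fit(self, images: Sequence, labels: Sequence[str]) -> None:
        self.model = build_model(seed=self.config.seed, channels=self.channels,
                                 config=self.config)
        _, self.loss_trace = fine_tune(self.model, images, labels, self.config)

    def predict(self, images: Sequence) -> list[str]:
        return [p.label for p in predict_batch(self.model, images)]

    def predict_proba(self, images: Sequence) -> list[float]:
        return [p.p_dyslexic for p in predict_batch(self.model, images)]
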
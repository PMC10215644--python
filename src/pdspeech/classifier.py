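"""MobileNet-style binary CNN over spectrogram images.

The architecture follows the MobileNet layer plan: a strided 3x3 stem
convolution, thirteen depthwise-separable blocks (depthwise 3x3 + pointwise
1x1, including the five repeated 512-channel blocks), each convolution
followed by batch normalization and ReLU, global average pooling and a
dense softmax head. Because the task is binary PD-vs-HC discrimination the
ImageNet 1000-way head is replaced by a 2-unit softmax trained with
cross-entropy (binary cross-entropy in its two-class softmax form). A width
multiplier scales every channel count so a reduced model can be trained at
desk scale on one CPU.

Training uses SGD (momentum 0.9) at the configured learning rate with
optional image augmentation (random contrast, horizontal flip, random
rotation), fully seeded for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import rotate as nd_rotate

from . import _nn

__all__ = [
    "TrainConfig",
    "DatasetSplit",
    "ConfusionCounts",
    "EvalResult",
    "MobileNet",
    "build_model",
    "split_dataset",
    "train",
    "evaluate",
    "load_images",
]

# (block kind, stride, nominal output channels); the final depthwise block
# keeps stride 1 so the network ends at 7x7 before the average pool, per the
# canonical MobileNet spatial sequence 224->112->56->28->14->7.
_MOBILENET_PLAN: list[tuple[str, int, int]] = [
    ("conv", 2, 32),
    ("dw", 1, 32), ("pw", 1, 64),
    ("dw", 2, 64), ("pw", 1, 128),
    ("dw", 1, 128), ("pw", 1, 128),
    ("dw", 2, 128), ("pw", 1, 256),
    ("dw", 1, 256), ("pw", 1, 256),
    ("dw", 2, 256), ("pw", 1, 512),
    *[op for _ in range(5) for op in (("dw", 1, 512), ("pw", 1, 512))],
    ("dw", 2, 512), ("pw", 1, 1024),
    ("dw", 1, 1024), ("pw", 1, 1024),
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the published recipe)."""

    learning_rate: float = 0.005
    batch_size: int = 128
    epochs: int = 100
    momentum: float = 0.9
    augment: bool = True
    contrast_factor: float = 0.3
    rotation_factor: float = 0.18  # fraction of a full turn, each direction
    horizontal_flip: bool = True
    input_size: int = 224
    width_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class DatasetSplit:
    """Stratified train/validation/test partition of (path, label) items."""

    train: list[tuple[str, str]]
    validation: list[tuple[str, str]]
    test: list[tuple[str, str]]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalResult:
    """Accuracy (TP+TN over all), mean BCE loss, confusion counts, history."""

    accuracy: float
    loss: float
    counts: ConfusionCounts
    history: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "loss": self.loss,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def accuracy_from_counts(counts: ConfusionCounts) -> float:
    """acc = (TP + TN) / (TP + TN + FP + FN)."""
    return (counts.tp + counts.tn) / counts.total


class MobileNet:
    """Sequential depthwise-separable CNN plus its layer plan metadata."""

    def __init__(self, net: _nn.Sequential, plan: list[dict], input_size: int,
                 width_multiplier: float, classes: tuple[str, str]):
        self.net = net
        self.plan = plan  # per conv layer: kind, stride, channels, in/out spatial
        self.input_size = input_size
        self.width_multiplier = width_multiplier
        self.classes = classes  # (negative, positive)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (N, 2); column 1 = positive class."""
        logits = self.net.forward(images.astype(np.float32), train=False)
        return _nn.softmax(logits)


def build_model(
    input_size: int = 224,
    width_multiplier: float = 1.0,
    seed: int = 0,
    classes: tuple[str, str] = ("HC", "PD"),
) -> MobileNet:
    """Build the depthwise-separable CNN with a 2-class softmax head.

    ``input_size`` must be divisible by 32 (five stride-2 stages).
    ``width_multiplier`` scales every channel count (minimum 1).
    """
    if input_size % 32 != 0 or input_size <= 0:
        raise ValueError(f"input_size must be a positive multiple of 32, got {input_size}")
    rng = np.random.default_rng(seed)
    width = lambda c: max(int(round(c * width_multiplier)), 1)

    layers: list[_nn.Layer] = []
    plan: list[dict] = []
    c_in, spatial = 3, input_size
    for kind, stride, c_nominal in _MOBILENET_PLAN:
        c_out = width(c_nominal)
        out_spatial = spatial // stride
        if kind == "conv":
            layers.append(_nn.Conv2D(c_in, c_out, 3, stride, rng))
        elif kind == "dw":
            c_out = c_in  # depthwise keeps the channel count
            layers.append(_nn.DepthwiseConv2D(c_in, 3, stride, rng))
        else:  # pointwise
            layers.append(_nn.Conv2D(c_in, c_out, 1, stride, rng))
        layers.append(_nn.BatchNorm2D(c_out))
        layers.append(_nn.ReLU())
        plan.append(
            {"kind": kind, "stride": stride, "channels": c_out,
             "in_spatial": spatial, "out_spatial": out_spatial}
        )
        c_in, spatial = c_out, out_spatial
    layers.append(_nn.GlobalAvgPool())
    layers.append(_nn.Dense(c_in, 2, rng))
    plan.append({"kind": "avgpool", "stride": 1, "channels": c_in,
                 "in_spatial": spatial, "out_spatial": 1})
    plan.append({"kind": "fc", "stride": 1, "channels": 2,
                 "in_spatial": 1, "out_spatial": 1})
    return MobileNet(_nn.Sequential(layers), plan, input_size, width_multiplier, classes)


def split_dataset(
    items: list[tuple[str, str]],
    seed: int = 0,
    test_fraction: float = 0.2,
    validation_fraction: float = 0.2,
    subjects: list[str] | None = None,
) -> DatasetSplit:
    """Stratified, seeded 80/20 split with 20% of the train portion as validation.

    ``items`` are (image path, class label) pairs. When ``subjects`` is
    given (one id per item) the split is grouped so no subject spans two
    partitions; grouping is applied within each class.
    """
    labels = sorted({lab for _, lab in items})
    if len(labels) < 2:
        raise ValueError(f"need both classes present, got {labels}")
    rng = np.random.default_rng(seed)
    train: list = []
    validation: list = []
    test: list = []
    for lab in labels:
        idx = [i for i, (_, l) in enumerate(items) if l == lab]
        if subjects is None:
            order = rng.permutation(len(idx))
            shuffled = [idx[i] for i in order]
            n_test = int(round(test_fraction * len(shuffled)))
            n_val = int(round(validation_fraction * (len(shuffled) - n_test)))
            test += shuffled[:n_test]
            validation += shuffled[n_test : n_test + n_val]
            train += shuffled[n_test + n_val :]
        else:
            groups = sorted({subjects[i] for i in idx})
            order = rng.permutation(len(groups))
            groups = [groups[i] for i in order]
            n_items = len(idx)
            test_g, val_g, train_g = [], [], []
            counts = {"test": 0, "val": 0}
            for g in groups:
                if counts["test"] < test_fraction * n_items:
                    test_g.append(g)
                    counts["test"] += sum(1 for i in idx if subjects[i] == g)
                elif counts["val"] < validation_fraction * (n_items - counts["test"]):
                    val_g.append(g)
                    counts["val"] += sum(1 for i in idx if subjects[i] == g)
                else:
                    train_g.append(g)
            test += [i for i in idx if subjects[i] in test_g]
            validation += [i for i in idx if subjects[i] in val_g]
            train += [i for i in idx if subjects[i] in train_g]
    pick = lambda ids: [items[i] for i in sorted(ids)]
    return DatasetSplit(train=pick(train), validation=pick(validation), test=pick(test))


def load_images(items: list[tuple[str, str]], input_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Load JPEGs as float32 NCHW in [0, 1]; labels as 0/1 (alphabetic order,
    so HC=0 and PD=1 for the standard labels)."""
    labels = sorted({lab for _, lab in items})
    lab_to_int = {lab: i for i, lab in enumerate(labels)}
    xs, ys = [], []
    for path, lab in items:
        img = Image.open(path).convert("RGB")
        if img.size != (input_size, input_size):
            img = img.resize((input_size, input_size), Image.BILINEAR)
        xs.append(np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0)
        ys.append(lab_to_int[lab])
    return np.stack(xs), np.asarray(ys)


def _augment_batch(x: np.ndarray, config: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    out = x.copy()
    n = out.shape[0]
    if config.contrast_factor > 0:
        u = rng.uniform(1 - config.contrast_factor, 1 + config.contrast_factor, n)
        mean = out.mean(axis=(2, 3), keepdims=True)
        out = mean + (out - mean) * u[:, None, None, None]
    if config.horizontal_flip:
        flip = rng.random(n) < 0.5
        out[flip] = out[flip, :, :, ::-1]
    if config.rotation_factor > 0:
        angles = rng.uniform(-1, 1, n) * config.rotation_factor * 360.0
        for i in range(n):
            out[i] = nd_rotate(
                out[i], angles[i], axes=(1, 2), reshape=False, order=1, mode="nearest"
            )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def train(
    model: MobileNet,
    split: DatasetSplit,
    config: TrainConfig,
) -> dict[str, list[float]]:
    """Train in place; returns per-epoch history of train/val loss and accuracy.

    Augmentation applies to training images only. The batch size is reduced
    to the training-set size when it exceeds it.
    """
    if not split.train:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    x_train, y_train = load_images(split.train, model.input_size)
    x_val, y_val = (
        load_images(split.validation, model.input_size)
        if split.validation
        else (None, None)
    )
    batch = min(config.batch_size, len(split.train))
    opt = _nn.SGD(model.net.params, model.net.grads, config.learning_rate, config.momentum)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    for _ in range(config.epochs):
        order = rng.permutation(len(y_train))
        losses, hits, seen = [], 0, 0
        for start in range(0, len(order), batch):
            sel = order[start : start + batch]
            xb = x_train[sel]
            if config.augment:
                xb = _augment_batch(xb, config, rng)
            logits = model.net.forward(xb, train=True)
            loss, grad = _nn.softmax_cross_entropy(logits, y_train[sel])
            model.net.backward(grad)
            opt.step()
            losses.append(loss * len(sel))
            hits += int(np.sum(np.argmax(logits, axis=1) == y_train[sel]))
            seen += len(sel)
        history["train_loss"].append(float(np.sum(losses) / seen))
        history["train_acc"].append(hits / seen)
        if x_val is not None:
            val_loss, val_acc = _eval_arrays(model, x_val, y_val)
            history["val_loss"].append(val_loss)
            history["val_acc"].append(val_acc)
    return history


def _eval_arrays(model: MobileNet, x: np.ndarray, y: np.ndarray, batch: int = 64):
    losses, hits = [], 0
    for start in range(0, len(y), batch):
        xb, yb = x[start : start + batch], y[start : start + batch]
        logits = model.net.forward(xb, train=False)
        loss, _ = _nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(yb))
        hits += int(np.sum(np.argmax(logits, axis=1) == yb))
    return float(np.sum(losses) / len(y)), hits / len(y)


def evaluate(
    model: MobileNet,
    test_items: list[tuple[str, str]],
    positive_class: str = "PD",
    history: dict | None = None,
) -> EvalResult:
    """Confusion counts at a 0.5 threshold, accuracy and mean BCE loss."""
    if not test_items:
        raise ValueError("empty test set")
    x, _ = load_images(test_items, model.input_size)
    y_true = np.array([1 if lab == positive_class else 0 for _, lab in test_items])
    probs = model.predict_proba(x)
    labels = sorted({lab for _, lab in test_items} | {positive_class})
    pos_col = labels.index(positive_class) if len(labels) == 2 else 1
    p_pos = probs[:, pos_col]
    y_pred = (p_pos > 0.5).astype(int)
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    eps = 1e-12
    bce = float(-np.mean(y_true * np.log(p_pos + eps) + (1 - y_true) * np.log(1 - p_pos + eps)))
    return EvalResult(
        accuracy=accuracy_from_counts(counts),
        loss=bce,
        counts=counts,
        history=history or {},
    )
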
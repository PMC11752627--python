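"""Dataset splitting, transfer-learning head replacement, and training.

The training recipe mirrors the study conditions: rmsprop with learning
rate 1e-4, mini-batch size 64, at most 105 epochs, stratified random
64:16:20 train/validation/test split, and early stopping once validation
accuracy fails to improve over 10 consecutive validation checks (one
check per epoch), returning the weights from the best check.

The backbone is pluggable. A bundled small reference CNN (two 3x3
convolution + ReLU + 2x2 max-pool blocks) keeps everything trainable on
a CPU; a pretrained backbone can be passed in instead, in which case
only the freshly attached head (fully connected layer -> softmax ->
argmax class decision) is trainable.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from afwave._nn import Conv2d, Dense, Flatten, Layer, MaxPool2, ReLU, RMSProp, cross_entropy_grad, softmax
from afwave.errors import InputError, ParameterError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Random split specification; default ratios 64:16:20."""

    ratios: tuple[float, float, float] = (0.64, 0.16, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.ratios):
            raise ParameterError("split ratios must be nonnegative")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ParameterError(f"split ratios must sum to 1, got {self.ratios}")


def _largest_remainder(total: int, ratios: tuple[float, ...]) -> list[int]:
    exact = [total * r for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    order = np.argsort([c - e for c, e in zip(counts, exact)])  # most negative remainder first
    for i in range(total - sum(counts)):
        counts[order[i]] += 1
    return counts


def split_dataset(
    items: list,
    spec: SplitSpec,
    labels: list | None = None,
) -> tuple[list, list, list]:
    """Partition items into (train, validation, test).

    Subset sizes are the largest-remainder rounding of the ratio shares
    (100 items at 64:16:20 give exactly 64/16/20). When ``labels`` are
    supplied the split is stratified: each class is spread across the
    three subsets as evenly as the rounding allows, while the global
    subset sizes stay exact. Same seed, same assignment.
    """
    n = len(items)
    if n == 0:
        raise InputError("cannot split an empty dataset")
    if labels is not None and len(labels) != n:
        raise InputError("labels length must match items")
    rng = np.random.default_rng(spec.seed)
    targets = _largest_remainder(n, spec.ratios)
    if labels is None:
        order = rng.permutation(n)
        bounds = np.cumsum([0] + targets)
        subsets = [[items[i] for i in order[bounds[s] : bounds[s + 1]]] for s in range(3)]
        return subsets[0], subsets[1], subsets[2]

    by_class: dict = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    class_names = sorted(by_class, key=str)
    # per-class floors of the exact shares, then a capacity-respecting
    # largest-remainder assignment of the leftover items
    alloc = {c: [int(np.floor(len(by_class[c]) * r)) for r in spec.ratios] for c in class_names}
    leftover = {c: len(by_class[c]) - sum(alloc[c]) for c in class_names}
    capacity = [targets[s] - sum(alloc[c][s] for c in class_names) for s in range(3)]
    frac = [
        (len(by_class[c]) * spec.ratios[s] - alloc[c][s], c, s)
        for c in class_names
        for s in range(3)
    ]
    frac.sort(key=lambda t: (-t[0], str(t[1]), t[2]))
    while any(leftover.values()):
        progressed = False
        for _, c, s in frac:
            if leftover[c] > 0 and capacity[s] > 0:
                alloc[c][s] += 1
                leftover[c] -= 1
                capacity[s] -= 1
                progressed = True
        if not progressed:  # pragma: no cover - sum(leftover) == sum(capacity) guarantees progress
            raise RuntimeError("split reconciliation failed")
    subsets: list[list] = [[], [], []]
    for c in class_names:
        idx = np.array(by_class[c])
        idx = idx[rng.permutation(idx.size)]
        start = 0
        for s in range(3):
            take = alloc[c][s]
            subsets[s].extend(items[i] for i in idx[start : start + take])
            start += take
    return subsets[0], subsets[1], subsets[2]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class Backbone:
    """A feature extractor: a stack of layers mapping NHWC images to features."""

    layers: list[Layer]
    feature_dim: int
    input_size: tuple[int, int]
    pretrained: bool = False
    name: str = "small-cnn"


def small_cnn_backbone(input_size: tuple[int, int] = (64, 64), seed: int = 0) -> Backbone:
    """The bundled reference CNN: two conv/ReLU/pool blocks.

    Input H and W must be divisible by 4 (two 2x2 poolings).
    """
    h, w = input_size
    if h % 4 or w % 4:
        raise ParameterError(f"input size must be divisible by 4, got {input_size}")
    rng = np.random.default_rng(seed)
    layers: list[Layer] = [
        Conv2d(3, 8, 3, rng),
        ReLU(),
        MaxPool2(),
        Conv2d(8, 16, 3, rng),
        ReLU(),
        MaxPool2(),
        Flatten(),
    ]
    return Backbone(layers=layers, feature_dim=(h // 4) * (w // 4) * 16, input_size=input_size)


class ClassifierModel:
    """Backbone + replaced classification head (dense -> softmax -> argmax).

    With a pretrained backbone only the head's parameters are trainable,
    mirroring transfer learning where the last three stages of the
    network are replaced and trained while the feature extractor stays
    frozen.
    """

    def __init__(self, backbone: Backbone, n_classes: int, seed: int = 0):
        if n_classes < 2:
            raise ParameterError(f"need at least 2 classes, got {n_classes}")
        self.backbone = backbone
        self.n_classes = n_classes
        rng = np.random.default_rng(seed + 1)
        self.head = Dense(backbone.feature_dim, n_classes, rng)
        self.class_names: list | None = None

    # -- forward / backward -------------------------------------------------

    @property
    def layers(self) -> list[Layer]:
        return self.backbone.layers + [self.head]

    @property
    def trainable_layers(self) -> list[Layer]:
        if self.backbone.pretrained:
            return [self.head]
        return self.layers

    def n_trainable_parameters(self) -> int:
        return sum(p.size for layer in self.trainable_layers for p in layer.params().values())

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images)
        if x.ndim != 4 or x.shape[3] != 3 or x.shape[1:3] != self.backbone.input_size:
            raise InputError(
                f"expected images of shape (B, {self.backbone.input_size[0]}, "
                f"{self.backbone.input_size[1]}, 3), got {x.shape}"
            )
        if x.dtype == np.uint8:
            x = x.astype(float) / 255.0 - 0.5
        return x.astype(float)

    def forward(self, images: np.ndarray) -> np.ndarray:
        x = self._check_input(images)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return softmax(self.forward(images))

    # -- weight snapshots ----------------------------------------------------

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [copy.deepcopy(layer.params()) for layer in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for layer, saved in zip(self.layers, weights):
            for name, value in saved.items():
                layer.params()[name][...] = value


def build_model(
    backbone_spec: str | Backbone = "small",
    n_classes: int = 4,
    input_size: tuple[int, int] = (64, 64),
    seed: int = 0,
) -> ClassifierModel:
    """Build a classifier from a backbone spec with a fresh head.

    ``backbone_spec`` is either the string ``"small"`` (the bundled
    reference CNN, fully trainable) or a :class:`Backbone` instance;
    a backbone flagged ``pretrained`` is frozen so only the new head
    trains.
    """
    if isinstance(backbone_spec, Backbone):
        backbone = backbone_spec
    elif backbone_spec == "small":
        backbone = small_cnn_backbone(input_size=input_size, seed=seed)
    else:
        raise ParameterError(f"unknown backbone spec {backbone_spec!r}")
    return ClassifierModel(backbone, n_classes=n_classes, seed=seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the study recipe)."""

    optimizer: str = "rmsprop"
    learning_rate: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 105
    patience: int = 10
    gradient_threshold: float | None = None  # global-norm clip; None = no clipping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ParameterError("learning_rate, batch_size and max_epochs must be positive")
        if self.patience < 1:
            raise ParameterError("patience must be >= 1")
        if self.optimizer != "rmsprop":
            raise ParameterError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainHistory:
    """Per-validation-check records plus why training stopped."""

    records: list[tuple[int, float, float]] = field(default_factory=list)  # (epoch, train_loss, val_acc)
    stop_reason: str = "max_epochs"  # or "early_stop"
    best_epoch: int = -1
    best_val_accuracy: float = float("nan")

    def to_rows(self) -> list[dict]:
        return [
            {"epoch": e, "train_loss": tl, "val_accuracy": va}
            for e, tl, va in self.records
        ]


def _clip_gradients(layers: list[Layer], threshold: float) -> None:
    norm = np.sqrt(sum(float(np.sum(g * g)) for layer in layers for g in layer.grads().values()))
    if norm > threshold > 0:
        scale = threshold / norm
        for layer in layers:
            for g in layer.grads().values():
                g *= scale


def train(
    model: ClassifierModel,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
) -> tuple[ClassifierModel, TrainHistory]:
    """Train with rmsprop and validation-patience early stopping.

    Validation accuracy is checked once per epoch. Training stops when
    accuracy has not improved over ``patience`` consecutive checks after
    the best one, or at ``max_epochs``; the weights from the best check
    are restored before returning.
    """
    if config is None:
        config = TrainConfig()
    x_train, y_train = train_set
    x_val, y_val = val_set
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    if len(x_train) == 0 or len(x_val) == 0:
        raise InputError("train and validation sets must be non-empty")
    present = np.unique(y_train)
    if present.size < 2:
        raise InputError("degenerate training set: fewer than 2 classes present")
    if present.size < model.n_classes:
        warnings.warn(
            f"only {present.size} of {model.n_classes} classes present in the training set",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    opt = RMSProp(learning_rate=config.learning_rate)
    trainable = model.trainable_layers
    history = TrainHistory()
    best_acc = -np.inf
    best_weights = model.get_weights()
    checks_since_best = 0
    n = len(x_train)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(x_train[idx])
            loss, grad = cross_entropy_grad(logits, y_train[idx])
            model.backward(grad)
            if config.gradient_threshold is not None:
                _clip_gradients(trainable, config.gradient_threshold)
            opt.step(trainable)
            losses.append(loss)
        _, decisions = predict(model, x_val)
        val_acc = float(np.mean(decisions == y_val))
        history.records.append((epoch, float(np.mean(losses)), val_acc))
        if val_acc > best_acc:
            best_acc = val_acc
            best_weights = model.get_weights()
            history.best_epoch = epoch
            checks_since_best = 0
        else:
            checks_since_best += 1
            if checks_since_best >= config.patience:
                history.stop_reason = "early_stop"
                break
    else:
        history.stop_reason = "max_epochs"
    history.best_val_accuracy = float(best_acc)
    model.set_weights(best_weights)
    logger.info(
        "training stopped (%s) after %d epochs; best val acc %.4f at epoch %d",
        history.stop_reason, len(history.records), best_acc, history.best_epoch,
    )
    return model, history


def predict(model: ClassifierModel, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (rows sum to 1) and argmax decisions.

    Ties resolve to the lowest class index (np.argmax convention).
    Large batches are processed in chunks to bound memory.
    """
    images = np.asarray(images)
    probs = []
    for start in range(0, len(images), 256):
        probs.append(model.predict_proba(images[start : start + 256]))
    p = np.concatenate(probs, axis=0)
    return p, np.argmax(p, axis=1)
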
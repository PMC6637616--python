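"""Stage-2 glaucoma classification on extracted optic discs.

The disc region carries most of the structural glaucoma evidence (cup
enlargement, rim thinning), so classification runs on a fixed-size crop of
the localized disc rather than the whole fundus image.  The network is an
AlexNet-style stack — four convolutional layers and three dense layers,
with local response normalization and overlapping 3x3/stride-2 max-pooling
after the first two convolutions, another pool after the fourth, ReLU
nonlinearities, and 0.5 dropout after the first two dense layers — ending
in a 2-way softmax.  Training uses a constant learning rate of 1e-4 with
Adam and cross-entropy loss, and stratified mini-batches that guarantee
minority-class (glaucoma) representation in every batch.

Augmentation, when enabled, is the deterministic product of
{identity, horizontal flip, vertical flip} x {four corner crops + center
crop}: 15 patches of 227x227x3 per 256x256x3 disc.  Test-time inference
always uses the center crop only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from skimage import transform

from . import nn
from .clf_metrics import (
    CLASSES,
    UndefinedMetricError,
    report,
    roc_auc,
    stratified_kfold_split,
)
from .types import BoundingBox, FundusImage, ValidationError

__all__ = [
    "NetSpec", "ConvSpec", "TrainConfig", "DiscImage", "TrainHistory",
    "extract_disc", "augment", "center_crop", "build_network",
    "stratified_batches", "train", "predict", "cross_validate",
    "DISC_SIZE", "PATCH_SIZE",
]

DISC_SIZE = 256
PATCH_SIZE = 227


@dataclass(frozen=True)
class ConvSpec:
    """One convolutional stage: kernels, geometry, and whether LRN /
    max-pooling follow it."""

    n_kernels: int
    kernel_size: int
    stride: int = 1
    pad: int = 0
    lrn: bool = False
    maxpool: bool = False


@dataclass
class NetSpec:
    """Architecture of the disc classifier.

    The default is the 4-conv / 3-dense configuration: conv1 96@11x11
    stride 4 (+LRN +pool), conv2 256@5x5 pad 2 (+LRN +pool), conv3 384@3x3
    pad 1, conv4 256@3x3 pad 1 (+pool); dense 1024 -> 1024 -> 2 with 0.5
    dropout after the first two.  Pooling is overlapping max (window 3,
    stride 2).  ``reduced()`` gives a narrow variant for desk-scale
    experiments with identical structure.
    """

    conv_layers: tuple[ConvSpec, ...] = (
        ConvSpec(96, 11, stride=4, lrn=True, maxpool=True),
        ConvSpec(256, 5, pad=2, lrn=True, maxpool=True),
        ConvSpec(384, 3, pad=1),
        ConvSpec(256, 3, pad=1, maxpool=True),
    )
    fc_layers: tuple[tuple[int, float], ...] = ((1024, 0.5), (1024, 0.5))
    pool_window: int = 3
    pool_stride: int = 2
    n_classes: int = 2

    @classmethod
    def reduced(cls) -> "NetSpec":
        """Narrow widths (same depth and structure) for CPU-scale runs.

        Widths are 1/6 to 1/4 of the full network's; anything much narrower
        makes the 0.5 dropout noise dominate short constant-rate training
        runs (underfitting, not regularization).
        """
        return cls(
            conv_layers=(
                ConvSpec(16, 11, stride=4, lrn=True, maxpool=True),
                ConvSpec(32, 5, pad=2, lrn=True, maxpool=True),
                ConvSpec(32, 3, pad=1),
                ConvSpec(32, 3, pad=1, maxpool=True),
            ),
            fc_layers=((256, 0.5), (256, 0.5)),
        )


@dataclass
class TrainConfig:
    """Training protocol: constant-rate Adam on cross-entropy with
    stratified batches."""

    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 10
    min_minority_per_batch: int = 4
    seed: int = 0
    augment: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValidationError("learning_rate must be >= 0")
        if self.min_minority_per_batch < 1:
            raise ValidationError("min_minority_per_batch must be >= 1")
        if self.min_minority_per_batch > self.batch_size // 2:
            raise ValidationError(
                f"min_minority_per_batch {self.min_minority_per_batch} exceeds "
                f"half the batch size ({self.batch_size})"
            )


@dataclass
class DiscImage:
    """A 256x256x3 8-bit crop of the optic disc region."""

    pixels: np.ndarray
    image_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.shape != (DISC_SIZE, DISC_SIZE, 3) or px.dtype != np.uint8:
            raise ValidationError(
                f"disc must be {DISC_SIZE}x{DISC_SIZE}x3 uint8, got "
                f"{px.shape} {px.dtype}"
            )
        if self.label is not None and self.label not in CLASSES:
            raise ValidationError(f"unknown label {self.label!r}")
        self.pixels = px


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


def extract_disc(image: FundusImage, box: BoundingBox, out_size: int = DISC_SIZE) -> DiscImage:
    """Crop the (clipped) box and resize to ``out_size`` square, bilinear."""
    clipped_x0 = max(0, box.x_min)
    clipped_y0 = max(0, box.y_min)
    clipped_x1 = min(image.width, box.x_max)
    clipped_y1 = min(image.height, box.y_max)
    if clipped_x0 >= clipped_x1 or clipped_y0 >= clipped_y1:
        raise ValidationError(
            f"box {box} does not intersect the {image.height}x{image.width} image"
        )
    crop = image.pixels[clipped_y0:clipped_y1, clipped_x0:clipped_x1]
    resized = transform.resize(
        crop, (out_size, out_size, 3), order=1, mode="reflect",
        anti_aliasing=True, preserve_range=True,
    )
    return DiscImage(
        np.clip(np.rint(resized), 0, 255).astype(np.uint8), image.image_id
    )


def center_crop(pixels: np.ndarray, size: int = PATCH_SIZE) -> np.ndarray:
    h, w = pixels.shape[:2]
    if h < size or w < size:
        raise ValidationError(f"cannot crop {size} from {h}x{w}")
    y0 = (h - size) // 2
    x0 = (w - size) // 2
    return pixels[y0:y0 + size, x0:x0 + size]


def augment(disc: DiscImage) -> list[np.ndarray]:
    """The deterministic 15-patch augmentation set.

    {identity, h-flip, v-flip} x {top-left, top-right, bottom-left,
    bottom-right, center} crops of 227x227x3, in that fixed order.
    """
    px = disc.pixels
    if px.shape != (DISC_SIZE, DISC_SIZE, 3):
        raise ValidationError(f"augment expects {DISC_SIZE}x{DISC_SIZE}x3, got {px.shape}")
    s = PATCH_SIZE
    d = DISC_SIZE - s
    crops = [(0, 0), (0, d), (d, 0), (d, d), (d // 2, d // 2)]
    flips = [lambda a: a, lambda a: a[:, ::-1], lambda a: a[::-1, :]]
    patches = []
    for flip in flips:
        flipped = flip(px)
        for (y0, x0) in crops:
            patches.append(np.ascontiguousarray(flipped[y0:y0 + s, x0:x0 + s]))
    return patches


def _patch(disc: DiscImage, patch_idx: int) -> np.ndarray:
    """Patch ``patch_idx`` of the 15-patch augmentation set, lazily."""
    if patch_idx == -1:  # center crop, no flip (the no-augmentation input)
        return center_crop(disc.pixels)
    return augment(disc)[patch_idx]


def build_network(spec: NetSpec | None = None, input_size: int = PATCH_SIZE,
                  seed: int = 0, dtype=np.float32) -> nn.Sequential:
    """Assemble the Sequential model; raises if the spatial size collapses."""
    spec = spec or NetSpec()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c, size = 3, input_size
    for conv in spec.conv_layers:
        layers.append(nn.Conv2D(c, conv.n_kernels, conv.kernel_size,
                                stride=conv.stride, pad=conv.pad, rng=rng, dtype=dtype))
        size = (size + 2 * conv.pad - conv.kernel_size) // conv.stride + 1
        if size < 1:
            raise ValidationError(
                f"spatial size collapsed to {size} at conv with kernel "
                f"{conv.kernel_size}, stride {conv.stride}"
            )
        layers.append(nn.ReLU())
        if conv.lrn:
            layers.append(nn.LRN())
        if conv.maxpool:
            layers.append(nn.MaxPool2D(spec.pool_window, spec.pool_stride))
            size = (size - spec.pool_window) // spec.pool_stride + 1
            if size < 1:
                raise ValidationError("spatial size collapsed in pooling")
        c = conv.n_kernels
    layers.append(nn.Flatten())
    n_in = c * size * size
    for width, dropout_p in spec.fc_layers:
        layers.append(nn.Dense(n_in, width, rng=rng, dtype=dtype))
        layers.append(nn.ReLU())
        if dropout_p > 0:
            layers.append(nn.Dropout(dropout_p))
        n_in = width
    layers.append(nn.Dense(n_in, spec.n_classes, rng=rng, dtype=dtype))
    return nn.Sequential(layers)


def stratified_batches(labels: list[str], batch_size: int,
                       min_minority_per_batch: int, seed: int = 0) -> list[list[int]]:
    """Index batches where every batch holds >= ``min_minority_per_batch``
    minority-class samples.

    All samples are shuffled into batches of ``batch_size``; a batch short
    of minority samples is topped up with minority indices drawn (with
    replacement across batches) from the minority pool, so majority samples
    each appear exactly once per epoch while minority samples may repeat.
    A topped-up batch can exceed ``batch_size`` by at most the deficit.
    """
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError("stratified batching needs both classes present")
    rng = np.random.default_rng(seed)
    n_per = {c: sum(1 for l in labels if l == c) for c in classes}
    minority = min(classes, key=lambda c: (n_per[c], c))
    minority_idx = np.array([i for i, l in enumerate(labels) if l == minority])
    order = rng.permutation(len(labels))
    batches = [list(order[i:i + batch_size]) for i in range(0, len(labels), batch_size)]
    for batch in batches:
        have = sum(1 for i in batch if labels[i] == minority)
        deficit = min_minority_per_batch - have
        if deficit > 0:
            batch.extend(rng.choice(minority_idx, size=deficit, replace=True).tolist())
    return [[int(i) for i in b] for b in batches]


def _to_tensor(patches: list[np.ndarray]) -> np.ndarray:
    """Stack uint8 HWC patches into a standardized float32 NCHW batch.

    Pixels are mapped to roughly zero mean / unit variance (fixed affine, so
    train and test inputs are on the same scale without dataset statistics).
    """
    x = (np.stack(patches).astype(np.float32) / 255.0 - 0.5) / 0.25
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def train(model: nn.Sequential, dataset: list[DiscImage],
          config: TrainConfig | None = None) -> tuple[nn.Sequential, TrainHistory]:
    """Train in place; returns the model and per-epoch loss/accuracy history.

    With ``config.augment`` the epoch iterates over all 15 patches of every
    disc (patches inherit the disc's label); otherwise over center crops
    only.  Mini-batches are stratified so each contains glaucomatous
    samples.  Fully deterministic under ``config.seed``.
    """
    config = config or TrainConfig()
    labels_present = {d.label for d in dataset}
    if None in labels_present:
        raise ValidationError("every training disc needs a label")
    if len(labels_present) < 2:
        raise ValidationError("training needs both classes present")

    if config.augment:
        samples = [(di, pi) for di in range(len(dataset)) for pi in range(15)]
    else:
        samples = [(di, -1) for di in range(len(dataset))]
    sample_labels = [dataset[di].label for di, _ in samples]
    targets_all = np.array([CLASSES.index(l) for l in sample_labels])

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model, lr=config.learning_rate)
    history = TrainHistory()
    for epoch in range(config.epochs):
        batch_seed = int(rng.integers(0, 2**31 - 1))
        batches = stratified_batches(
            sample_labels, config.batch_size, config.min_minority_per_batch,
            seed=batch_seed,
        )
        losses, n_correct, n_seen = [], 0, 0
        for batch in batches:
            x = _to_tensor([_patch(dataset[samples[i][0]], samples[i][1]) for i in batch])
            t = targets_all[batch]
            logits = model.forward(x, train=True, rng=rng)
            loss, dlogits = nn.softmax_cross_entropy(logits, t)
            model.backward(dlogits)
            if config.learning_rate > 0:
                opt.step()
            losses.append(loss)
            n_correct += int((logits.argmax(axis=1) == t).sum())
            n_seen += len(t)
        history.loss.append(float(np.mean(losses)))
        history.accuracy.append(100.0 * n_correct / n_seen)
    return model, history


def predict(model: nn.Sequential, discs: list[DiscImage],
            batch_size: int = 32) -> np.ndarray:
    """Per-disc probability of glaucoma, from the center 227x227 crop."""
    out = np.empty(len(discs))
    for i in range(0, len(discs), batch_size):
        chunk = discs[i:i + batch_size]
        x = _to_tensor([center_crop(d.pixels) for d in chunk])
        probs = nn.softmax(model.forward(x, train=False))
        out[i:i + len(chunk)] = probs[:, CLASSES.index("glaucoma")]
    return out


def cross_validate(dataset: list[DiscImage], k: int = 10,
                   config: TrainConfig | None = None,
                   net_spec: NetSpec | None = None, seed: int = 0) -> dict:
    """Stratified k-fold cross-validation of the disc classifier.

    Folds preserve class proportions (plain random folds can leave a
    training partition single-class at small n).  Returns per-fold reports
    and the mean +/- sample standard deviation of accuracy, total
    precision, total F1 and AUC over folds.
    """
    config = config or TrainConfig()
    ids = [f"{i}:{d.image_id}" for i, d in enumerate(dataset)]
    labels = [d.label for d in dataset]
    if None in labels:
        raise ValidationError("every disc needs a label for cross-validation")
    split = stratified_kfold_split(ids, labels, k, seed=seed)
    folds = []
    for fold in range(k):
        test_idx = [i for i, key in enumerate(ids) if split.assignment[key] == fold]
        train_idx = [i for i, key in enumerate(ids) if split.assignment[key] != fold]
        train_set = [dataset[i] for i in train_idx]
        test_set = [dataset[i] for i in test_idx]
        if len({d.label for d in train_set}) < 2:
            raise ValidationError(f"fold {fold}: training partition is single-class")
        fold_config = dataclasses.replace(config, seed=config.seed + fold)
        model = build_network(net_spec, seed=seed + fold)
        model, _ = train(model, train_set, fold_config)
        scores = predict(model, test_set)
        preds = [CLASSES[1] if s >= 0.5 else CLASSES[0] for s in scores]
        test_labels = [d.label for d in test_set]
        entry = {"fold": fold, "n_test": len(test_set)}
        try:
            rep = report(test_labels, preds)
            entry.update(accuracy=rep.accuracy, total_precision=rep.total_precision,
                         total_f1=rep.total_f1)
        except UndefinedMetricError:
            # degenerate fold (a class absent or never predicted): accuracy is
            # still well-defined, weighted metrics are not
            acc = 100.0 * sum(p == l for p, l in zip(preds, test_labels)) / len(test_labels)
            entry.update(accuracy=acc, total_precision=float("nan"),
                         total_f1=float("nan"))
        try:
            entry["auc"] = roc_auc(scores, test_labels).auc
        except ValueError:
            entry["auc"] = float("nan")
        folds.append(entry)
    summary = {}
    for key in ("accuracy", "total_precision", "total_f1", "auc"):
        vals = np.array([f[key] for f in folds], dtype=float)
        summary[key] = {
            "mean": float(np.nanmean(vals)),
            "std": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0,
        }
    return {"folds": folds, "summary": summary, "k": k}
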
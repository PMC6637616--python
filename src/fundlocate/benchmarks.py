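"""Standard desk-scale benchmarks: fixed study conditions, seedable runs.

Two benchmarks are defined once here so tests, examples and the acceptance
script all run identical conditions:

* the **localization suite** — clean synthetic fundus scenes (no fringe, no
  reflections; resolution, illumination, disc geometry and CDR vary per
  image) scored by IOU against exact ground truth, plus a paired
  with/without-fringe robustness variant;
* the **separable CDR benchmark** — disc crops at two well-separated
  cup-to-disc ratios (0.30 vs 0.85, 50/50) on which the reduced-width
  classifier must demonstrate learning from scratch.
"""

from __future__ import annotations

import numpy as np

from . import synthetic
from .classifier import (
    DiscImage,
    NetSpec,
    TrainConfig,
    build_network,
    extract_disc,
    predict,
    train,
)
from .clf_metrics import roc_auc
from .heuristic import HeuristicConfig, localize
from .loc_eval import evaluate

__all__ = [
    "localization_suite_report",
    "fringe_robustness",
    "cdr_benchmark_discs",
    "split_train_test",
    "run_cdr_benchmark",
]


def localization_suite_report(n: int = 200, seed: int = 0,
                              config: HeuristicConfig | None = None):
    """Localize the standard clean suite and score it; returns the report."""
    items, _ = synthetic.standard_suite(n=n, seed=seed)
    preds, gts = {}, {}
    for image, gt in items:
        preds[image.image_id] = localize(image, config).box
        gts[image.image_id] = gt.od_box
    return evaluate(preds, gts, thresholds=(0.2, 0.5, 0.6, 0.7, 0.8))


def fringe_robustness(n_pairs: int = 100, seed: int = 0,
                      extent: float = 120.0, thickness_frac: float = 0.025,
                      config: HeuristicConfig | None = None) -> float:
    """Fraction of image pairs whose predicted disc center moves by at most
    2% of the image width when a rim fringe arc is added.

    The fringe is thinner than the rim crop margin (thickness <= 3% of the
    retina radius), so a robust localizer should barely react to it.
    """
    items, _ = synthetic.standard_suite(n=n_pairs, seed=seed)
    ok = 0
    for image, gt in items:
        clean = localize(image, config)
        fringed_img = synthetic.add_fringe(
            image, gt.retina_circle, extent=extent, brightness=252.0,
            seed=seed, thickness_frac=thickness_frac,
        )
        fringed = localize(fringed_img, config)
        shift = np.hypot(clean.circle.cx - fringed.circle.cx,
                         clean.circle.cy - fringed.circle.cy) / image.width
        ok += shift <= 0.02
    return ok / n_pairs


def cdr_benchmark_discs(n: int = 200, seed: int = 0,
                        cdr_low: float = 0.30, cdr_high: float = 0.85,
                        image_size: int = 512) -> list[DiscImage]:
    """Labelled disc crops at two fixed, well-separated CDR values (50/50)."""
    items, _ = synthetic.generate_dataset(
        n=n,
        ranges={
            "image_size": [image_size],
            "cdr_healthy": (cdr_low, cdr_low),
            "cdr_glaucoma": (cdr_high, cdr_high),
        },
        glaucoma_fraction=0.5,
        seed=seed,
    )
    discs = []
    for image, gt in items:
        disc = extract_disc(image, gt.od_box)
        disc.label = gt.label
        discs.append(disc)
    return discs


def split_train_test(discs: list[DiscImage], train_fraction: float = 0.7,
                     seed: int = 0):
    """Stratified train/test split preserving the class ratio."""
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted({d.label for d in discs}):
        idx = [i for i, d in enumerate(discs) if d.label == label]
        rng.shuffle(idx)
        cut = int(round(train_fraction * len(idx)))
        train_idx += idx[:cut]
        test_idx += idx[cut:]
    return [discs[i] for i in sorted(train_idx)], [discs[i] for i in sorted(test_idx)]


def run_cdr_benchmark(seed: int = 0, n: int = 200, epochs: int = 20,
                      batch_size: int = 4) -> dict:
    """Train the reduced network on the separable CDR benchmark from scratch.

    70/30 stratified split, constant-rate Adam on cross-entropy, stratified
    mini-batches, at most ``epochs`` epochs.  Returns held-out accuracy (%),
    AUC, the training history and the problem size.
    """
    discs = cdr_benchmark_discs(n=n, seed=seed)
    train_set, test_set = split_train_test(discs, train_fraction=0.7, seed=seed)
    model = build_network(NetSpec.reduced(), seed=seed)
    config = TrainConfig(epochs=epochs, batch_size=batch_size,
                         min_minority_per_batch=1, seed=seed)
    model, history = train(model, train_set, config)
    scores = predict(model, test_set)
    labels = [d.label for d in test_set]
    accuracy = 100.0 * float(
        np.mean([(s >= 0.5) == (l == "glaucoma") for s, l in zip(scores, labels)])
    )
    return {
        "accuracy": accuracy,
        "auc": roc_auc(scores, labels).auc,
        "history": history,
        "n_train": len(train_set),
        "n_test": len(test_set),
        "scores": scores,
        "labels": labels,
        "model": model,
    }
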
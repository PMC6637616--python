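# fundlocate

Optic-disc localization and glaucoma-screening toolkit for colour retinal
fundus images.

Glaucoma damages the optic nerve head; its key structural signature in a
fundus photograph is enlargement of the optic cup within the optic disc
(OD), summarized by the cup-to-disc ratio (CDR). Screening pipelines
therefore (1) find the OD — a bright, roughly circular region — and
(2) classify the extracted disc as healthy or glaucomatous. This package
provides a tested implementation of the desk-side of such a pipeline, for
researchers building or evaluating fundus-analysis methods:

* **`fundlocate.synthetic`** — a seedable generator of fundus-like scenes
  (bright retina, elliptical disc with a brighter cup core, radiating
  vessels, rim-fringe and reflection artifacts, noise) with *exact* ground
  truth: disc box, disc circle, CDR, class label. Every other module is
  verifiable against it without downloading any dataset.
* **`fundlocate.heuristic`** — a rule-based OD localizer: Otsu retina
  estimation → circular rim crop → adaptive binarization at the mean of the
  top-1% brightest pixels → disc-element erosion/dilation → largest-blob
  circle proposal, run at a fixed 1500 px working scale and mapped back to
  the input resolution.
* **`fundlocate.annotations`** — the semi-automated ground-truth workflow:
  machine proposals on CSV, human corrections, provenance-tracking merges
  (proposed / corrected / verified), Pascal-VOC XML export for detector
  training.
* **`fundlocate.loc_eval`** — localization scoring: IOU and coverage
  fraction of half-open boxes, accuracy at IOU thresholds (strict >), mean
  overlap, and the weak center-distance (IOU > 0) criterion.
* **`fundlocate.clf_metrics`** — precision/recall/F1/specificity from
  confusion counts, support-weighted report totals, ROC/AUC with exact
  tie handling, sensitivity at a target specificity, k-fold splits.
* **`fundlocate.classifier` / `fundlocate.nn`** — an AlexNet-family CNN
  (4 conv + 3 dense, local response normalization, overlapping 3×3/stride-2
  max-pooling, 0.5 dropout) trained with constant-rate Adam on
  cross-entropy over stratified mini-batches, on 227×227 crops of 256×256
  disc images. The tensor layers and backprop are implemented in numpy and
  gradient-checked; no GPU or autodiff framework is required.

## The core quantities

For boxes *A*, *B* on the pixel grid (half-open, 0-based):

    IOU(A, B) = |A ∩ B| / |A ∪ B|        coverage(P, G) = |P ∩ G| / |G|

Localization accuracy at threshold *t* is the percentage of images with
IOU strictly above *t*. For a class *c* with counts TP, FP, FN, TN:

    precision = TP / (TP + FP)           recall = TP / (TP + FN)
    F1 = 2·P·R / (P + R)                 specificity = TN / (TN + FP)

AUC is the trapezoidal area under sensitivity vs 1−specificity over all
score thresholds, equal to P(score⁺ > score⁻) + ½·P(tie).

## Worked example

`examples/04_classification_metrics.py` rebuilds a screening evaluation
from its raw outcome lists — 412 healthy test images of which 391 were
called healthy, 139 glaucomatous of which 48 were called glaucoma — and
prints:

```
class       precision   recall       f1  support
healthy        81.12%   94.90%   0.8747      412
glaucoma       69.57%   34.53%   0.4615      139
total          78.21%   79.67%   0.7705      551
```

Reading it: among images *called* glaucoma only 69.57% truly were
(precision), and only 34.53% of truly glaucomatous images were found
(recall) — even though overall accuracy looks decent at 79.67%, which is
exactly why imbalanced screening studies must report per-class metrics
rather than accuracy or AUC alone. The total row weights per-class values
by support and shows overall accuracy in the recall column.

`examples/02_localize_optic_disc.py` generates six synthetic images,
localizes the disc and scores it:

```
syn-00000: predicted BoundingBox(x_min=248, y_min=250, x_max=340, y_max=343), IOU 0.936, confidence normal
...
mean IOU 78.1%  accuracy@0.5 100%  accuracy@0.2 100%
```

The other examples cover dataset generation (`01`), the semi-automated
ground-truth workflow (`03`), and training the disc classifier on a small
separable-CDR benchmark (`05`).

A command-line front end wires the same operations into shell workflows:

```sh
fundlocate generate --n 50 --seed 1 --out data/
fundlocate localize --images data/ --out proposals.csv
fundlocate eval-loc --pred proposals.csv --gt data/manifest.csv --out report.json
fundlocate extract-discs --images data/ --gt data/manifest.csv --out discs/
fundlocate train --discs discs/ --epochs 10 --out model/
```

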
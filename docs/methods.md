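# Methods

`fundlocate` implements the desk-side of a two-stage glaucoma-screening
pipeline for colour retinal fundus photographs: rule-based optic-disc (OD)
localization with a semi-automated ground-truth workflow, an IOU-based
localization evaluation protocol, and a CNN classifier that decides
healthy vs glaucomatous from the extracted disc region. A seedable
synthetic-scene generator makes every stage testable without any image
download.

## The synthetic fundus generator

The generator emulates exactly the image properties the rule-based
localizer exploits, not photo-realistic anatomy. A scene consists of:

* a circular **retina** disc of moderate brightness on a dark background
  (radius 0.82–0.96 of the half-width by default, center jittered);
* an elliptical **optic disc** (axis ratio drawn in [0.9, 1.1], random
  orientation) whose brightness *profile* peaks in a specular **cup core**
  and decays smoothly across the neuroretinal rim to the disc boundary.
  The core radius is 0.6 × CDR in normalized disc radius, so its area grows
  as CDR²: that is the class signal. A flat-plateau disc would be wrong
  twice over — real discs are not flat, and a plateau plus pixel noise
  turns any top-percentile threshold into unusable speckle;
* dark **vessels** as quadratic Bézier strips radiating from the disc
  center to the rim, widths tapering from 2–8 px (at a 1500 px scale) to
  1 px. They provide the dark-vessel/bright-disc contrast, not a
  realistic vascular tree;
* optional artifacts: a bright **fringe** arc hugging the retinal rim
  (ambient-light leakage; default thickness 2.5% of the retina radius) and
  bright Gaussian **reflection** blobs placed away from the disc;
* additive Gaussian noise, and per-image variation of resolution,
  illumination levels and geometry through sampling ranges.

Intensity ordering `background < retina < disc rim <= cup` holds in every
noise-free scene; colour is a fixed red-dominant channel mix (R > G > B)
so grayscale-luminance processing stays valid. Labels are `glaucoma` iff
CDR > 0.65 — between the 0.5 clinical screening cut-off and severe
disease; the threshold is configurable. Dataset generation samples CDR
conditionally on the drawn label (healthy 0.25–0.55, glaucomatous
0.70–0.92 by default) so requested class fractions are exact.

Everything is a pure function of the spec (including its seed): identical
specs render bit-identical images.

**What passing tests do and do not show.** The generator provides a
controlled world where the localizer's assumptions (single brightest
compact region ≈ disc) hold by construction, plus the two artifact modes
that break naive thresholding. Success here demonstrates algorithmic
correctness and robustness to those artifacts — not performance on real
fundus images, which add pathology (exudates mimic bright spots), camera
vignetting, and anatomical variation the generator does not model.

## The rule-based localizer

Pipeline (all luminance-based, at a fixed 1500 px working scale so one
parameter set covers any input resolution):

1. **Retina estimate** — Otsu threshold on grayscale luminance; the
   foreground's centroid and equivalent-area radius `sqrt(area/pi)` give
   the retina circle. Less than 1% foreground raises "no retina found".
2. **Rim crop** — zero everything outside 0.95 × retina radius, removing
   the rim and any fringe thinner than 5% of the radius.
3. **Adaptive binarization** — keep pixels at least as bright as the mean
   of the brightest 1% of nonzero pixels. On a fundus-like image only the
   disc core survives.
4. **Morphological cleanup** — erosion (disc radius 2 px) kills impulse
   noise and thin speckle; dilation (radius 10 px) reconnects the disc
   core fragments that vessels split apart.
5. **Proposal** — the largest connected component's centroid and
   equivalent-area radius, inflated by `proposal_scale` (default 1.5),
   define the circle; its tight square box (clipped to the frame) is the
   box output. Area ties break toward the smaller (y, x) centroid.
6. **Mapping back** — the circle is mapped to original coordinates with
   independent x/y scale factors (the radius with their mean).

If the cleaned mask is empty (or the optional `max_disc_radius_frac`
sanity bound trips), the localizer falls back to the centroid of the
brightest 1% of pixels with r = 0.1 × retina radius and flags the record
low-confidence.

**Parameter provenance.** The crop margin, morphology radii, minimum blob
area and `proposal_scale` are empirical. They were fixed once by a small
grid search on a 60-image synthetic validation suite (seed distinct from
every test suite), mirroring how such parameters are tuned on a held-out
validation set in practice; defaults: margin 0.95, erode 2, dilate 10,
scale 1.5, min area 25 px². The 1% brightness fraction is part of the
method definition, not a knob. The grayscale-luminance channel choice
(0.299 R + 0.587 G + 0.114 B) is the neutral default; related approaches
variously prefer the green (contrast) or red (fewer vessels) channel, and
the channel is configurable in principle by pre-mapping the input.

## Localization evaluation

`iou` is intersection-over-union of half-open integer boxes;
`coverage_fraction` is the asymmetric `area(pred ∩ gt)/area(gt)`. Accuracy
at threshold t is the percentage of images with IOU **strictly** above t,
reported on the grid {20, 50, 60, 70, 80}%; the report carries both mean
IOU and mean coverage because prose statements of "average overlap" are
ambiguous between the two. The much weaker center-distance criterion
(centers closer than the expected disc diameter, i.e. IOU > 0; diameter
taken as max(gt width, gt height)) is implemented for comparison with the
older localization literature, not used for headline accuracy. Missing
predictions count as incorrect at every threshold.

## Classification metrics

Precision, recall and specificity are percentages from per-class TP/FP/FN/TN
counts; F1 is the harmonic mean reported on the [0, 1] scale. Report
totals are support-weighted means of per-class precision and F1, with
overall accuracy in the recall column — the convention used by
class-imbalanced screening studies. Undefined metrics (zero denominators)
raise rather than silently returning 0, except F1 at precision = recall
= 0, which is 0 by documented convention.

ROC curves enumerate every distinct score threshold (positive iff
score ≥ t, positive class = glaucoma); AUC is the trapezoid over
sensitivity vs 1−specificity and equals pair concordance with half-credit
for ties (asserted against a brute-force oracle). Sensitivity at a target
specificity uses the conservative step convention: the highest sensitivity
among operating points whose specificity still meets the target, no
interpolation.

k-fold splitting shuffles ids under a seed and deals round-robin (sizes
differ by ≤ 1); the stratified variant deals within class so every fold
preserves class proportions.

## The disc classifier

`extract_disc` crops the (clipped) disc box and resizes to 256×256×3;
inputs to the network are 227×227 crops, standardized by a fixed affine
map to roughly zero mean and unit variance (no dataset statistics, so
train and test inputs are always on the same scale).

The network is a four-conv / three-dense stack in the AlexNet family:
conv1 96@11×11 stride 4 → LRN → overlapping max-pool (3×3, stride 2);
conv2 256@5×5 pad 2 → LRN → pool; conv3 384@3×3 pad 1; conv4 256@3×3
pad 1 → pool; dense 1024 → 1024 → 2 with ReLU after every layer except
the output, dropout 0.5 after the first two dense layers, softmax output.
LRN uses the classical constants (window 5, k = 2, α = 1e-4, β = 0.75,
sum scaled by α/n). Filter counts and dense widths beyond conv1 are
stated nowhere authoritative for this architecture variant; the values
above are the documented assumption, and every piece is configurable
through `NetSpec`.

Because no tensor/autodiff library is part of the supported environment,
the layers, backprop and the Adam optimizer are implemented directly in
numpy (`fundlocate.nn`), with every layer's analytic gradient verified
against central-difference numeric gradients in float64.

**Training protocol.** Constant learning rate 1e-4, Adam, softmax
cross-entropy. Mini-batches are stratified: all samples are shuffled into
batches, and any batch short of `min_minority_per_batch` glaucomatous
samples is topped up by oversampling the minority class — majority
samples appear exactly once per epoch, minority samples may repeat, and a
topped-up batch may exceed the nominal batch size by at most the deficit.
Optional augmentation is the deterministic 15-patch product
{identity, h-flip, v-flip} × {4 corner crops, center crop}; it is off by
default and inference always uses the center crop.

**The reduced benchmark network.** Desk-scale runs use `NetSpec.reduced()`
— identical structure at 1/4 to 1/12 of the full widths (conv
16/32/32/32, dense 256/256/2) — on the separable CDR benchmark: 200
discs at CDR 0.30 vs 0.85 (50/50), stratified 70/30 split, batch size 4,
≤ 20 epochs. The widths were chosen so that the fixed 1e-4 step
size can move the network far enough within that step budget: with very
narrow dense layers the 0.5 dropout noise dominates the few hundred Adam
steps available, which shows up as underfitting rather than
regularization. Cross-validation folds are stratified by class — plain
random folds can leave a training partition single-class at small n;
degenerate per-fold metrics (a class never predicted) are recorded as NaN
and excluded from fold means.

## Numerical and degenerate-input choices

* Box convention 0-based half-open everywhere; the 1-based inclusive
  Pascal-VOC convention exists only at the XML import/export boundary.
* Rescaling uses bilinear interpolation for images; masks are never
  rescaled (morphology happens at the working scale).
* Otsu on a constant image is undefined; a constant bright frame counts
  entirely as foreground, a black frame has no retina.
* Adaptive binarization requires ≥ 100 nonzero pixels so the top-1% set
  is nonempty; the threshold uses `>=` so a perfectly flat image is
  all-foreground.
* Morphology and component labeling run on the mask's tight bounding
  window; results equal full-frame operation (asserted in tests).
* `learning_rate = 0` is accepted and provably freezes the weights
  (used as a harness sanity check).

## Known limitations

* The generator's vessels do not branch and its illumination field is
  flat; methods that rely on vessel convergence or vignetting structure
  cannot be evaluated against it.
* The localizer's accuracy floor is demonstrated on synthetic scenes
  designed to satisfy its core assumption; real-data accuracy requires
  real annotated images and the full two-stage pipeline (the detector
  stage is out of scope here — the `Localizer`-style contract is the
  heuristic's call signature, which an external detector can satisfy).
* The CNN harness is CPU-bound numpy; it is sized for hundreds of discs,
  not for training at archive scale.
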
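"""Localize the optic disc with the rule-based algorithm and score it.

The localizer estimates the retina by Otsu thresholding, crops the rim (and
any bright fringe on it), binarizes at the mean of the top-1% brightest
pixels, cleans the mask with erosion/dilation, and proposes a circle around
the largest remaining blob.  Scores are IOU against the generator's exact
ground truth.
"""

import fundlocate as fl

items, _ = fl.generate_dataset(n=6, glaucoma_fraction=0.5, seed=11)

preds, gts = {}, {}
for image, gt in items:
    result = fl.localize(image)
    preds[image.image_id] = result.box
    gts[image.image_id] = gt.od_box
    print(f"{image.image_id}: predicted {result.box}, "
          f"IOU {fl.iou(result.box, gt.od_box):.3f}, confidence {result.confidence}")

report = fl.evaluate(preds, gts, thresholds=(0.2, 0.5, 0.7))
print()
print(f"mean IOU {report.mean_iou:.1f}%  "
      f"accuracy@0.5 {report.accuracy_at[0.5]:.0f}%  "
      f"accuracy@0.2 {report.accuracy_at[0.2]:.0f}%")
print("accuracy@t is the percentage of images whose predicted box overlaps")
print("the true disc box with IOU strictly above t.")
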
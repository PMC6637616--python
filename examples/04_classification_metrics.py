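"""Screening-evaluation metrics from a recorded confusion outcome.

Re-creates a classifier evaluation from its raw outcome lists: 412 healthy
test images of which 391 were called healthy, and 139 glaucomatous images
of which 48 were called glaucoma.  Prints per-class precision/recall/F1,
support-weighted totals, and overall accuracy.
"""

import fundlocate as fl

labels = ["healthy"] * 412 + ["glaucoma"] * 139
preds = ["healthy"] * 391 + ["glaucoma"] * 21 + ["glaucoma"] * 48 + ["healthy"] * 91

rep = fl.report(labels, preds)
print(f"{'class':<10} {'precision':>10} {'recall':>8} {'f1':>8} {'support':>8}")
for cls, m in rep.per_class.items():
    print(f"{cls:<10} {m.precision:>9.2f}% {m.recall:>7.2f}% {m.f1:>8.4f} {m.support:>8}")
print(f"{'total':<10} {rep.total_precision:>9.2f}% {rep.accuracy:>7.2f}% "
      f"{rep.total_f1:>8.4f} {rep.n:>8}")
print()
print("Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean;")
print("the total row weights per-class precision and F1 by class support and")
print("reports overall accuracy in the recall column, as screening studies do.")

counts = fl.confusion(labels, preds)
print(f"\nspecificity toward glaucoma: {fl.specificity(counts, 'glaucoma'):.2f}% "
      "(= healthy recall, by binary complementarity)")
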
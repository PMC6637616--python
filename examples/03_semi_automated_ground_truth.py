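"""The semi-automated ground-truth workflow: propose, correct, merge, export.

Machine proposals are saved to CSV; a human reviewer corrects the few
failures and explicitly accepts the rest; the merge records provenance
(proposed / corrected / verified) per image; verified annotations export to
Pascal-VOC XML for detector training.
"""

import tempfile
from pathlib import Path

import fundlocate as fl
from fundlocate.annotations import (
    AnnotationRecord, export_voc_xml, load_annotations, merge_corrections,
    save_annotations,
)

workdir = Path(tempfile.mkdtemp())
items, _ = fl.generate_dataset(n=5, seed=2)

proposals = []
for image, _ in items:
    result = fl.localize(image)
    proposals.append(AnnotationRecord(
        image_id=image.image_id, box=result.box, circle=result.circle,
        status="proposed", confidence=result.confidence,
    ))
save_annotations(proposals, workdir / "proposals.csv")

# the reviewer corrects one box and accepts the others as-is
corrections = [AnnotationRecord("syn-00000", fl.BoundingBox(10, 10, 120, 120))]
corrections += [
    AnnotationRecord(p.image_id, p.box, status="verified") for p in proposals[1:]
]
merged = merge_corrections(load_annotations(workdir / "proposals.csv"), corrections)

for rec in merged:
    print(f"{rec.image_id}: status={rec.status}")

xml_paths = export_voc_xml(merged, workdir, workdir / "voc")
print(f"\n{len(xml_paths)} VOC XML files written (1-based inclusive boxes,")
print('object name "optic_disc") — the dialect detector-training pipelines expect.')
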
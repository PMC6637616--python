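"""Annotation data model and I/O for the semi-automated ground-truth workflow.

Machine proposals are written to CSV, a human reviews them, and the review
outcome (corrected boxes and explicit acceptances) is merged back to produce
verified ground truth.  Provenance is tracked per record: ``proposed`` (raw
machine output), ``corrected`` (human replaced or re-asserted the box) and
``verified`` (human accepted the proposal as-is).

CSV schema (UTF-8, comma-separated, header mandatory)::

    image_id,x_min,y_min,x_max,y_max,cx,cy,r,status,confidence,note

Coordinates are 0-based half-open throughout the package; the 1-based
inclusive Pascal-VOC convention appears only in the XML export/import
(``xmin = x_min + 1`` on the way out, ``x_max = xmax`` unchanged).
Unknown CSV columns are preserved across a load/save round-trip.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .types import BoundingBox, CircleProposal, ValidationError

__all__ = [
    "AnnotationRecord",
    "save_annotations",
    "load_annotations",
    "merge_corrections",
    "export_voc_xml",
    "import_voc_xml",
    "CSV_COLUMNS",
]

CSV_COLUMNS = [
    "image_id", "x_min", "y_min", "x_max", "y_max",
    "cx", "cy", "r", "status", "confidence", "note",
]

STATUSES = ("proposed", "corrected", "verified")
CONFIDENCES = ("normal", "low")


@dataclass
class AnnotationRecord:
    """One image's OD location with provenance."""

    image_id: str
    box: BoundingBox
    circle: CircleProposal | None = None
    status: str = "proposed"
    confidence: str = "normal"
    note: str = ""
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.image_id:
            raise ValidationError("image_id must be non-empty")
        if self.status not in STATUSES:
            raise ValidationError(f"invalid status {self.status!r} (expected one of {STATUSES})")
        if self.confidence not in CONFIDENCES:
            raise ValidationError(
                f"invalid confidence {self.confidence!r} (expected one of {CONFIDENCES})"
            )


def _check_unique(records: list[AnnotationRecord], where: str) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.image_id in seen:
            raise ValidationError(f"duplicate image_id {rec.image_id!r} in {where}")
        seen.add(rec.image_id)


def save_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    """Write records as CSV; extra per-record columns are appended after the
    standard schema."""
    _check_unique(records, "records")
    extra_cols: list[str] = []
    for rec in records:
        for k in rec.extras:
            if k not in extra_cols:
                extra_cols.append(k)
    rows = []
    for rec in records:
        row = {
            "image_id": rec.image_id,
            "x_min": rec.box.x_min, "y_min": rec.box.y_min,
            "x_max": rec.box.x_max, "y_max": rec.box.y_max,
            "cx": rec.circle.cx if rec.circle else "",
            "cy": rec.circle.cy if rec.circle else "",
            "r": rec.circle.r if rec.circle else "",
            "status": rec.status,
            "confidence": rec.confidence,
            "note": rec.note,
        }
        for k in extra_cols:
            row[k] = rec.extras.get(k, "")
        rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS + extra_cols).to_csv(path, index=False)


def load_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation CSV; malformed rows raise with their line number."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    extra_cols = [c for c in df.columns if c not in CSV_COLUMNS]
    records: list[AnnotationRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            box = BoundingBox(
                int(row["x_min"]), int(row["y_min"]),
                int(row["x_max"]), int(row["y_max"]),
            )
            circle = None
            if str(row["cx"]).strip() != "":
                circle = CircleProposal(float(row["cx"]), float(row["cy"]), float(row["r"]))
            rec = AnnotationRecord(
                image_id=str(row["image_id"]),
                box=box,
                circle=circle,
                status=str(row["status"]),
                confidence=str(row["confidence"]) or "normal",
                note=str(row["note"]),
                extras={k: row[k] for k in extra_cols},
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path} line {line_no}: {exc}") from exc
        records.append(rec)
    _check_unique(records, str(path))
    return records


def merge_corrections(
    proposals: list[AnnotationRecord], corrections: list[AnnotationRecord]
) -> list[AnnotationRecord]:
    """Merge human review output into machine proposals.

    A correction record with ``status == "verified"`` is an explicit
    acceptance: the proposal's own box is kept and its status becomes
    ``verified``.  Any other correction record replaces the box (even if
    geometrically identical — provenance, not geometry) and sets status
    ``corrected``.  Proposals without a matching correction stay as they
    are.  Output order and count equal the proposals'.  Idempotent: merging
    the same corrections twice equals merging once.
    """
    _check_unique(proposals, "proposals")
    _check_unique(corrections, "corrections")
    by_id = {rec.image_id: rec for rec in proposals}
    for corr in corrections:
        if corr.image_id not in by_id:
            raise ValidationError(f"correction for unknown image_id {corr.image_id!r}")
    merged: list[AnnotationRecord] = []
    corr_by_id = {c.image_id: c for c in corrections}
    for prop in proposals:
        corr = corr_by_id.get(prop.image_id)
        if corr is None:
            merged.append(prop)
        elif corr.status == "verified":
            merged.append(AnnotationRecord(
                image_id=prop.image_id, box=prop.box, circle=prop.circle,
                status="verified", confidence=prop.confidence,
                note=corr.note or prop.note, extras=dict(prop.extras),
            ))
        else:
            merged.append(AnnotationRecord(
                image_id=prop.image_id, box=corr.box, circle=corr.circle or prop.circle,
                status="corrected", confidence=prop.confidence,
                note=corr.note or prop.note, extras=dict(prop.extras),
            ))
    return merged


def export_voc_xml(
    records: list[AnnotationRecord],
    image_dir: str | Path,
    out_dir: str | Path,
    allow_proposed: bool = False,
) -> list[Path]:
    """Write one Pascal-VOC-style XML per record (object name "optic_disc").

    The dialect is 1-based inclusive, so ``xmin = x_min + 1`` and
    ``xmax = x_max`` (a half-open upper bound equals an inclusive 1-based
    one).  Records still in ``proposed`` status are refused unless
    ``allow_proposed`` — exported boxes are supposed to be ground truth.
    """
    _check_unique(records, "records")
    if not allow_proposed:
        bad = [r.image_id for r in records if r.status == "proposed"]
        if bad:
            raise ValidationError(
                f"{len(bad)} record(s) still 'proposed' (e.g. {bad[0]!r}); "
                "verify/correct them or pass allow_proposed=True"
            )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for rec in records:
        root = ET.Element("annotation")
        ET.SubElement(root, "folder").text = str(image_dir)
        ET.SubElement(root, "filename").text = f"{rec.image_id}.png"
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = "optic_disc"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(rec.box.x_min + 1)
        ET.SubElement(bnd, "ymin").text = str(rec.box.y_min + 1)
        ET.SubElement(bnd, "xmax").text = str(rec.box.x_max)
        ET.SubElement(bnd, "ymax").text = str(rec.box.y_max)
        path = out_dir / f"{rec.image_id}.xml"
        ET.ElementTree(root).write(path, encoding="unicode")
        written.append(path)
    return written


def import_voc_xml(path: str | Path) -> AnnotationRecord:
    """Read one exported XML back into an internal (0-based half-open) record."""
    tree = ET.parse(path)
    image_id = Path(tree.findtext("filename", default=Path(path).stem)).stem
    bnd = tree.find("./object/bndbox")
    if bnd is None:
        raise ValidationError(f"{path}: no object/bndbox element")
    box = BoundingBox(
        int(bnd.findtext("xmin")) - 1,
        int(bnd.findtext("ymin")) - 1,
        int(bnd.findtext("xmax")),
        int(bnd.findtext("ymax")),
    )
    return AnnotationRecord(image_id=image_id, box=box, status="verified")
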
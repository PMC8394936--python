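"""Annotation CSV dialect, image I/O and result export.

One annotation record is one point on one image: centroid, class, optional
detection score/confidence, optional central-pair angle and its provenance
(predicted / manual / ground_truth).  The CSV dialect is comma-separated
UTF-8 with a header row and '.' decimals; an unmeasured angle (the -1
sentinel) is written as "-0", following the display convention for failed
measurements, and parsed back as failure.

``export_results`` writes one CSV per analysed image plus a joint
statistics file whose class counts are the exact sums of the per-image
counts and whose angle summary is recomputed on the pooled valid angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .angles import SENTINEL, SENTINEL_DISPLAY, AngleMeasurement, summarize_angles
from .synth import CLASS_NAMES

ANNOTATION_COLUMNS = ["image_id", "x", "y", "class", "score", "confident",
                      "angle_deg", "source"]
SOURCES = ("predicted", "manual", "ground_truth")

__all__ = [
    "ANNOTATION_COLUMNS",
    "AnnotationRecord",
    "read_annotations",
    "write_annotations",
    "read_image",
    "write_image",
    "export_results",
    "records_from_detections",
    "records_from_scene",
]


@dataclass
class AnnotationRecord:
    """One annotated point; ``angle_deg`` of -1 means measurement failure."""

    image_id: str
    x: float
    y: float
    cls: str
    score: float | None = None
    confident: bool | None = None
    angle_deg: float | None = None
    source: str = "predicted"

    def __post_init__(self) -> None:
        if self.cls not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.cls!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


def _format_angle(angle: float | None) -> str:
    if angle is None:
        return ""
    if angle == SENTINEL:
        return SENTINEL_DISPLAY
    return repr(float(angle))


def _parse_angle(text: str):
    if text == "" or text is None:
        return None
    if text.strip() in (SENTINEL_DISPLAY, "−0"):  # ASCII or minus sign
        return SENTINEL
    return float(text)


def write_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    """Write records in the annotation CSV dialect (lossless round trip)."""
    rows = []
    for r in records:
        rows.append({
            "image_id": r.image_id,
            "x": repr(float(r.x)),
            "y": repr(float(r.y)),
            "class": r.cls,
            "score": "" if r.score is None else repr(float(r.score)),
            "confident": "" if r.confident is None else str(bool(r.confident)),
            "angle_deg": _format_angle(r.angle_deg),
            "source": r.source,
        })
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation CSV; malformed rows raise with their row index."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(AnnotationRecord(
                image_id=row["image_id"],
                x=float(row["x"]),
                y=float(row["y"]),
                cls=row["class"],
                score=None if row["score"] == "" else float(row["score"]),
                confident=(None if row["confident"] == ""
                           else row["confident"] == "True"),
                angle_deg=_parse_angle(row["angle_deg"]),
                source=row["source"],
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: bad annotation in row {i}: {exc}") from exc
    return records


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image (PNG/TIFF)."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img.astype(np.uint8)


def write_image(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


# ---------------------------------------------------------------------------
# conversions

def records_from_detections(detections, image_id: str) -> list[AnnotationRecord]:
    out = []
    for d in detections:
        cx, cy = d.centroid
        out.append(AnnotationRecord(image_id=image_id, x=cx, y=cy,
                                    cls=d.class_label, score=d.score,
                                    confident=d.confident, source="predicted"))
    return out


def records_from_scene(scene) -> list[AnnotationRecord]:
    return [AnnotationRecord(image_id=scene.image_id, x=s.center[0],
                             y=s.center[1], cls=s.class_name,
                             angle_deg=s.angle_deg, source="ground_truth")
            for s in scene.specs]


# ---------------------------------------------------------------------------
# export

def _class_counts(records: list[AnnotationRecord]) -> dict[str, int]:
    counts = {c: 0 for c in CLASS_NAMES}
    for r in records:
        counts[r.cls] += 1
    return counts


def export_results(per_image: dict[str, list[AnnotationRecord]],
                   out_dir: str | Path) -> dict[str, Path]:
    """Write one annotation CSV per image plus joint statistics.

    The joint statistics file carries, per image and pooled: the class
    counts (the joint row is the exact sum of the per-image rows) and the
    re-referenced angle summary recomputed over the pooled valid angles.
    Returns the written paths keyed by image id plus ``"joint"``.
    """
    if not per_image:
        raise ValueError("no analysed images to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stat_rows = []
    pooled_angles: list[float] = []
    total = {c: 0 for c in CLASS_NAMES}
    for image_id in sorted(per_image):
        records = per_image[image_id]
        path = out_dir / f"{image_id}.csv"
        write_annotations(records, path)
        written[image_id] = path
        counts = _class_counts(records)
        for c in CLASS_NAMES:
            total[c] += counts[c]
        valid = [r.angle_deg for r in records
                 if r.angle_deg is not None and r.angle_deg != SENTINEL]
        failed = sum(1 for r in records if r.angle_deg == SENTINEL)
        row = {"image_id": image_id, **counts,
               "n_points": len(records), "n_angle_failures": failed}
        if valid:
            ms = [AngleMeasurement(i, a) for i, a in enumerate(valid)]
            aset = summarize_angles(ms)
            row["mean_angle_deg"] = aset.mean_deg
            row["angle_range_deg"] = float(np.nanmax(aset.normalized_deg))
            pooled_angles.extend(valid)
        else:
            row["mean_angle_deg"] = ""
            row["angle_range_deg"] = ""
        stat_rows.append(row)

    joint = {"image_id": "joint", **total,
             "n_points": sum(r["n_points"] for r in stat_rows),
             "n_angle_failures": sum(r["n_angle_failures"] for r in stat_rows)}
    if pooled_angles:
        ms = [AngleMeasurement(i, a) for i, a in enumerate(pooled_angles)]
        aset = summarize_angles(ms)
        joint["mean_angle_deg"] = aset.mean_deg
        joint["angle_range_deg"] = float(np.nanmax(aset.normalized_deg))
    else:
        joint["mean_angle_deg"] = ""
        joint["angle_range_deg"] = ""
    stat_rows.append(joint)
    joint_path = out_dir / "joint_statistics.csv"
    pd.DataFrame(stat_rows).to_csv(joint_path, index=False)
    written["joint"] = joint_path
    return written
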
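"""Activation–mask overlap: hit decisions, IoU, and stratified count tables.

The interpretability question is binary per (image, lesion type): did
the classifier's high-activation region touch that lesion at all?  A
"hit" is any non-empty pixel-wise AND between the thresholded
activation map and the lesion mask — the amount of overlap is
deliberately not scored, because coarse (Grad-CAM) and diffuse (IG)
maps make exact boundary agreement with small lesions uninformative.
IoU is still recorded per record for reference.

Counts are aggregated per (DR grade, prediction correctness, lesion
type) so that attention patterns can be compared between images the
classifier got right and wrong.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .heatmap_ops import (
    BinaryActivationMap,
    Heatmap,
    ThresholdSpec,
    percentile_threshold,
)
from .mask_ops import LesionMask

__all__ = [
    "OverlapRecord",
    "intersect",
    "evaluate_image",
    "build_overlap_table",
    "records_to_frame",
]


@dataclass
class OverlapRecord:
    """Per (image, method, lesion type) overlap outcome."""

    image_id: str
    method: str
    lesion_type: str
    hit: bool
    intersection_pixels: int
    iou: float
    grade: int = -1
    correct: bool = False
    both_empty: bool = False


def intersect(
    a: BinaryActivationMap, m: LesionMask, image_id: str = "", method: str = ""
) -> OverlapRecord:
    """Pixel-wise AND of activation map and mask.

    hit is true iff the intersection is non-empty; IoU is
    |A AND M| / |A OR M|, defined as 0 (and flagged) when both sets are
    empty.
    """
    if a.values.shape != m.values.shape:
        raise ValueError(
            f"activation shape {a.values.shape} != mask shape {m.values.shape}"
        )
    inter = int(np.sum((a.values > 0) & (m.values > 0)))
    union = int(np.sum((a.values > 0) | (m.values > 0)))
    both_empty = union == 0
    iou = 0.0 if both_empty else inter / union
    return OverlapRecord(
        image_id=image_id,
        method=method,
        lesion_type=m.lesion_type,
        hit=inter > 0,
        intersection_pixels=inter,
        iou=iou,
        both_empty=both_empty,
    )


def evaluate_image(
    image_id: str,
    masks: list[LesionMask],
    heatmaps: dict[str, Heatmap],
    grade: int,
    predicted_grade: int,
    percentiles: dict[str, float] | None = None,
    methods: tuple[str, ...] = ("gradcam", "ig"),
) -> list[OverlapRecord]:
    """One overlap record per (method, lesion type) for a single image.

    Each method's heatmap is binarized at its own percentile (Grad-CAM
    90th, IG 97th by default) before intersecting with every mask.
    """
    for method in methods:
        if method not in heatmaps:
            raise KeyError(f"no heatmap supplied for method {method!r}")
    if not masks:
        warnings.warn(f"no masks supplied for image {image_id!r}", stacklevel=2)
        return []
    records = []
    correct = grade == predicted_grade
    for method in methods:
        p = (percentiles or {}).get(method)
        spec = ThresholdSpec(p) if p is not None else ThresholdSpec.for_method(method)
        amap = percentile_threshold(heatmaps[method], spec)
        for mask in masks:
            rec = intersect(amap, mask, image_id=image_id, method=method)
            rec.grade = int(grade)
            rec.correct = correct
            records.append(rec)
    return records


def records_to_frame(records: list[OverlapRecord]) -> pd.DataFrame:
    """Flatten records to the CSV schema used throughout the pipeline."""
    return pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "method": r.method,
                "lesion": r.lesion_type,
                "grade": r.grade,
                "correct": r.correct,
                "hit": r.hit,
                "intersection_pixels": r.intersection_pixels,
                "iou": r.iou,
            }
            for r in records
        ]
    )


def build_overlap_table(records: list[OverlapRecord] | pd.DataFrame) -> pd.DataFrame:
    """Stratified hit counts per (method, grade, correctness, lesion).

    Returns a long-format frame with one row per stratum and lesion:
    method, grade, correct, lesion, n_images (stratum total), n_hit.
    Empty strata are rendered as '-' only at report time; here they are
    simply absent.  Duplicate records for one (image, method, lesion)
    are a data error.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        return pd.DataFrame(
            columns=["method", "grade", "correct", "lesion", "n_images", "n_hit"]
        )
    dupes = df.duplicated(subset=["image_id", "method", "lesion"], keep=False)
    if dupes.any():
        conflicting = df[dupes].groupby(["image_id", "method", "lesion"])["hit"].nunique()
        if (conflicting > 1).any():
            bad = conflicting[conflicting > 1].index.tolist()
            raise ValueError(f"inconsistent duplicate overlap records for {bad}")
        df = df.drop_duplicates(subset=["image_id", "method", "lesion"])
    rows = []
    for (method, grade, correct, lesion), group in df.groupby(
        ["method", "grade", "correct", "lesion"], sort=True
    ):
        rows.append(
            {
                "method": method,
                "grade": int(grade),
                "correct": bool(correct),
                "lesion": lesion,
                "n_images": int(group["image_id"].nunique()),
                "n_hit": int(group["hit"].sum()),
            }
        )
    return pd.DataFrame(rows)


def render_overlap_table(table: pd.DataFrame) -> pd.DataFrame:
    """Wide rendering: one row per (method, grade), hit counts per lesion
    split into correct / incorrect columns; empty strata shown as '-'."""
    if table.empty:
        return table
    lesions = sorted(table["lesion"].unique())
    rows = []
    for (method, grade), g in table.groupby(["method", "grade"]):
        row: dict = {"method": method, "grade": grade}
        for correct, tag in ((True, "correct"), (False, "incorrect")):
            sub = g[g["correct"] == correct]
            total = int(sub["n_images"].max()) if not sub.empty else 0
            row[f"{tag}_total"] = total if total else "-"
            for lesion in lesions:
                cell = sub[sub["lesion"] == lesion]
                row[f"{tag}_{lesion}"] = (
                    int(cell["n_hit"].iloc[0]) if not cell.empty else "-"
                )
        rows.append(row)
    return pd.DataFrame(rows)
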
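"""Pooled per-class IoU / mIoU and canopy-coverage statistics.

mIoU here pools intersections and unions across all evaluated images per
class *before* dividing (dataset-level pooling), then averages the two
class IoUs — not the mean of per-image IoUs. With strong class imbalance
and uneven dataset sizes the two definitions differ materially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DimensionError, ParameterError
from .imgio import validate_mask

__all__ = ["EvalReport", "miou", "iou", "canopy_coverage", "coverage_histogram"]

_CLASSES = (0, 1)  # background, crop


@dataclass
class EvalReport:
    """Pooled evaluation over N mask pairs and C = 2 classes."""

    iou_background: float
    iou_crop: float
    miou: float
    n: int
    per_group: dict[str, "EvalReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "iou_background": self.iou_background,
            "iou_crop": self.iou_crop,
            "miou": self.miou,
            "n": self.n,
        }
        if self.per_group:
            d["per_group"] = {k: v.to_dict() for k, v in self.per_group.items()}
        return d


def iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Foreground IoU of a single mask pair (convenience for experiments)."""
    pred, gt = validate_mask(pred), validate_mask(gt)
    if pred.shape != gt.shape:
        raise DimensionError(f"shape mismatch {pred.shape} vs {gt.shape}")
    union = np.logical_or(pred, gt).sum()
    return 1.0 if union == 0 else float(np.logical_and(pred, gt).sum() / union)


def _pooled(preds: Sequence[np.ndarray], gts: Sequence[np.ndarray]) -> EvalReport:
    inter = np.zeros(2)
    union = np.zeros(2)
    for p, g in zip(preds, gts):
        for c in _CLASSES:
            pc, gc = p == c, g == c
            inter[c] += np.logical_and(pc, gc).sum()
            union[c] += np.logical_or(pc, gc).sum()
    # a class absent from both pred and gt everywhere scores 1 by convention
    ious = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return EvalReport(
        iou_background=float(ious[0]),
        iou_crop=float(ious[1]),
        miou=float(ious.mean()),
        n=len(preds),
    )


def miou(
    preds: Sequence[np.ndarray],
    gts: Sequence[np.ndarray],
    groups: Sequence[str] | None = None,
) -> EvalReport:
    """Pooled two-class mIoU over a list of predicted/ground-truth masks.

    When ``groups`` is given, a per-group breakdown (same pooled
    definition on each subset) is attached to the report.
    """
    if len(preds) != len(gts):
        raise DimensionError(f"{len(preds)} predictions vs {len(gts)} ground truths")
    if len(preds) == 0:
        raise ParameterError("need at least one mask pair")
    preds = [validate_mask(p) for p in preds]
    gts = [validate_mask(g) for g in gts]
    for p, g in zip(preds, gts):
        if p.shape != g.shape:
            raise DimensionError(f"shape mismatch {p.shape} vs {g.shape}")
    report = _pooled(preds, gts)
    if groups is not None:
        if len(groups) != len(preds):
            raise DimensionError("groups length must match mask count")
        for tag in dict.fromkeys(groups):
            sel = [k for k, t in enumerate(groups) if t == tag]
            report.per_group[str(tag)] = _pooled(
                [preds[k] for k in sel], [gts[k] for k in sel]
            )
    return report


def canopy_coverage(mask: np.ndarray) -> float:
    """Fraction of image pixels labeled crop."""
    return float(validate_mask(mask).mean())


def coverage_histogram(
    masks: Sequence[np.ndarray], bins: Sequence[float]
) -> np.ndarray:
    """Count masks per coverage bin.

    ``bins`` are strictly increasing breakpoints over [0, 1] defining
    half-open bins [lo, hi); the last bin is closed at its upper edge.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.size < 2 or (np.diff(bins) <= 0).any() or bins[0] < 0 or bins[-1] > 1:
        raise ParameterError("bins must be strictly increasing within [0, 1]")
    cov = np.array([canopy_coverage(m) for m in masks])
    if cov.size == 0:
        return np.zeros(bins.size - 1, dtype=int)
    counts, _ = np.histogram(cov, bins=bins)
    return counts.astype(int)
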
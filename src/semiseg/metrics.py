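"""Segmentation evaluation metrics.

Overlap metrics (Dice, IoU) and surface-distance metrics (95th-percentile
Hausdorff distance, average surface distance) between binary masks, plus a
per-class reduction for integer label maps.

Conventions
-----------
* Boundary points are foreground voxels with at least one face-adjacent
  background neighbour (4-connectivity in 2-D, 6-connectivity in 3-D);
  faces on the array border count as background.
* The 95th percentile interpolates linearly between order statistics.
* Dice(empty, empty) = IoU(empty, empty) = 1; surface metrics are
  undefined (NaN, flagged) whenever either mask is empty — never
  silently zero.
* Distances are in voxel units unless per-axis ``spacing`` is given, in
  which case coordinates are scaled to physical units first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = ["dice_score", "iou_score", "boundary_points", "hd95", "asd",
           "evaluate_volume", "MetricsReport"]


def _check_pair(m1, m2):
    m1 = np.asarray(m1).astype(bool)
    m2 = np.asarray(m2).astype(bool)
    if m1.shape != m2.shape:
        raise ValueError(f"mask shapes differ: {m1.shape} vs {m2.shape}")
    return m1, m2


def dice_score(m1, m2) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1 when both masks are empty."""
    m1, m2 = _check_pair(m1, m2)
    total = int(m1.sum()) + int(m2.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((m1 & m2).sum()) / total


def iou_score(m1, m2) -> float:
    """Jaccard overlap |A∩B| / |A∪B|; 1 when both masks are empty."""
    m1, m2 = _check_pair(m1, m2)
    union = int((m1 | m2).sum())
    if union == 0:
        return 1.0
    return int((m1 & m2).sum()) / union


def boundary_points(mask) -> np.ndarray:
    """Coordinates (K, ndim) of the face-connected outer foreground shell."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("boundary of an empty mask is undefined")
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~interior)


def _surface_distances(m1, m2, spacing=None):
    """Nearest boundary-to-boundary distances, both directions."""
    p1 = boundary_points(m1).astype(float)
    p2 = boundary_points(m2).astype(float)
    if spacing is not None:
        spacing = np.asarray(spacing, dtype=float)
        if spacing.shape != (p1.shape[1],) or (spacing <= 0).any():
            raise ValueError("spacing must be positive, one entry per axis")
        p1 = p1 * spacing
        p2 = p2 * spacing
    d12 = cKDTree(p2).query(p1)[0]
    d21 = cKDTree(p1).query(p2)[0]
    return d12, d21


def hd95(m1, m2, spacing=None) -> float:
    """Symmetric 95th-percentile Hausdorff distance between mask boundaries."""
    m1, m2 = _check_pair(m1, m2)
    d12, d21 = _surface_distances(m1, m2, spacing)
    return float(max(np.percentile(d12, 95), np.percentile(d21, 95)))


def asd(m1, m2, spacing=None) -> float:
    """Average symmetric surface distance, normalised by total boundary size."""
    m1, m2 = _check_pair(m1, m2)
    d12, d21 = _surface_distances(m1, m2, spacing)
    return float((d12.sum() + d21.sum()) / (d12.size + d21.size))


@dataclass
class MetricsReport:
    """Per-class and mean segmentation scores.

    ``per_class`` maps class label -> {dice, iou, hd95, asd}; surface
    metrics are NaN when undefined.  Aggregates are unweighted means over
    evaluable classes (background excluded); ``undefined_classes`` lists
    labels absent from both masks, excluded from every mean.
    """

    per_class: dict[int, dict[str, float]] = field(default_factory=dict)
    dice: float = float("nan")
    iou: float = float("nan")
    hd95: float = float("nan")
    asd: float = float("nan")
    undefined_classes: list[int] = field(default_factory=list)


def evaluate_volume(pred_mask, gt_mask, classes=None, spacing=None) -> MetricsReport:
    """One-vs-rest metrics per foreground class of two integer label maps."""
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    if classes is None:
        present = np.union1d(np.unique(pred), np.unique(gt))
        classes = [int(c) for c in present if c != 0]
    report = MetricsReport()
    for cls in classes:
        p = pred == cls
        g = gt == cls
        if not p.any() and not g.any():
            report.undefined_classes.append(cls)
            continue
        row = {"dice": dice_score(p, g), "iou": iou_score(p, g)}
        if p.any() and g.any():
            row["hd95"] = hd95(p, g, spacing)
            row["asd"] = asd(p, g, spacing)
        else:
            row["hd95"] = float("nan")
            row["asd"] = float("nan")
        report.per_class[cls] = row
    if report.per_class:
        for key in ("dice", "iou", "hd95", "asd"):
            vals = [row[key] for row in report.per_class.values()]
            finite = [v for v in vals if np.isfinite(v)]
            setattr(report, key, float(np.mean(finite)) if finite else float("nan"))
    return report
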
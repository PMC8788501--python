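"""Segmentation evaluation metrics: overlap, boundary distance, paired tests.

* ``dsc`` — Dice similarity coefficient 2|A∩B| / (|A|+|B|),
* ``iou`` — intersection over union |A∩B| / |A∪B|,
* ``hd95`` — 95th percentile of the pooled symmetric boundary nearest-point
  distances (``hausdorff`` gives the classical maximum),
* ``paired_compare`` — two-sided paired t-test on per-case metric values.

Boundaries are foreground pixels with at least one background neighbor under
4-connectivity (6-connectivity in 3D); pixels on the image edge count as
boundary.  Distances are Euclidean in physical units given a per-axis
``spacing`` (default 1, i.e. pixel units); percentiles use linear
interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, EmptyMaskError, InvalidInputError

__all__ = [
    "dsc", "iou", "hd95", "hausdorff", "boundary_points",
    "paired_compare", "evaluate_cases", "MetricReport",
]


def _as_binary(mask) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim not in (2, 3):
        raise InvalidInputError(f"mask must be 2D or 3D, got ndim {mask.ndim}")
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise InvalidInputError("mask must be strictly binary (values 0/1)")
    return mask.astype(bool)


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_binary(a), _as_binary(b)
    if a.shape != b.shape:
        raise InvalidInputError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dsc(a, b) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    a, b = _check_pair(a, b)
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / total


def iou(a, b) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    a, b = _check_pair(a, b)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(a, b).sum()) / union


def boundary_points(mask) -> np.ndarray:
    """(n_points, ndim) coordinates of foreground pixels with a background
    4-neighbor (6-neighbor in 3D); image-edge foreground counts as boundary."""
    mask = _as_binary(mask)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~interior)


def _boundary_distances(a, b, spacing) -> np.ndarray:
    """Pooled directed nearest-point distances between the two boundaries."""
    a, b = _check_pair(a, b)
    if not a.any() or not b.any():
        raise EmptyMaskError("boundary distance is undefined for an empty mask")
    spacing = np.asarray(
        spacing if spacing is not None else np.ones(a.ndim), dtype=float)
    if spacing.shape != (a.ndim,) or np.any(spacing <= 0):
        raise InvalidInputError(f"spacing must be {a.ndim} positive values")
    pa = boundary_points(a) * spacing
    pb = boundary_points(b) * spacing
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return np.concatenate([d_ab, d_ba])


def hd95(a, b, spacing=None) -> float:
    """95th percentile (linear interpolation) of the pooled symmetric
    boundary nearest-point distances, in physical units."""
    return float(np.percentile(_boundary_distances(a, b, spacing), 95))


def hausdorff(a, b, spacing=None) -> float:
    """Classical maximum Hausdorff distance between the mask boundaries."""
    return float(_boundary_distances(a, b, spacing).max())


def paired_compare(per_case_a, per_case_b) -> float:
    """Two-sided paired t-test p-value on per-case metric differences."""
    a = np.asarray(per_case_a, dtype=float)
    b = np.asarray(per_case_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("inputs must be 1D arrays of equal length")
    if a.size < 2:
        raise InvalidInputError("need at least two paired cases")
    diff = a - b
    if np.allclose(diff, diff[0]):
        raise DegenerateInputError("all paired differences identical (zero variance)")
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class MetricReport:
    """Per-case (dsc, iou, hd95) triples plus mean/std summaries."""

    per_case: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path) -> None:
        table = self.per_case.copy()
        for stat in ("mean", "std"):
            row = self.summary.loc[stat].to_dict()
            row["case"] = stat
            table = pd.concat([table, pd.DataFrame([row])], ignore_index=True)
        table.to_csv(path, index=False)


def evaluate_cases(pred_masks, truth_masks, case_ids=None, spacing=None,
                   per_slice: bool = False) -> MetricReport:
    """Evaluate prediction/truth mask pairs case by case.

    With ``per_slice`` each 3D case contributes one row per axial slice
    (slices where both masks are empty count dsc=iou=1 and hd95 is skipped);
    the default treats each case as one unit.  hd95 of an empty-mask case is
    reported as NaN (missing), never as 0.
    """
    rows = []
    ids = case_ids if case_ids is not None else list(range(len(pred_masks)))
    for cid, pred, truth in zip(ids, pred_masks, truth_masks):
        units = [(cid, pred, truth)]
        if per_slice and np.asarray(pred).ndim == 3:
            units = [(f"{cid}/{k}", pred[k], truth[k]) for k in range(len(pred))]
        for uid, p, t in units:
            sp = spacing
            if sp is not None and len(sp) != np.asarray(p).ndim:
                sp = np.asarray(sp)[-np.asarray(p).ndim:]
            try:
                h = hd95(p, t, spacing=sp)
            except EmptyMaskError:
                h = np.nan
            rows.append({"case": uid, "dsc": dsc(p, t), "iou": iou(p, t), "hd95": h})
    per_case = pd.DataFrame(rows)
    summary = per_case[["dsc", "iou", "hd95"]].agg(["mean", "std"])
    return MetricReport(per_case=per_case, summary=summary)
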
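"""Segmentation-agreement metrics.

Voxelwise measures (sensitivity, specificity, Jaccard index JI, Dice
coefficient DC) are computed from the confusion counts of two aligned
binary volumes; boundary agreement uses the modified Hausdorff distance

    MHD(A, B) = max( mean_a min_b ||a-b||, mean_b min_a ||a-b|| )

over boundary voxel sets, and MHD-CL is the same statistic on rasterized
centerline graphs.  Distances are reported in voxel units on an isotropic
grid unless a spacing is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import CenterlineGraph, as_binary

log = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(seg: np.ndarray, gt: np.ndarray) -> ConfusionCounts:
    """Voxelwise confusion counts; foreground is the positive class."""
    seg = as_binary(seg)
    gt = as_binary(gt)
    if seg.shape != gt.shape:
        raise ValueError(f"shape mismatch: {seg.shape} vs {gt.shape}")
    s = seg.astype(bool)
    g = gt.astype(bool)
    tp = int(np.count_nonzero(s & g))
    fp = int(np.count_nonzero(s & ~g))
    fn = int(np.count_nonzero(~s & g))
    tn = s.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def sensitivity_specificity(c: ConfusionCounts) -> tuple[float, float]:
    """(TP/(TP+FN), TN/(TN+FP)); NaN with a warning on empty denominators."""
    sens = spec = float("nan")
    if c.tp + c.fn > 0:
        sens = c.tp / (c.tp + c.fn)
    else:
        log.warning("no ground-truth foreground: sensitivity undefined")
    if c.tn + c.fp > 0:
        spec = c.tn / (c.tn + c.fp)
    else:
        log.warning("no ground-truth background: specificity undefined")
    return sens, spec


def jaccard_dice(c: ConfusionCounts) -> tuple[float, float]:
    """(JI, DC).  Two empty volumes agree vacuously: (1, 1), logged."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        log.info("both volumes empty; defining JI = DC = 1")
        return 1.0, 1.0
    ji = c.tp / denom
    dc = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
    return ji, dc


def boundary_points(seg: np.ndarray, connectivity: int = 1) -> np.ndarray:
    """Foreground voxels adjacent to background (or the volume border), (n, 3).

    ``connectivity=1`` (default) defines the surface by 6-adjacency;
    ``connectivity=3`` uses 26-adjacency.
    """
    seg = as_binary(seg).astype(bool)
    structure = ndimage.generate_binary_structure(3, connectivity)
    interior = ndimage.binary_erosion(seg, structure=structure, border_value=0)
    return np.argwhere(seg & ~interior)


def modified_hausdorff(
    a: np.ndarray, b: np.ndarray, spacing: tuple[float, float, float] | None = None
) -> float:
    """MHD between two (n, 3) point sets (voxel units unless spacing given)."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 3)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("MHD requires two non-empty point sets")
    if spacing is not None:
        sp = np.asarray(spacing, dtype=np.float64)
        a = a * sp
        b = b * sp
    d_ab = cKDTree(b).query(a, k=1)[0].mean()
    d_ba = cKDTree(a).query(b, k=1)[0].mean()
    return float(max(d_ab, d_ba))


def mhd_boundary(seg: np.ndarray, gt: np.ndarray, connectivity: int = 1) -> float:
    """MHD between the surfaces of two segmentations."""
    return modified_hausdorff(boundary_points(seg, connectivity), boundary_points(gt, connectivity))


def mhd_centerline(ga: CenterlineGraph, gb: CenterlineGraph) -> float:
    """MHD-CL: modified Hausdorff distance between rasterized centerlines."""
    a = ga.rasterize()
    b = gb.rasterize()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("MHD-CL requires two non-empty centerline graphs")
    return modified_hausdorff(a, b)


def slicewise_dice(seg: np.ndarray, gt: np.ndarray) -> list[float]:
    """Dice coefficient per x-y plane (imaging quality varies with depth)."""
    seg = as_binary(seg)
    gt = as_binary(gt)
    if seg.shape != gt.shape:
        raise ValueError(f"shape mismatch: {seg.shape} vs {gt.shape}")
    return [
        jaccard_dice(confusion(seg[z][None], gt[z][None]))[1] for z in range(seg.shape[0])
    ]


def evaluation_report(seg: np.ndarray, gt: np.ndarray, boundary_connectivity: int = 1) -> dict:
    """All voxelwise + boundary metrics for a segmentation/ground-truth pair."""
    c = confusion(seg, gt)
    sens, spec = sensitivity_specificity(c)
    ji, dc = jaccard_dice(c)
    report = {
        "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
        "sensitivity": sens, "specificity": spec,
        "jaccard": ji, "dice": dc,
        "slicewise_dice": slicewise_dice(seg, gt),
    }
    try:
        report["mhd_boundary"] = mhd_boundary(seg, gt, boundary_connectivity)
    except ValueError:
        report["mhd_boundary"] = float("nan")
    return report
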
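"""Segmentation evaluation metrics.

Overlap scores (Dice, Jaccard, precision, recall) from voxel-wise
TP/FP/FN counts, and boundary distances (Hausdorff distance and its 95th
percentile variant) between spacing-aware boundary point sets:

    HD(X, Y)   = max( max_x min_y |x - y|, max_y min_x |y - x| )
    HD95(X, Y) = max( h95(X, Y), h95(Y, X) )

where h95 is the 95th percentile (linear interpolation between order
statistics) of the directed nearest-neighbour distances.  Boundaries are
foreground voxels with at least one face-adjacent (6-connected)
background neighbour; distances are measured between boundary voxel
centres in mm.  A slice-wise 2D Hausdorff distance is provided for
characteristic slices where the dentation pattern is visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ParameterError
from .volume import BinaryMask, require_same_grid

log = logging.getLogger("dentamorph")

_STRUCT_3D = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
_STRUCT_2D = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass
class SegScores:
    """Overlap and distance scores between a predicted and a true mask."""

    dsc: float
    jaccard: float
    recall: float
    precision: float
    hd_mm: float | None = None
    hd95_mm: float | None = None

    def __post_init__(self):
        # consistency identity between Dice and Jaccard
        if np.isfinite(self.dsc) and np.isfinite(self.jaccard):
            expect = 2 * self.jaccard / (1 + self.jaccard)
            if abs(expect - self.dsc) > 1e-12:
                raise ParameterError(
                    f"inconsistent scores: dsc={self.dsc} vs 2j/(1+j)={expect}")


def overlap_metrics(pred: BinaryMask, truth: BinaryMask) -> SegScores:
    """Voxel-wise Dice, Jaccard, recall and precision.

    DSC = 2TP/(2TP+FP+FN), Jaccard = TP/(TP+FP+FN), Recall = TP/(TP+FN),
    Precision = TP/(TP+FP).  Two empty masks score 1 by convention
    (logged); an empty mask against a non-empty one scores 0.
    """
    require_same_grid(pred, truth, "pred and truth")
    p = pred.data.astype(bool)
    t = truth.data.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    if tp + fp + fn == 0:
        log.info("overlap_metrics: both masks empty; scores defined as 1")
        return SegScores(dsc=1.0, jaccard=1.0, recall=1.0, precision=1.0)
    dsc = 2 * tp / (2 * tp + fp + fn)
    jac = tp / (tp + fp + fn)
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    return SegScores(dsc=dsc, jaccard=jac, recall=recall, precision=precision)


def boundary_voxels(mask: np.ndarray, structure=None) -> np.ndarray:
    """Indices of foreground voxels with a face-adjacent background
    neighbour (the array edge counts as background)."""
    fg = mask.astype(bool)
    if structure is None:
        structure = _STRUCT_3D if fg.ndim == 3 else _STRUCT_2D
    interior = ndimage.binary_erosion(fg, structure=structure, border_value=0)
    return np.argwhere(fg & ~interior)


def _directed_distances(a_pts: np.ndarray, b_pts: np.ndarray,
                        spacing: float) -> np.ndarray:
    tree = cKDTree(b_pts * spacing)
    d, _ = tree.query(a_pts * spacing, k=1)
    return d


def hausdorff_metrics(pred: BinaryMask, truth: BinaryMask) -> SegScores:
    """HD and HD95 in mm between the two masks' boundary voxel sets."""
    require_same_grid(pred, truth, "pred and truth")
    if not pred.data.any() or not truth.data.any():
        raise ParameterError("Hausdorff distance is undefined for empty masks")
    pb = boundary_voxels(pred.data)
    tb = boundary_voxels(truth.data)
    d_pt = _directed_distances(pb, tb, pred.spacing_mm)
    d_tp = _directed_distances(tb, pb, pred.spacing_mm)
    hd = max(float(d_pt.max()), float(d_tp.max()))
    hd95 = max(float(np.percentile(d_pt, 95)), float(np.percentile(d_tp, 95)))
    ov = overlap_metrics(pred, truth)
    return SegScores(dsc=ov.dsc, jaccard=ov.jaccard, recall=ov.recall,
                     precision=ov.precision, hd_mm=hd, hd95_mm=hd95)


def characteristic_slice(mask: BinaryMask, slice_axis) -> int:
    """Index of the slice with the largest foreground area along an axis
    (an anatomical plane name or a grid-axis integer).  Stand-in for the
    slice that best shows the dentation pattern; overridable."""
    axis = mask.plane_axis(slice_axis) if isinstance(slice_axis, str) else int(slice_axis)
    areas = mask.data.astype(bool).sum(axis=tuple(k for k in range(3) if k != axis))
    idx = int(np.argmax(areas))
    log.info("characteristic slice along axis %d: index %d (area %d voxels)",
             axis, idx, int(areas[idx]))
    return idx


def hausdorff_2d(pred: BinaryMask, truth: BinaryMask, slice_axis,
                 slice_index: int | None = None) -> float:
    """Full 2D Hausdorff distance (mm) between boundary contours of one
    slice of each mask.  When ``slice_index`` is omitted the
    characteristic (largest-area) slice of the truth mask is used."""
    require_same_grid(pred, truth, "pred and truth")
    axis = pred.plane_axis(slice_axis) if isinstance(slice_axis, str) else int(slice_axis)
    if slice_index is None:
        slice_index = characteristic_slice(truth, axis)
    if not 0 <= slice_index < pred.shape[axis]:
        raise ParameterError(f"slice index {slice_index} out of range "
                             f"for axis {axis} (size {pred.shape[axis]})")
    sl = [slice(None)] * 3
    sl[axis] = slice_index
    p2 = pred.data[tuple(sl)].astype(bool)
    t2 = truth.data[tuple(sl)].astype(bool)
    if not p2.any() or not t2.any():
        raise ParameterError(
            f"empty slice at index {slice_index} along axis {axis}")
    pb = boundary_voxels(p2, _STRUCT_2D)
    tb = boundary_voxels(t2, _STRUCT_2D)
    d_pt = _directed_distances(pb, tb, pred.spacing_mm)
    d_tp = _directed_distances(tb, pb, pred.spacing_mm)
    return max(float(d_pt.max()), float(d_tp.max()))
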
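"""Evaluation metrics: Dice, Hausdorff distance, centerline overlap.

Hausdorff is measured between the *boundary* voxel centers of the two masks
(it is a distance between surfaces) and reported in voxel units of the
evaluation grid.  Centerline overlap is the fraction of ground-truth
centerline length that lies inside the predicted segmentation, discretized
at half the minimum voxel spacing.  Because clinical ground truth rarely
annotates every vessel, evaluation is typically restricted to the region
within six local radii of the ground-truth centerline
(:func:`evaluation_mask`), applied to prediction and truth alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ValidationError
from .image_io import ImageVolume, SegmentationMap
from .local_geometry import CenterlineTree
from .local_segmentation import dice_score

__all__ = [
    "EvalReport",
    "dice",
    "hausdorff",
    "centerline_overlap",
    "evaluation_mask",
    "evaluate",
]


@dataclass
class EvalReport:
    dice: float
    hausdorff: float  # voxel units
    centerline_overlap: float
    masked: bool = False

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "hausdorff_voxels": self.hausdorff,
            "centerline_overlap": self.centerline_overlap,
            "masked": self.masked,
        }


def _binary(x) -> np.ndarray:
    arr = x.data if isinstance(x, ImageVolume) else np.asarray(x)
    return arr > 0.5


def dice(x, y) -> float:
    """Volumetric Dice overlap of two binary maps (empty-vs-empty scores 1)."""
    return dice_score(_binary(x).astype(np.float64), _binary(y).astype(np.float64))


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    # voxels on the array edge count as boundary (erosion border_value=0)
    eroded = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1))
    return np.argwhere(mask & ~eroded).astype(np.float64)


def hausdorff(x, y) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in voxels.

    ``H(X, Y) = max(sup_x inf_y d, sup_y inf_x d)`` over the boundary voxel
    centers; 0 iff the boundaries coincide.
    """
    bx, by = _binary(x), _binary(y)
    if not bx.any() or not by.any():
        raise ValidationError("Hausdorff distance is undefined for an empty mask")
    px, py = _boundary_points(bx), _boundary_points(by)
    d_xy = cKDTree(py).query(px)[0].max()
    d_yx = cKDTree(px).query(py)[0].max()
    return float(max(d_xy, d_yx))


def centerline_overlap(pred: SegmentationMap, centerline: CenterlineTree) -> float:
    """Fraction of the ground-truth centerline captured by the prediction.

    Each branch is resampled at half the minimum voxel spacing; a sample
    counts as captured when its nearest voxel is foreground.  Samples outside
    the grid count as missed.
    """
    if not centerline.branches or centerline.total_length() == 0:
        raise ValidationError("empty centerline")
    step = 0.5 * float(pred.spacing.min())
    binary = _binary(pred)
    shape = np.array(pred.shape)
    hit = 0
    total = 0
    for branch in centerline.branches:
        pts = branch.resample(step).points
        idx = np.round((pts - pred.origin) / pred.spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        total += len(pts)
        if ok.any():
            sel = idx[ok]
            hit += int(binary[sel[:, 0], sel[:, 1], sel[:, 2]].sum())
    return hit / total


def evaluation_mask(
    centerline: CenterlineTree, template: ImageVolume, radius_multiple: float = 6.0
) -> SegmentationMap:
    """Voxels within ``radius_multiple`` local radii of the truth centerline.

    A voxel is included iff its distance to some centerline point ``p`` is at
    most ``radius_multiple * radius(p)`` — the local radius at that point, so
    thin distal branches get proportionally tight evaluation corridors.
    """
    out = np.zeros(template.shape, dtype=bool)
    shape = np.array(template.shape)
    step = 0.5 * float(template.spacing.min())
    for branch in centerline.branches:
        if branch.radii is None:
            raise ValidationError("evaluation mask needs per-point radii")
        rs = branch.resample(step)
        for p, r in zip(rs.points, rs.radii):
            reach = radius_multiple * float(r)
            lo = np.maximum(
                np.ceil((p - reach - template.origin) / template.spacing).astype(int), 0
            )
            hi = np.minimum(
                np.floor((p + reach - template.origin) / template.spacing).astype(int),
                shape - 1,
            )
            if np.any(hi < lo):
                continue
            sl = tuple(slice(a, b + 1) for a, b in zip(lo, hi))
            idx = np.indices(tuple(hi - lo + 1)).reshape(3, -1).T + lo
            pts = template.origin + idx * template.spacing
            inside = np.linalg.norm(pts - p, axis=1) <= reach
            out[sl] |= inside.reshape(tuple(hi - lo + 1))
    return SegmentationMap(out.astype(np.uint8), template.spacing, template.origin)


def evaluate(
    pred: SegmentationMap,
    truth: SegmentationMap,
    centerline: CenterlineTree,
    mask_six_radius: bool = False,
) -> EvalReport:
    """Full report against a ground-truth mask and centerline."""
    p = _binary(pred)
    t = _binary(truth)
    if mask_six_radius:
        m = evaluation_mask(centerline, truth).data > 0
        p, t = p & m, t & m
    return EvalReport(
        dice=dice(p, t),
        hausdorff=hausdorff(p, t),
        centerline_overlap=centerline_overlap(
            SegmentationMap(p.astype(np.uint8), pred.spacing, pred.origin), centerline
        ),
        masked=mask_six_radius,
    )
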
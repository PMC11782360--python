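"""The pluggable local-segmenter contract, a reference oracle, and loss terms.

A local segmenter maps an image subvolume to a per-voxel vessel probability
map on the identical grid.  Any implementation (a trained 3D U-Net served
through ONNX, a thresholding oracle, ...) plugs in behind the same contract;
the tracer only ever calls :meth:`Segmenter.segment`.

The shipped :class:`OracleSegmenter` squashes smoothed intensity through a
logistic around a threshold.  On two-level phantoms with the threshold midway
between the levels it behaves like a well-trained network — which makes the
whole tracing loop testable at desk scale without any model weights.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .errors import ValidationError
from .image_io import ImageVolume, SegmentationMap

__all__ = [
    "Segmenter",
    "OracleSegmenter",
    "BatchLossReport",
    "dice_score",
    "cross_entropy",
    "batch_loss",
    "get_segmenter",
]

#: probability clamp before logarithms; the cross-entropy is undefined at {0, 1}
PROB_EPS = 1e-7


class Segmenter(ABC):
    """Contract: ``segment`` returns probabilities in [0, 1] on the input grid.

    Implementations must be deterministic given identical input (seed any
    internal randomness at construction).
    """

    @abstractmethod
    def segment(self, subvolume: ImageVolume) -> SegmentationMap:
        ...


@dataclass
class OracleSegmenter(Segmenter):
    """Reference segmenter: smooth, then logistic-squash around a threshold.

    ``probability = expit(gain * (smoothed_intensity - threshold))`` — strictly
    monotone in intensity, above 0.5 exactly where the (smoothed) intensity
    exceeds the threshold.
    """

    threshold: float = 0.5
    smooth_sigma: float = 0.0  # mm
    gain: float = 50.0

    def segment(self, subvolume: ImageVolume) -> SegmentationMap:
        data = subvolume.data.astype(np.float64)
        if self.smooth_sigma > 0:
            data = ndimage.gaussian_filter(data, self.smooth_sigma / subvolume.spacing)
        prob = expit(self.gain * (data - self.threshold))
        return SegmentationMap(prob, subvolume.spacing, subvolume.origin,
                               subvolume.index_offset)


def get_segmenter(name: str, **kwargs) -> Segmenter:
    """Resolve a segmenter by config name (``oracle`` or ``module:path.to:attr``)."""
    if name == "oracle":
        return OracleSegmenter(**kwargs)
    if name.startswith("module:"):
        import importlib

        modname, _, attr = name[len("module:"):].partition(":")
        obj = getattr(importlib.import_module(modname), attr)
        seg = obj(**kwargs) if isinstance(obj, type) else obj
        if not isinstance(seg, Segmenter):
            raise ValidationError(f"{name} does not provide a Segmenter")
        return seg
    raise ValidationError(f"unknown segmenter {name!r}")


# ---------------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------------

def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, ImageVolume) else np.asarray(x)


def dice_score(yp, yt) -> float:
    """Soft Dice: ``2 |Yp . Yt| / (|Yp| + |Yt|)``; two empty masks score 1.

    The intersection of soft maps is the elementwise product, so on binary
    inputs this reduces to the usual overlap count.
    """
    p, t = _as_array(yp).astype(np.float64), _as_array(yt).astype(np.float64)
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: {p.shape} vs {t.shape}")
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (p * t).sum() / denom)


def cross_entropy(yp, yt) -> float:
    """Mean Bernoulli log-likelihood ``(1/n) sum yt log yp + (1-yt) log(1-yp)``.

    Kept in log-likelihood form (a non-positive number, 0 at a perfect
    prediction up to the clamp); the batch loss *subtracts* it so the total
    grows with misclassification.  Probabilities are clamped to
    ``[PROB_EPS, 1 - PROB_EPS]`` before the logarithms.
    """
    p, t = _as_array(yp).astype(np.float64), _as_array(yt).astype(np.float64)
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: {p.shape} vs {t.shape}")
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    return float(np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))


@dataclass
class BatchLossReport:
    dice_terms: np.ndarray
    ce_terms: np.ndarray
    item_losses: np.ndarray
    total: float


def batch_loss(truths, predictions) -> BatchLossReport:
    """Batch loss ``sum_i (1 - Dice_i - CE_i)``: ~0 for perfect predictions."""
    truths, predictions = list(truths), list(predictions)
    if len(truths) != len(predictions):
        raise ValidationError(
            f"batch length mismatch: {len(truths)} truths vs {len(predictions)} predictions"
        )
    d = np.array([dice_score(p, t) for p, t in zip(predictions, truths)])
    ce = np.array([cross_entropy(p, t) for p, t in zip(predictions, truths)])
    items = 1.0 - d - ce
    return BatchLossReport(d, ce, items, float(items.sum()))
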
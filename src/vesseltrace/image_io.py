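"""Volume containers, file I/O, intensity normalization and resampling.

Coordinate model
----------------
Volumes are axis-aligned scalar grids.  Voxel ``(i, j, k)`` (0-based) sits at
physical position ``origin + (i, j, k) * spacing`` in millimetres.  Array axis
order is ``(x, y, z)``, i.e. ``data.shape == (W, H, D)``.  Oblique direction
matrices are rejected on read: the tracing pipeline, and the phantoms it is
validated on, operate in an identity-orientation frame.

Normalization follows the two modality-specific rules used when preparing
angiographic training data: MR volumes are z-scored per image, CT volumes are
clipped to the 0.5/99.5 intensity percentiles of the vessel foreground and
z-scored with foreground statistics pooled over the training cases (held
constant at inference).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import OutOfBoundsError, ValidationError

__all__ = [
    "ImageVolume",
    "SegmentationMap",
    "SubVolumeSpec",
    "NormalizationStats",
    "read_volume",
    "write_volume",
    "fit_normalization",
    "normalize",
    "resample",
    "extract_subvolume",
]

#: guard against zero/degenerate standard deviations on blank patches
SIGMA_EPS = 1e-8


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical spacing and origin (mm).

    Parameters
    ----------
    data : ndarray, shape (W, H, D)
    spacing : array-like of 3 positive floats, mm per voxel along each axis.
    origin : array-like of 3 floats, physical position of voxel (0, 0, 0).
    index_offset : optional (i, j, k) of this volume's voxel (0,0,0) inside a
        parent grid; set by :func:`extract_subvolume` so that local predictions
        can be fused back into the global accumulator.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    index_offset: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3D array, got ndim={self.data.ndim}")
        if np.any(self.spacing <= 0):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValidationError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_phys(self, idx: Sequence[float]) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def phys_to_index(self, point: Sequence[float]) -> np.ndarray:
        """Continuous (fractional) voxel index of a physical point."""
        return (np.asarray(point, dtype=float) - self.origin) / self.spacing

    def center_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box spanned by the voxel *centers*."""
        hi = self.origin + (np.array(self.shape) - 1) * self.spacing
        return self.origin.copy(), hi

    def contains_point(self, point: Sequence[float]) -> bool:
        idx = self.phys_to_index(point)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.array(self.shape) - 0.5))

    def copy(self) -> "ImageVolume":
        return type(self)(
            self.data.copy(), self.spacing.copy(), self.origin.copy(), self.index_offset
        )


class SegmentationMap(ImageVolume):
    """An :class:`ImageVolume` whose values are vessel probabilities in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        lo, hi = float(self.data.min(initial=0)), float(self.data.max(initial=0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValidationError(
                f"segmentation values must lie in [0, 1], got range [{lo}, {hi}]"
            )
        if np.issubdtype(self.data.dtype, np.floating):
            np.clip(self.data, 0.0, 1.0, out=self.data)

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def binarize(self, threshold: float = 0.5) -> "SegmentationMap":
        """Threshold with >= (a fused value of exactly 0.5 is kept)."""
        return SegmentationMap(
            (self.data >= threshold).astype(np.uint8),
            self.spacing,
            self.origin,
            self.index_offset,
        )


@dataclass
class SubVolumeSpec:
    """An axis-aligned cube: center point ``c`` and side length ``L``, in mm."""

    center: np.ndarray
    side: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.side = float(self.side)
        if self.side <= 0:
            raise ValidationError(f"cube side must be positive, got {self.side}")

    @property
    def sigma(self) -> float:
        """Gaussian fusion-weight scale sigma = L / 4."""
        return self.side / 4.0


@dataclass
class NormalizationStats:
    """Fitted intensity-normalization parameters.

    ``mr_zscore`` re-derives mu/sigma from each image at application time (the
    stored values are informational); ``ct_clip_foreground`` stores pooled
    foreground statistics and clip bounds that are held constant at inference.
    """

    mode: Literal["mr_zscore", "ct_clip_foreground"]
    clip_lo: float | None = None
    clip_hi: float | None = None
    mu: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("mr_zscore", "ct_clip_foreground"):
            raise ValidationError(f"unknown normalization mode {self.mode!r}")
        if self.mode == "ct_clip_foreground":
            if self.clip_lo is None or self.clip_hi is None or self.clip_lo >= self.clip_hi:
                raise ValidationError("ct_clip_foreground requires clip_lo < clip_hi")
            if self.sigma is None or self.sigma <= 0:
                raise ValidationError("sigma must be positive")


def save_normalization(stats: NormalizationStats, path: str | os.PathLike) -> None:
    """Persist fitted normalization statistics as YAML (held fixed at inference)."""
    import yaml

    payload = {k: v for k, v in vars(stats).items() if v is not None}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def load_normalization(path: str | os.PathLike) -> NormalizationStats:
    import yaml

    with open(path) as fh:
        return NormalizationStats(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_IDENTITY = np.eye(3).ravel()


def _check_direction(img: sitk.Image, path: str) -> None:
    if not np.allclose(img.GetDirection(), _IDENTITY, atol=1e-6):
        raise ValidationError(
            f"{path}: oblique/non-identity direction matrices are not supported; "
            "resample the volume to an axis-aligned identity orientation first"
        )


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = sitk.ReadImage(path)
    _check_direction(img, path)
    # sitk arrays come back (z, y, x); our convention is (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ImageVolume(data, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write a volume to NIfTI or MetaImage, preserving spacing and origin."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, os.fspath(path))


# ---------------------------------------------------------------------------
# intensity normalization
# ---------------------------------------------------------------------------

def fit_normalization(
    images: Iterable[ImageVolume],
    masks: Iterable[SegmentationMap] | None = None,
    mode: Literal["mr_zscore", "ct_clip_foreground"] = "mr_zscore",
) -> NormalizationStats:
    """Fit normalization statistics over a set of training volumes.

    ``mr_zscore`` is stateless per-image z-scoring; the returned stats only
    record the mode.  ``ct_clip_foreground`` pools the intensities of voxels
    labeled as vessel across all training cases, takes the 0.5/99.5
    percentiles (linear interpolation between order statistics) as clip
    bounds, and the pooled foreground mean/std as mu/sigma.
    """
    images = list(images)
    if not images:
        raise ValidationError("need at least one image")
    if mode == "mr_zscore":
        pooled = np.concatenate([im.data.ravel() for im in images])
        return NormalizationStats(
            mode="mr_zscore",
            mu=float(pooled.mean()),
            sigma=float(max(pooled.std(), SIGMA_EPS)),
        )
    if masks is None:
        raise ValidationError("ct_clip_foreground requires foreground masks")
    masks = list(masks)
    if len(masks) != len(images):
        raise ValidationError("images and masks must pair up")
    fg = np.concatenate(
        [im.data[m.data > 0.5].ravel() for im, m in zip(images, masks)]
    )
    if fg.size == 0:
        raise ValidationError("empty foreground: no voxels labeled as vessel")
    clip_lo, clip_hi = np.percentile(fg, [0.5, 99.5], method="linear")
    if clip_hi <= clip_lo:
        clip_hi = clip_lo + SIGMA_EPS
    return NormalizationStats(
        mode="ct_clip_foreground",
        clip_lo=float(clip_lo),
        clip_hi=float(clip_hi),
        mu=float(fg.mean()),
        sigma=float(max(fg.std(), SIGMA_EPS)),
    )


def normalize(vol: ImageVolume, stats: NormalizationStats) -> ImageVolume:
    """Apply fitted normalization to a volume.

    MR: ``(x - mu) / sigma`` with mu/sigma computed from *this* image.
    CT: clip to ``[clip_lo, clip_hi]`` then z-score with the stored
    (training-time) foreground statistics.
    """
    x = vol.data.astype(np.float64)
    if stats.mode == "mr_zscore":
        mu = x.mean()
        sigma = max(x.std(), SIGMA_EPS)
        out = (x - mu) / sigma
    else:
        out = np.clip(x, stats.clip_lo, stats.clip_hi)
        out = (out - stats.mu) / max(stats.sigma, SIGMA_EPS)  # type: ignore[operator]
    return ImageVolume(out, vol.spacing, vol.origin, vol.index_offset)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample(
    vol: ImageVolume,
    target_spacing: Sequence[float],
    kind: Literal["image", "label"] = "image",
) -> ImageVolume:
    """Resample to a new spacing, covering the same physical extent.

    Images use cubic-spline interpolation; label maps use linear interpolation
    on one-hot encoded classes followed by argmax (for a binary map this is
    linear interpolation and a 0.5 threshold), which keeps them crisp.

    The output grid is cell-centered on the same physical extent: with extent
    ``E = n * spacing`` the new axis gets ``round(E / target)`` voxels and its
    first voxel center shifts by ``(target - spacing) / 2``.
    """
    tsp = np.asarray(target_spacing, dtype=float).reshape(3)
    if np.any(tsp <= 0):
        raise ValidationError(f"target spacing must be positive, got {tsp}")
    if kind not in ("image", "label"):
        raise ValidationError(f"kind must be 'image' or 'label', got {kind!r}")

    shape = np.array(vol.shape)
    extent = shape * vol.spacing
    new_shape = np.maximum(1, np.round(extent / tsp).astype(int))
    new_origin = vol.origin - vol.spacing / 2.0 + tsp / 2.0

    grids = np.meshgrid(
        *[
            (new_origin[a] + np.arange(new_shape[a]) * tsp[a] - vol.origin[a])
            / vol.spacing[a]
            for a in range(3)
        ],
        indexing="ij",
    )
    coords = np.stack(grids)

    if kind == "image":
        out = ndimage.map_coordinates(
            vol.data.astype(np.float64), coords, order=3, mode="nearest"
        )
        return ImageVolume(out, tsp, new_origin)

    labels = np.unique(vol.data)
    if labels.size <= 2:
        soft = ndimage.map_coordinates(
            (vol.data > 0.5).astype(np.float64), coords, order=1, mode="nearest"
        )
        out = (soft >= 0.5).astype(np.uint8)
    else:
        onehot = np.stack(
            [
                ndimage.map_coordinates(
                    (vol.data == lab).astype(np.float64), coords, order=1, mode="nearest"
                )
                for lab in labels
            ]
        )
        out = labels[np.argmax(onehot, axis=0)].astype(vol.data.dtype)
    return SegmentationMap(out, tsp, new_origin)


# ---------------------------------------------------------------------------
# subvolume extraction
# ---------------------------------------------------------------------------

def extract_subvolume(
    vol: ImageVolume,
    spec: SubVolumeSpec,
    max_outside_fraction: float = 0.0,
) -> ImageVolume:
    """Crop the axis-aligned cube ``[c - L/2, c + L/2]^3`` from a volume.

    The crop keeps voxels whose centers fall inside the cube.  If part of the
    cube lies outside the global grid, the fraction of missing voxels is
    compared against ``max_outside_fraction`` (default 0: any missing data is
    an error).  Exceeding it raises :class:`OutOfBoundsError`, which is the
    tracer's boundary stop criterion — the step requested image data that
    does not exist.
    """
    lo = spec.center - spec.side / 2.0
    hi = spec.center + spec.side / 2.0
    i0 = np.ceil((lo - vol.origin) / vol.spacing - 1e-9).astype(int)
    i1 = np.floor((hi - vol.origin) / vol.spacing + 1e-9).astype(int)
    nominal = i1 - i0 + 1
    if np.any(nominal < 1):
        raise ValidationError(
            f"cube side {spec.side} mm is smaller than one voxel along some axis"
        )
    shape = np.array(vol.shape)
    c0 = np.maximum(i0, 0)
    c1 = np.minimum(i1, shape - 1)
    if np.any(c1 < c0):
        raise OutOfBoundsError(
            f"subvolume centered at {spec.center} (L={spec.side}) lies entirely "
            "outside the image"
        )
    inside = np.prod((c1 - c0 + 1).astype(float)) / np.prod(nominal.astype(float))
    outside_fraction = 1.0 - inside
    if outside_fraction > max_outside_fraction + 1e-12:
        raise OutOfBoundsError(
            f"subvolume centered at {np.round(spec.center, 3)} (L={spec.side:.3g}) "
            f"requests {outside_fraction:.1%} of its voxels outside the image "
            f"(allowed {max_outside_fraction:.1%})"
        )
    sl = tuple(slice(int(a), int(b) + 1) for a, b in zip(c0, c1))
    cls = SegmentationMap if isinstance(vol, SegmentationMap) else ImageVolume
    return cls(
        vol.data[sl].copy(),
        vol.spacing.copy(),
        vol.index_to_phys(c0),
        index_offset=(int(c0[0]), int(c0[1]), int(c0[2])),
    )
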
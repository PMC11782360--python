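"""Synthetic 3D vascular phantoms with exact ground truth.

Every downstream stage of the tracer is validated on these phantoms, so no
image download is ever required.  A phantom is a union of *capsules* (tube
segments with hemispherical ends, so that chained and branching segments join
watertight), voxelized at voxel centers.  The image is a two-level intensity
field (inside/outside) passed through an optional Gaussian blur plus additive
Gaussian noise — the minimal model that reproduces the blurred, ambiguous
vessel boundaries that make local segmentation hard in real angiography.

The ground-truth mask is the *unblurred* capsule indicator; the ground-truth
centerline is the set of branch axis polylines with the (constant per-branch)
tube radius attached to every point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image_io import ImageVolume, SegmentationMap
from .local_geometry import CenterlineBranch, CenterlineTree

__all__ = [
    "BranchSpec",
    "TreeSpec",
    "PhantomCase",
    "make_phantom",
    "make_standard_suite",
    "capsule_volume",
]


@dataclass
class BranchSpec:
    """One straight tube segment: start/end points (mm), radius (mm), parent index."""

    start: np.ndarray
    end: np.ndarray
    radius: float
    parent: int | None = None

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float).reshape(3)
        self.end = np.asarray(self.end, dtype=float).reshape(3)
        self.radius = float(self.radius)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))


@dataclass
class TreeSpec:
    """A branching tube tree plus the imaging model used to render it."""

    branches: list[BranchSpec]
    shape: tuple[int, int, int]
    spacing: np.ndarray = field(default_factory=lambda: 0.5 * np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    intensity_inside: float = 1.0
    intensity_outside: float = 0.0
    blur_sigma: float = 0.0  # mm
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.validate()

    def validate(self) -> None:
        if not self.branches:
            raise ValidationError("tree needs at least one branch")
        if np.any(self.spacing <= 0):
            raise ValidationError("spacing must be positive")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValidationError("blur_sigma and noise_sigma must be >= 0")
        vox = float(self.spacing.max())
        for i, br in enumerate(self.branches):
            if br.radius <= 0:
                raise ValidationError(f"branch {i}: radius must be positive")
            if br.parent is not None:
                if not (0 <= br.parent < len(self.branches)) or br.parent == i:
                    raise ValidationError(f"branch {i}: dangling parent index {br.parent}")
                parent = self.branches[br.parent]
                if _point_segment_distance(br.start, parent.start, parent.end) > vox:
                    raise ValidationError(
                        f"branch {i}: start point is not on its parent's axis "
                        "(within one voxel)"
                    )


@dataclass
class PhantomCase:
    """A rendered phantom: image, exact mask and centerline in one frame."""

    name: str
    image: ImageVolume
    truth_mask: SegmentationMap
    truth_centerline: CenterlineTree
    spec: TreeSpec
    # convenience seed for the tracer: (point mm, unit direction, radius mm)
    seed_hint: tuple[np.ndarray, np.ndarray, float] | None = None


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    d = b - a
    l2 = float(d @ d)
    t = 0.0 if l2 == 0 else float(np.clip((p - a) @ d / l2, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * d)))


def capsule_volume(length: float, radius: float) -> float:
    """Analytic volume of a capsule: cylinder plus two hemispherical caps."""
    return np.pi * radius**2 * length + 4.0 / 3.0 * np.pi * radius**3


def _capsule_indicator(points: np.ndarray, spec: TreeSpec) -> np.ndarray:
    """Boolean indicator of the capsule union, evaluated at arbitrary points."""
    inside = np.zeros(points.shape[0], dtype=bool)
    for br in spec.branches:
        d = br.end - br.start
        l2 = float(d @ d)
        rel = points - br.start
        if l2 == 0:
            dist2 = np.einsum("ij,ij->i", rel, rel)
        else:
            t = np.clip(rel @ d / l2, 0.0, 1.0)
            closest = np.outer(t, d)
            diff = rel - closest
            dist2 = np.einsum("ij,ij->i", diff, diff)
        inside |= dist2 <= br.radius**2 + 1e-12
    return inside


def make_phantom(spec: TreeSpec, centerline_step: float | None = None) -> PhantomCase:
    """Render a :class:`TreeSpec` into an image, truth mask and centerline.

    The mask samples the capsule indicator at voxel centers (value 1 iff the
    center is inside some capsule).  The image is the two-level field blurred
    with ``blur_sigma`` (mm) and corrupted with seeded additive Gaussian
    noise, so the same spec and seed always render bit-identical output.
    """
    spec.validate()
    shape = tuple(int(s) for s in spec.shape)
    idx = np.indices(shape).reshape(3, -1).T
    points = spec.origin + idx * spec.spacing
    inside = _capsule_indicator(points, spec).reshape(shape)

    mask = SegmentationMap(inside.astype(np.uint8), spec.spacing, spec.origin)

    img = np.where(inside, spec.intensity_inside, spec.intensity_outside).astype(
        np.float64
    )
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma / spec.spacing)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    image = ImageVolume(img, spec.spacing, spec.origin)

    step = centerline_step if centerline_step is not None else 0.5 * float(spec.spacing.min())
    lo_b, hi_b = mask.center_bounds()
    branches = []
    for br in spec.branches:
        n = max(2, int(np.ceil(br.length / step)) + 1)
        t = np.linspace(0.0, 1.0, n)
        pts = br.start + t[:, None] * (br.end - br.start)
        # clip to the rendered volume: the truth centerline lives in the mask
        keep = np.all((pts >= lo_b) & (pts <= hi_b), axis=1)
        if keep.sum() < 2:
            continue
        pts = pts[keep]
        branches.append(CenterlineBranch(pts, np.full(len(pts), br.radius)))
    tree = CenterlineTree(branches, source_point=spec.branches[0].start.copy())

    return PhantomCase(name="phantom", image=image, truth_mask=mask,
                       truth_centerline=tree, spec=spec)


# ---------------------------------------------------------------------------
# standard suite
# ---------------------------------------------------------------------------

def _chain(points: Sequence[np.ndarray], radii: Sequence[float]) -> list[BranchSpec]:
    """Consecutive segments through `points`; segment i gets radii[i]."""
    out = []
    for i in range(len(points) - 1):
        out.append(
            BranchSpec(points[i], points[i + 1], radii[i], parent=None if i == 0 else i - 1)
        )
    return out


def make_standard_suite(noise_sigma: float = 0.05, blur_sigma: float = 0.4,
                        seed: int = 20) -> list[PhantomCase]:
    """Render the five reference phantoms the test suite traces end to end.

    straight        a straight tube, radius 2 mm, both ends inside the volume.
    bend            a 90-degree bend discretized into short chained segments.
    y_bifurcation   a trunk splitting into two daughters of unequal radius
                    that both exit through volume faces.
    side_branch     a main tube with a thin perpendicular side branch,
                    radius ratio 3:1.
    taper           a tube whose radius steps down below the 0.5 mm minimum-
                    radius stop criterion (rendered at finer spacing/blur so
                    the thin distal segments stay resolvable).
    """
    cases: list[PhantomCase] = []

    def build(name, branches, shape, spacing, hint, blur=blur_sigma, noise=noise_sigma,
              case_seed=0):
        spec = TreeSpec(
            branches=branches, shape=shape, spacing=np.full(3, spacing),
            blur_sigma=blur, noise_sigma=noise, seed=seed + case_seed,
        )
        case = make_phantom(spec)
        case.name = name
        point, direction, radius = hint
        case.seed_hint = (
            np.asarray(point, float),
            np.asarray(direction, float) / np.linalg.norm(direction),
            float(radius),
        )
        cases.append(case)
        return case

    # 1. straight tube, r = 2 mm, axis along z
    build(
        "straight",
        [BranchSpec((16, 16, 4), (16, 16, 36), 2.0)],
        (64, 64, 80), 0.5,
        hint=((16.0, 16.0, 8.0), (0, 0, 1), 2.0),
        case_seed=1,
    )

    # 2. 90-degree bend in the x-z plane, arc radius 12 mm
    theta = np.linspace(0, np.pi / 2, 9)
    arc = np.stack([16 + 12 * np.sin(theta), np.full(9, 16.0), 18 - 12 * np.cos(theta)]).T
    pts = [np.array([16.0, 16.0, 4.0])] + [p for p in arc]
    build(
        "bend",
        _chain(pts, [2.0] * (len(pts) - 1)),
        (72, 64, 48), 0.5,
        hint=((16.0, 16.0, 6.0), (0, 0, 1), 2.0),
        case_seed=2,
    )

    # 3. symmetric-angle Y, daughters of radius 1.5 / 1.2 exiting the x faces
    trunk = BranchSpec((20, 16, 6), (20, 16, 22), 2.0)
    da = BranchSpec((20, 16, 22), (44, 16, 40), 1.5, parent=0)
    db = BranchSpec((20, 16, 22), (-4, 16, 40), 1.2, parent=0)
    build(
        "y_bifurcation",
        [trunk, da, db],
        (80, 64, 88), 0.5,
        hint=((20.0, 16.0, 10.0), (0, 0, 1), 2.0),
        case_seed=3,
    )

    # 4. main tube with a thin perpendicular side branch (ratio 3:1)
    main = BranchSpec((16, 16, 4), (16, 16, 44), 2.1)
    side = BranchSpec((16, 16, 24), (34, 16, 30), 0.7, parent=0)
    build(
        "side_branch",
        [main, side],
        (80, 64, 96), 0.5,
        hint=((16.0, 16.0, 8.0), (0, 0, 1), 2.1),
        case_seed=4,
    )

    # 5. tapering tube, radius 2.0 mm down to 0.32 mm (below R_min = 0.5)
    radii = [2.0, 1.7, 1.4, 1.1, 0.9, 0.7, 0.55, 0.42, 0.32]
    z = np.linspace(4, 52, len(radii) + 1)
    pts = [np.array([13.0, 13.0, zz]) for zz in z]
    build(
        "taper",
        _chain(pts, radii),
        (66, 66, 140), 0.4,
        hint=((13.0, 13.0, 8.0), (0, 0, 1), 2.0),
        blur=0.3,
        case_seed=5,
    )

    return cases
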
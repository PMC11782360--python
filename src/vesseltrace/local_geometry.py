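"""Local geometry: surfaces, truncation caps, eikonal centerlines, radii.

Given a local vessel probability map this module extracts an isosurface
(marching cubes at 0.5), finds the open loops where the vessel is cut by the
subvolume faces ("truncation boundaries", i.e. inlets/outlets), classifies
them into one source and the remaining targets, and extracts a centerline per
target by wave propagation: solve the eikonal equation ``|grad T| F = 1``
with a speed ``F`` that grows with distance from the vessel wall, then run
gradient descent on the arrival time ``T`` from each target back to the
source.  Because the wave runs fastest along the vessel axis, the descent
path hugs the centerline.  Radii come from the Euclidean distance transform
of the binary mask evaluated along the path.

The eikonal solver is a first-order upwind fast-marching method on the voxel
grid, restricted to the vessel mask.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import (
    EmptySegmentationError,
    NoOutletError,
    StallError,
    UnreachableTargetError,
    ValidationError,
)
from .image_io import ImageVolume, SegmentationMap

__all__ = [
    "SurfaceMesh",
    "TruncationBoundary",
    "EikonalField",
    "CenterlineBranch",
    "CenterlineTree",
    "extract_surface",
    "find_caps",
    "assign_source_target",
    "build_speed",
    "solve_eikonal",
    "trace_centerline",
    "estimate_radius",
    "smooth_radii",
]


@dataclass
class SurfaceMesh:
    """Triangle mesh in physical (mm) coordinates.

    ``cut_vertex`` flags vertices on open boundary loops, i.e. where the
    surface was truncated by the subvolume faces.
    """

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    cut_vertex: np.ndarray  # (n,) bool

    def boundary_edges(self) -> np.ndarray:
        """Edges incident to exactly one triangle, as (k, 2) vertex pairs."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def area(self) -> float:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())


@dataclass
class TruncationBoundary:
    """One open loop where the vessel surface meets a subvolume face."""

    vertex_ids: np.ndarray
    center: np.ndarray  # mean of loop vertices, mm
    face_id: int  # 0..5: (x-, x+, y-, y+, z-, z+)
    role: str | None = None  # "source" | "target"


@dataclass
class EikonalField:
    """Solved arrival times ``T`` (seeded at the source) and the speed ``F``."""

    T: np.ndarray
    speed: ImageVolume
    source_index: tuple[int, int, int]

    @property
    def spacing(self) -> np.ndarray:
        return self.speed.spacing

    @property
    def origin(self) -> np.ndarray:
        return self.speed.origin


@dataclass
class CenterlineBranch:
    """A polyline (mm) with a radius at every point.

    Traced branches are ordered target -> source, so the last point is (one
    voxel from) the source cap center.
    """

    points: np.ndarray  # (n, 3)
    radii: np.ndarray | None = None  # (n,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float).reshape(-1)

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def resample(self, step: float) -> "CenterlineBranch":
        """Resample at fixed arclength step (linear interpolation)."""
        if len(self.points) < 2:
            return CenterlineBranch(self.points.copy(),
                                    None if self.radii is None else self.radii.copy())
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        n = max(2, int(np.ceil(total / step)) + 1)
        snew = np.linspace(0.0, total, n)
        pts = np.stack([np.interp(snew, s, self.points[:, a]) for a in range(3)], axis=1)
        radii = None if self.radii is None else np.interp(snew, s, self.radii)
        return CenterlineBranch(pts, radii)


@dataclass
class CenterlineTree:
    """A collection of branches sharing one source point."""

    branches: list[CenterlineBranch]
    source_point: np.ndarray | None = None

    def total_length(self) -> float:
        return float(sum(b.length for b in self.branches))

    def endpoints(self) -> np.ndarray:
        """The non-source end (first point) of every branch."""
        return np.array([b.points[0] for b in self.branches])

    def all_points(self) -> np.ndarray:
        return np.concatenate([b.points for b in self.branches], axis=0)


# ---------------------------------------------------------------------------
# surface and caps
# ---------------------------------------------------------------------------

def extract_surface(prob: SegmentationMap, iso: float = 0.5) -> SurfaceMesh:
    """Marching-cubes isosurface of a probability map, in mm coordinates.

    Where the vessel meets the subvolume boundary the surface stays open;
    vertices on those open loops are flagged via ``cut_vertex``.
    """
    arr = prob.data.astype(np.float64)
    if arr.max(initial=0.0) < iso or arr.min(initial=1.0) > iso:
        raise EmptySegmentationError(
            f"no isosurface at level {iso}: map range "
            f"[{arr.min(initial=0):.3g}, {arr.max(initial=0):.3g}]"
        )
    verts, faces, _, _ = measure.marching_cubes(
        arr, level=iso, spacing=tuple(prob.spacing)
    )
    verts = verts + prob.origin
    mesh = SurfaceMesh(verts, faces.astype(np.int64),
                       np.zeros(len(verts), dtype=bool))
    be = mesh.boundary_edges()
    if be.size:
        mesh.cut_vertex[np.unique(be)] = True
    return mesh


def _face_planes(vol_like: ImageVolume) -> list[tuple[int, int, float]]:
    """(axis, sign, plane coordinate) for the 6 voxel-center bounding planes."""
    lo, hi = vol_like.center_bounds()
    planes = []
    for a in range(3):
        planes.append((a, -1, float(lo[a])))
        planes.append((a, +1, float(hi[a])))
    return planes


def find_caps(mesh: SurfaceMesh, cube: ImageVolume, tol: float | None = None
              ) -> list[TruncationBoundary]:
    """Group open boundary loops into per-face truncation boundaries.

    Each connected component of boundary edges becomes one cap; its face id is
    the bounding plane of the subvolume that its vertices lie on (within half
    a voxel).  Caps are returned in a deterministic order (face id, then
    center lexicographically).
    """
    be = mesh.boundary_edges()
    if be.size == 0:
        raise NoOutletError("closed surface: no truncation boundaries")
    if tol is None:
        tol = 0.51 * float(cube.spacing.max())

    # union-find over boundary-loop vertices
    parent: dict[int, int] = {}

    def root(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in be:
        parent.setdefault(int(u), int(u))
        parent.setdefault(int(v), int(v))
        ru, rv = root(int(u)), root(int(v))
        if ru != rv:
            parent[ru] = rv

    groups: dict[int, list[int]] = {}
    for v in parent:
        groups.setdefault(root(v), []).append(v)

    planes = _face_planes(cube)
    caps = []
    for verts_ids in groups.values():
        ids = np.array(sorted(verts_ids))
        pts = mesh.vertices[ids]
        # face whose plane the loop hugs most tightly
        dev = [np.abs(pts[:, a] - coord).max() for a, _, coord in planes]
        fid = int(np.argmin(dev))
        if dev[fid] > 4 * tol:
            # a ragged loop not on any face (should not happen on clean maps);
            # keep it, callers only use the center
            pass
        caps.append(TruncationBoundary(ids, pts.mean(axis=0), fid))
    caps.sort(key=lambda c: (c.face_id, tuple(np.round(c.center, 9))))
    if not caps:
        raise NoOutletError("no truncation boundaries found")
    return caps


def assign_source_target(
    caps: Sequence[TruncationBoundary], previous_point: Sequence[float]
) -> tuple[TruncationBoundary, list[TruncationBoundary]]:
    """Pick the cap nearest the previous stepping point as source, rest targets.

    Exact distance ties break deterministically on (face id, center).
    """
    if not caps:
        raise NoOutletError("no caps to classify")
    prev = np.asarray(previous_point, dtype=float)
    order = sorted(
        range(len(caps)),
        key=lambda i: (
            round(float(np.linalg.norm(caps[i].center - prev)), 9),
            caps[i].face_id,
            tuple(np.round(caps[i].center, 9)),
        ),
    )
    source = caps[order[0]]
    source.role = "source"
    targets = [caps[i] for i in order[1:]]
    for t in targets:
        t.role = "target"
    return source, targets


# ---------------------------------------------------------------------------
# eikonal machinery
# ---------------------------------------------------------------------------

def build_speed(mask: SegmentationMap, eps: float = 1e-3) -> ImageVolume:
    """Wave speed field: distance to the vessel wall (mm) inside, 0 outside.

    Adding ``eps`` keeps boundary voxels marchable; F is highest on the
    vessel axis so the wave runs fastest there.
    """
    m = mask.data > 0.5
    if not m.any():
        raise ValidationError("empty mask: cannot build a speed field")
    edt = ndimage.distance_transform_edt(m, sampling=mask.spacing)
    F = np.where(m, edt + eps, 0.0)
    return ImageVolume(F, mask.spacing, mask.origin, mask.index_offset)


def _project_to_mask(inside: np.ndarray, idx: np.ndarray) -> tuple[int, int, int] | None:
    """Nearest inside voxel to a (possibly outside) voxel index, or None."""
    idx = np.clip(np.round(idx).astype(int), 0, np.array(inside.shape) - 1)
    if inside[tuple(idx)]:
        return tuple(int(i) for i in idx)
    # nearest inside voxel via EDT indices of the complement
    _, nearest = ndimage.distance_transform_edt(~inside, return_indices=True)
    tgt = tuple(int(nearest[a][tuple(idx)]) for a in range(3))
    return tgt if inside[tgt] else None


def solve_eikonal(speed: ImageVolume, source_point: Sequence[float]) -> EikonalField:
    """First-order upwind fast marching for ``|grad T| F = 1``, ``T(x0) = 0``.

    The march is restricted to voxels with positive speed.  The source point
    is projected to the nearest in-mask voxel (cap centers computed on the
    sub-voxel surface can fall marginally outside the voxelized mask).
    Voxels the wave cannot reach keep ``T = inf``.

    To avoid the well-known point-source inaccuracy of first-order upwind
    schemes, arrival times inside a small ball around the source (kept
    within the local wall distance, so the straight ray stays in the mask)
    are initialized analytically from the trapezoidal travel time before the
    march starts.
    """
    F = speed.data
    inside = F > 0
    if not inside.any():
        raise ValidationError("speed field is zero everywhere")
    src_idx = _project_to_mask(inside, speed.phys_to_index(source_point))
    if src_idx is None:
        raise ValidationError("source point cannot be projected into the mask")

    shape = F.shape
    h = speed.spacing
    T = np.full(shape, np.inf)
    known = np.zeros(shape, dtype=bool)
    T[src_idx] = 0.0
    heap: list[tuple[float, tuple[int, int, int]]] = [(0.0, src_idx)]

    # analytic source-ball initialization (radius 3 voxels, only along rays
    # whose straight segment to the source stays inside the mask)
    r_init = 3.0 * float(h.max())
    rad_vox = np.maximum(np.floor(r_init / h).astype(int), 0)
    lo = np.maximum(np.array(src_idx) - rad_vox, 0)
    hi = np.minimum(np.array(src_idx) + rad_vox, np.array(shape) - 1)
    box = tuple(slice(int(a), int(b) + 1) for a, b in zip(lo, hi))
    bidx = np.indices(tuple(hi - lo + 1)).reshape(3, -1).T + lo
    d = np.linalg.norm((bidx - np.array(src_idx)) * h, axis=1)
    ok = (d <= r_init) & inside[box].reshape(-1) & (d > 0)
    f_here = F[box].reshape(-1)
    t_init = d * 0.5 * (1.0 / np.maximum(f_here, 1e-12) + 1.0 / F[src_idx])
    for (i, j, k), tv in zip(bidx[ok], t_init[ok]):
        v = (int(i), int(j), int(k))
        # line-of-sight: midpoints of the segment must stay in the mask
        steps = np.linspace(0.0, 1.0, 7)[1:-1]
        seg = np.array(src_idx) + np.outer(steps, np.array(v) - np.array(src_idx))
        seg_idx = np.clip(np.round(seg).astype(int), 0, np.array(shape) - 1)
        if not all(inside[tuple(s)] for s in seg_idx):
            continue
        T[v] = float(tv)
        heapq.heappush(heap, (float(tv), v))
    neighbors = [(+1, 0, 0), (-1, 0, 0), (0, +1, 0), (0, -1, 0), (0, 0, +1), (0, 0, -1)]

    def update(v: tuple[int, int, int]) -> float:
        # per axis: upwind arrival, second order where two aligned known
        # neighbors are available (term (alpha t - beta)^2 in the quadratic)
        terms = []  # (t1, alpha, beta)
        for ax in range(3):
            best: tuple[float, float, float] | None = None
            for s in (-1, +1):
                n1 = list(v)
                n1[ax] += s
                if not (0 <= n1[ax] < shape[ax]):
                    continue
                n1t = tuple(n1)
                if not known[n1t]:
                    continue
                t1 = T[n1t]
                if best is not None and t1 >= best[0]:
                    continue
                n2 = list(v)
                n2[ax] += 2 * s
                use2 = False
                if 0 <= n2[ax] < shape[ax]:
                    n2t = tuple(n2)
                    if known[n2t] and T[n2t] <= t1:
                        use2 = True
                        t2 = T[n2t]
                if use2:
                    best = (t1, 1.5 / h[ax], (4.0 * t1 - t2) / (2.0 * h[ax]))
                else:
                    best = (t1, 1.0 / h[ax], t1 / h[ax])
            if best is not None:
                terms.append(best)
        inv_f2 = 1.0 / F[v] ** 2
        terms.sort(key=lambda x: x[0])
        for m in range(len(terms), 0, -1):
            A = sum(al * al for _, al, _ in terms[:m])
            B = sum(al * be for _, al, be in terms[:m])
            C = sum(be * be for _, _, be in terms[:m]) - inv_f2
            disc = B * B - A * C
            if disc >= 0:
                t = (B + np.sqrt(disc)) / A
                if t >= terms[m - 1][0]:
                    return float(t)
        t1, _, _ = terms[0]
        ax = h.min()
        return float(t1 + ax / F[v])

    while heap:
        t, v = heapq.heappop(heap)
        if known[v]:
            continue
        known[v] = True
        for off in neighbors:
            n = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if not all(0 <= n[ax] < shape[ax] for ax in range(3)):
                continue
            if known[n] or not inside[n]:
                continue
            tn = update(n)
            if tn < T[n]:
                T[n] = tn
                heapq.heappush(heap, (tn, n))

    return EikonalField(T=T, speed=speed, source_index=src_idx)


def _interp(arr: np.ndarray, idx: np.ndarray) -> float:
    return float(
        ndimage.map_coordinates(arr, idx.reshape(3, 1), order=1, mode="nearest")[0]
    )


def trace_centerline(
    field: EikonalField,
    targets: Sequence[Sequence[float]],
    step: float | None = None,
    max_iter: int | None = None,
    skip_unreachable: bool = True,
) -> CenterlineTree:
    """Descend the arrival-time field from each target to the source.

    Steps are sub-voxel (0.25 x min spacing by default) along the trilinearly
    interpolated negative gradient of ``T``; a branch terminates once it comes
    within one voxel of the source.  A descent that stops making progress
    raises :class:`StallError`; an unreachable target is skipped (or raises,
    with ``skip_unreachable=False``).  Raises
    :class:`UnreachableTargetError` if no target yields a branch.
    """
    sp = field.spacing
    if step is None:
        step = 0.25 * float(sp.min())
    T = field.T
    reached = np.isfinite(T)
    if not reached.any():
        raise ValidationError("eikonal field has no finite arrival times")
    tmax = float(T[reached].max())
    # fill unreached voxels high so the interpolated gradient points inward
    Tf = np.where(reached, T, tmax * 1.5 + 1.0)
    grads = np.gradient(Tf, *sp)
    src_pt = field.speed.index_to_phys(field.source_index)
    done_dist = float(sp.max())
    diag = float(np.linalg.norm(np.array(T.shape) * sp))
    if max_iter is None:
        max_iter = int(10 * diag / step)

    branches = []
    errors: list[Exception] = []
    for tgt in targets:
        tgt_idx = field.speed.phys_to_index(tgt)
        start_idx = _project_to_mask(reached, tgt_idx)
        if start_idx is None:
            err: Exception = UnreachableTargetError(f"target {tgt} unreachable")
            if skip_unreachable:
                errors.append(err)
                continue
            raise err
        if np.linalg.norm((np.array(start_idx) - tgt_idx) * sp) > 3 * sp.max():
            err = UnreachableTargetError(
                f"target {tgt} lies far from any reached voxel"
            )
            if skip_unreachable:
                errors.append(err)
                continue
            raise err
        x = field.speed.index_to_phys(start_idx).astype(float)
        pts = [x.copy()]
        best_T = _interp(Tf, field.speed.phys_to_index(x))
        since_best = 0
        ok = False
        for _ in range(max_iter):
            if np.linalg.norm(x - src_pt) <= done_dist:
                ok = True
                break
            ci = field.speed.phys_to_index(x)
            g = np.array([_interp(grads[a], ci) for a in range(3)])
            gn = np.linalg.norm(g)
            if gn < 1e-12:
                break
            x = x - step * g / gn
            pts.append(x.copy())
            tcur = _interp(Tf, field.speed.phys_to_index(x))
            if tcur < best_T - 1e-12:
                best_T = tcur
                since_best = 0
            else:
                since_best += 1
                if since_best > 60:
                    break
        if not ok:
            err = StallError(
                f"centerline descent from target {np.round(np.asarray(tgt), 2)} stalled"
            )
            if skip_unreachable:
                errors.append(err)
                continue
            raise err
        pts.append(src_pt.astype(float))
        branches.append(CenterlineBranch(np.array(pts)))

    if not branches:
        if errors and all(isinstance(e, StallError) for e in errors):
            raise StallError("all centerline descents stalled")
        raise UnreachableTargetError("no target could be traced to the source")
    return CenterlineTree(branches, source_point=src_pt.astype(float))


def estimate_radius(
    points: np.ndarray, mask: SegmentationMap
) -> np.ndarray:
    """Vessel radius at each point: distance to the wall of the binary mask.

    Implemented as the trilinearly interpolated Euclidean distance transform
    (mm).  Points on or outside the surface get ~0.
    """
    edt = ndimage.distance_transform_edt(mask.data > 0.5, sampling=mask.spacing)
    idx = np.stack([mask.phys_to_index(p) for p in np.atleast_2d(points)], axis=1)
    r = ndimage.map_coordinates(edt, idx, order=1, mode="nearest")
    return np.maximum(r, 0.0)


def surface_distance_radius(points: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Radius option measured to the extracted surface instead of the mask."""
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.vertices)
    d, _ = tree.query(np.atleast_2d(points))
    return np.asarray(d, dtype=float)


def smooth_radii(radii: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average used before monotonicity checks on tapers."""
    radii = np.asarray(radii, dtype=float)
    if radii.size < window:
        return radii.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(radii, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")
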
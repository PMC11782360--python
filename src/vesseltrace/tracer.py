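"""The sequential tracing engine.

Starting from a single seed (point, direction, radius estimate) the tracer
repeatedly: sizes a cube around the current point from the carried radius
(``L = 5 (r_i + r_{i-1}) / 2``), extracts and segments it, enlarges the cube
while the vessel fills too much of it, turns the local probability map into a
surface with truncation caps, extracts centerlines from the source cap to
every target cap, fuses the local prediction into the global accumulator,
and steps to the point 80% of the way along each branch.  When more than one
branch leaves the cube, the largest-radius one is continued and the rest are
queued as bifurcations, the queue being kept sorted by radius so the largest
vessels are traced first.

Local failures (empty segmentation, fewer than two caps, no reachable
target, a stalled descent) trigger a *chance*: advance one radius along the
current tangent and retry, at most three consecutive times.  A branch ends at
the image boundary, when the radius estimate falls under ``R_min``, when the
chances are exhausted, or when a periodic check finds the candidate region
already fused by past branches.  The whole trace halts when the queue is
empty or the step/branch budgets run out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .assembly import FusionConfig, GlobalAccumulator
from .errors import (
    EmptySegmentationError,
    NoOutletError,
    OutOfBoundsError,
    StallError,
    TraceFailedError,
    UnreachableTargetError,
    ValidationError,
)
from .image_io import ImageVolume, SegmentationMap, SubVolumeSpec, extract_subvolume
from .local_geometry import (
    CenterlineTree,
    assign_source_target,
    build_speed,
    estimate_radius,
    extract_surface,
    find_caps,
    solve_eikonal,
    trace_centerline,
)
from .local_segmentation import Segmenter

__all__ = [
    "Seed",
    "TracerConfig",
    "StepCandidate",
    "QueueEntry",
    "TraceResult",
    "next_side_length",
    "take_chance",
    "choose_step_points",
    "update_queue",
    "enlarge_until_ok",
    "EnlargeResult",
    "already_traced",
    "run_trace",
]

_FAILURE_REASONS = {
    EmptySegmentationError: "empty_segmentation",
    NoOutletError: "insufficient_outlets",
    UnreachableTargetError: "unreachable_target",
    StallError: "centerline_stall",
}


@dataclass
class Seed:
    """Initialization: a point on the vessel, its direction, a radius estimate."""

    point: np.ndarray
    direction: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValidationError("seed direction must be nonzero")
        self.direction = d / n
        self.radius = float(self.radius)
        if self.radius <= 0:
            raise ValidationError("seed radius must be positive")


@dataclass
class TracerConfig:
    """Tunable parameters of the stepping engine (lengths in mm)."""

    size_multiplier: float = 5.0      # cube side per unit mean radius
    gamma_star: float = 0.5           # vessel-fill cutoff triggering enlargement
    enlarge_factor: float = 1.25
    max_enlargements: int = 4
    max_chances: int = 3              # consecutive retries before a branch dies
    step_fraction: float = 0.8        # step point at 80% along each branch
    n_max: int = 500                  # global step budget
    r_min: float = 0.5                # stop tracing below this radius (mm)
    nb_max: int | None = None         # optional branch budget
    retrace_check_period: int = 5     # steps between retracing checks
    retrace_overlap: float = 0.9      # cube fraction already fused => retraced
    retrace_buffer_steps: int = 3     # recent own steps excluded from the check
    max_outside_fraction: float = 0.0 # strict: stop at the image boundary
    dedupe_factor: float = 2.0        # push suppressed within this x radius
    visited_fraction: float = 0.5     # candidate dropped if this fraction of its
                                      # surrounding ball is fused by other branches
    iso: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.step_fraction <= 1.0):
            raise ValidationError("step_fraction must lie in (0, 1]")
        for name in ("size_multiplier", "gamma_star", "enlarge_factor", "r_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.max_chances < 0 or self.n_max < 1:
            raise ValidationError("max_chances >= 0 and n_max >= 1 required")


@dataclass
class StepCandidate:
    """A possible next step: point, local tangent (unit), local radius."""

    point: np.ndarray
    tangent: np.ndarray
    radius: float
    branch_length: float = 0.0


@dataclass
class QueueEntry:
    point: np.ndarray
    tangent: np.ndarray
    radius: float
    from_branch: int
    order: int  # discovery order; stable tie-break for equal radii


@dataclass
class TraceResult:
    accumulator: GlobalAccumulator
    step_log: list[dict]
    centerlines: list[tuple[int, CenterlineTree]]
    seed: Seed
    config: TracerConfig
    stop_reason: str
    n_steps: int
    n_branches: int

    def events(self, kind: str) -> list[dict]:
        return [e for e in self.step_log if e["event"] == kind]

    def branch_end_reasons(self) -> list[str]:
        return [e["reason"] for e in self.events("branch_end")]


# ---------------------------------------------------------------------------
# individual mechanisms (unit-testable on their own)
# ---------------------------------------------------------------------------

def next_side_length(r_i: float, r_prev: float, multiplier: float = 5.0) -> float:
    """Cube side from the carried radius: ``L = multiplier * (r_i + r_prev) / 2``.

    Averaging with the previous step's estimate guards against a single
    underestimated radius shrinking the subvolume too far.
    """
    if r_i <= 0 or r_prev <= 0:
        raise ValidationError(f"radii must be positive, got ({r_i}, {r_prev})")
    return multiplier * (r_i + r_prev) / 2.0


def take_chance(
    point: np.ndarray, tangent: np.ndarray, radius: float
) -> np.ndarray:
    """Advance one radius along the tangent: ``p_{i+1} = p_i + R t_i``."""
    return np.asarray(point, dtype=float) + float(radius) * np.asarray(tangent, dtype=float)


@dataclass
class EnlargeResult:
    spec: SubVolumeSpec
    subvolume: ImageVolume
    prob: SegmentationMap
    gamma: float
    n_enlargements: int
    saturated: bool  # still above gamma_star after max_enlargements


def enlarge_until_ok(
    segmenter: Segmenter,
    image: ImageVolume,
    spec: SubVolumeSpec,
    cfg: TracerConfig,
) -> EnlargeResult:
    """Grow the cube while the predicted vessel fraction exceeds ``gamma_star``.

    A high fill fraction means the cube is small relative to the vessel; each
    round multiplies the side by ``enlarge_factor`` and re-segments, up to
    ``max_enlargements`` rounds.  :class:`OutOfBoundsError` from an enlarged
    extraction propagates (the boundary stop criterion).
    """
    for k in range(cfg.max_enlargements + 1):
        sub = extract_subvolume(image, spec, cfg.max_outside_fraction)
        prob = segmenter.segment(sub)
        gamma = float(np.mean(prob.data >= cfg.iso))
        if gamma <= cfg.gamma_star or k == cfg.max_enlargements:
            return EnlargeResult(spec, sub, prob, gamma, k, gamma > cfg.gamma_star)
        spec = SubVolumeSpec(spec.center, spec.side * cfg.enlarge_factor)
    raise AssertionError("unreachable")


def choose_step_points(
    tree: CenterlineTree, cfg: TracerConfig, min_length: float = 0.0
) -> list[StepCandidate]:
    """Step point per branch at arclength fraction ``step_fraction`` from the source.

    Branches shorter than ``min_length`` (nominally two voxels) are dropped.
    The tangent is a central difference at the step point, oriented away from
    the source; the radius is interpolated along the branch.
    """
    out: list[StepCandidate] = []
    for branch in tree.branches:
        pts = branch.points[::-1]  # source -> target
        radii = None if branch.radii is None else branch.radii[::-1]
        if len(pts) < 2:
            continue
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        if total <= max(min_length, 1e-12):
            continue
        s_star = cfg.step_fraction * total
        point = np.array([np.interp(s_star, s, pts[:, a]) for a in range(3)])
        h = max(total * 0.02, 1e-6)
        lo = np.array([np.interp(max(s_star - h, 0.0), s, pts[:, a]) for a in range(3)])
        hi = np.array([np.interp(min(s_star + h, total), s, pts[:, a]) for a in range(3)])
        tangent = hi - lo
        n = np.linalg.norm(tangent)
        if n < 1e-12:
            continue
        tangent /= n
        radius = float(np.interp(s_star, s, radii)) if radii is not None else 0.0
        out.append(StepCandidate(point, tangent, radius, total))
    return out


def update_queue(
    candidates: Sequence[StepCandidate],
) -> tuple[StepCandidate, list[StepCandidate]]:
    """Continue along the largest-radius candidate; the rest become queue pushes.

    The sort is stable, so equal radii preserve discovery order.
    """
    if not candidates:
        raise ValidationError("need at least one step candidate")
    order = sorted(range(len(candidates)), key=lambda i: -candidates[i].radius)
    cont = candidates[order[0]]
    rest = [candidates[i] for i in order[1:]]
    return cont, rest


def sort_queue(queue: list[QueueEntry]) -> None:
    """Radius-descending, discovery-order stable — largest vessels pop first."""
    queue.sort(key=lambda e: (-e.radius, e.order))


def _cube_slices(
    acc: GlobalAccumulator, spec: SubVolumeSpec
) -> tuple[slice, slice, slice] | None:
    lo = (spec.center - spec.side / 2 - acc.origin) / acc.spacing
    hi = (spec.center + spec.side / 2 - acc.origin) / acc.spacing
    i0 = np.maximum(np.ceil(lo - 1e-9).astype(int), 0)
    i1 = np.minimum(np.floor(hi + 1e-9).astype(int), np.array(acc.shape) - 1)
    if np.any(i1 < i0):
        return None
    return tuple(slice(int(a), int(b) + 1) for a, b in zip(i0, i1))  # type: ignore[return-value]


def already_traced(
    acc: GlobalAccumulator,
    spec: SubVolumeSpec,
    branch_id: int,
    current_step: int,
    cfg: TracerConfig,
) -> bool:
    """Has this cube already been fused by *prior* tracing?

    Counts voxels fused at >= 0.5 that were claimed by another branch, or by
    this branch more than ``retrace_buffer_steps`` ago (the buffer keeps the
    check from firing on the branch's own immediately preceding steps).
    True when the prior-fused fraction of the cube exceeds
    ``retrace_overlap``.
    """
    sl = _cube_slices(acc, spec)
    if sl is None or acc.n_accumulated == 0:
        return False
    fusedv = np.zeros_like(acc.wsum[sl])
    m = acc.w[sl] > 0
    fusedv[m] = acc.wsum[sl][m] / acc.w[sl][m]
    claimed = fusedv >= 0.5
    b = acc.branch[sl]
    s = acc.step[sl]
    prior = claimed & (
        ((b >= 0) & (b != branch_id))
        | ((b == branch_id) & (s <= current_step - cfg.retrace_buffer_steps))
    )
    return float(prior.mean()) > cfg.retrace_overlap


def _visited_by_other_branch(
    acc: GlobalAccumulator,
    cand: StepCandidate,
    branch_id: int,
    cfg: TracerConfig,
) -> bool:
    """Is the ball around a step candidate already fused by another branch?

    Used to drop candidates that would walk back into vasculature some other
    branch has traced (e.g. re-entering the trunk from a daughter).
    """
    r = max(cand.radius, float(acc.spacing.max()))
    spec = SubVolumeSpec(cand.point, 2 * r)
    sl = _cube_slices(acc, spec)
    if sl is None or acc.n_accumulated == 0:
        return False
    idx = np.indices(acc.wsum[sl].shape).reshape(3, -1).T
    lo = np.array([s.start for s in sl])
    pts = acc.origin + (idx + lo) * acc.spacing
    ball = np.linalg.norm(pts - cand.point, axis=1) <= r
    if not ball.any():
        return False
    fusedv = np.zeros_like(acc.wsum[sl])
    m = acc.w[sl] > 0
    fusedv[m] = acc.wsum[sl][m] / acc.w[sl][m]
    other = (fusedv.reshape(-1) >= 0.5) & (acc.branch[sl].reshape(-1) >= 0) & (
        acc.branch[sl].reshape(-1) != branch_id
    )
    return float(other[ball].mean()) >= cfg.visited_fraction


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------

def _mask_component_containing(
    prob: SegmentationMap, point: np.ndarray, iso: float
) -> np.ndarray | None:
    """Binary component of the thresholded map containing (or nearest) `point`."""
    binary = prob.data >= iso
    if not binary.any():
        return None
    labels, n = ndimage.label(binary, structure=ndimage.generate_binary_structure(3, 3))
    idx = np.clip(
        np.round(prob.phys_to_index(point)).astype(int), 0, np.array(prob.shape) - 1
    )
    lab = labels[tuple(idx)]
    if lab == 0:
        # nearest foreground voxel decides the component
        _, nearest = ndimage.distance_transform_edt(~binary, return_indices=True)
        nidx = tuple(int(nearest[a][tuple(idx)]) for a in range(3))
        if np.linalg.norm((np.array(nidx) - idx) * prob.spacing) > prob.shape[0] * max(
            prob.spacing
        ):
            return None
        lab = labels[nidx]
        if lab == 0:
            return None
    return labels == lab


def run_trace(
    image: ImageVolume,
    seed: Seed,
    segmenter: Segmenter,
    cfg: TracerConfig | None = None,
    fusion_cfg: FusionConfig | None = None,
) -> TraceResult:
    """Trace the vasculature reachable from a seed and fuse it globally.

    Deterministic: identical image, seed, config and (deterministic)
    segmenter reproduce the step log exactly.  Raises
    :class:`TraceFailedError` only when the very first step fails after all
    chances with nothing fused; boundary termination at the first step is
    reported through the log, not raised.
    """
    cfg = cfg or TracerConfig()
    if not image.contains_point(seed.point):
        raise ValidationError(f"seed point {seed.point} lies outside the image")

    acc = GlobalAccumulator(image, fusion_cfg)
    log: list[dict] = []
    centerlines: list[tuple[int, CenterlineTree]] = []
    queue: list[QueueEntry] = []
    pushed_history: list[tuple[np.ndarray, float]] = []
    min_len = 2.0 * float(image.spacing.min())

    p = seed.point.copy()
    t = seed.direction.copy()
    r = r_prev = seed.radius
    prev_point = p - r * t
    chances = 0
    steps_in_branch = 0
    branch_id = 0
    n_branches = 1
    total_steps = 0
    push_order = 0
    stop_reason = "queue_empty"

    def logev(event: str, **kw) -> None:
        rec = {"event": event, "step": total_steps, "branch": branch_id}
        rec.update(kw)
        log.append(rec)

    def end_branch(reason: str) -> None:
        logev("branch_end", reason=reason, point=p.copy(), radius=r)

    tracing = True
    while tracing:
        branch_done = None  # reason, or None while the branch is alive

        while branch_done is None:
            if total_steps >= cfg.n_max:
                branch_done = "n_max"
                stop_reason = "n_max"
                tracing = False
                break
            total_steps += 1
            L = next_side_length(r, r_prev, cfg.size_multiplier)
            spec = SubVolumeSpec(p.copy(), L)
            failure = None
            result = None
            try:
                enlarged = enlarge_until_ok(segmenter, image, spec, cfg)
            except OutOfBoundsError:
                branch_done = "out_of_bounds"
                break
            spec, prob = enlarged.spec, enlarged.prob
            try:
                comp = _mask_component_containing(prob, p, cfg.iso)
                if comp is None:
                    raise EmptySegmentationError("no vessel voxels in the subvolume")
                mask = SegmentationMap(
                    comp.astype(np.uint8), prob.spacing, prob.origin, prob.index_offset
                )
                masked_prob = SegmentationMap(
                    np.where(comp, prob.data, 0.0),
                    prob.spacing, prob.origin, prob.index_offset,
                )
                surf = extract_surface(masked_prob, iso=cfg.iso)
                caps = find_caps(surf, mask)
                if len(caps) < 2:
                    raise NoOutletError(
                        f"only {len(caps)} truncation boundary in the subvolume"
                    )
                source, targets = assign_source_target(caps, prev_point)
                speed = build_speed(mask)
                field_ = solve_eikonal(speed, source.center)
                tree = trace_centerline(
                    field_, [c.center for c in targets], skip_unreachable=True
                )
                for br in tree.branches:
                    br.radii = estimate_radius(br.points, mask)
                    br.radii = np.maximum(br.radii, 1e-6)
                cands = choose_step_points(tree, cfg, min_length=min_len)
                cands = [
                    c for c in cands
                    if not _visited_by_other_branch(acc, c, branch_id, cfg)
                ]
                if not cands:
                    raise NoOutletError("no fresh step candidate from this subvolume")
                result = (tree, cands)
            except tuple(_FAILURE_REASONS) as exc:
                failure = _FAILURE_REASONS[type(exc)]

            if failure is not None:
                logev("chance", reason=failure, point=p.copy(), radius=r,
                      chances_used=chances)
                if chances >= cfg.max_chances:
                    branch_done = "chances_exhausted"
                    break
                prev_point = p.copy()
                p = take_chance(p, t, r)
                chances += 1
                continue

            # successful step
            tree, cands = result  # type: ignore[misc]
            chances = 0
            steps_in_branch += 1
            acc.accumulate(prob, spec, branch_id=branch_id, step_id=total_steps)
            centerlines.append((branch_id, tree))
            logev(
                "step",
                point=p.copy(),
                radius=r,
                side=spec.side,
                gamma=enlarged.gamma,
                n_enlargements=enlarged.n_enlargements,
                n_caps=len(cands) + 1,
                n_candidates=len(cands),
            )

            cont, rest = update_queue(cands)
            for cand in rest:
                dup = any(
                    np.linalg.norm(cand.point - q_pt)
                    < cfg.dedupe_factor * max(cand.radius, q_r)
                    for q_pt, q_r in pushed_history
                )
                if dup:
                    logev("push_skipped", point=cand.point.copy(), radius=cand.radius)
                    continue
                queue.append(
                    QueueEntry(cand.point.copy(), cand.tangent.copy(),
                               cand.radius, branch_id, push_order)
                )
                pushed_history.append((cand.point.copy(), cand.radius))
                push_order += 1
                logev("push", point=cand.point.copy(), radius=cand.radius)
                sort_queue(queue)

            if cont.radius < cfg.r_min:
                branch_done = "r_min"
                break

            if (
                cfg.retrace_check_period > 0
                and steps_in_branch % cfg.retrace_check_period == 0
            ):
                next_spec = SubVolumeSpec(
                    cont.point,
                    next_side_length(max(cont.radius, 1e-6), r, cfg.size_multiplier),
                )
                if already_traced(acc, next_spec, branch_id, total_steps, cfg):
                    branch_done = "retraced"
                    break

            prev_point = p.copy()
            p = cont.point.copy()
            t = cont.tangent.copy()
            r_prev = r
            r = max(cont.radius, 1e-6)

        # ---- branch finished
        end_branch(branch_done)  # type: ignore[arg-type]
        if branch_id == 0 and acc.n_accumulated == 0 and branch_done == "chances_exhausted":
            raise TraceFailedError(
                "segmentation failed at the very first step after all chances"
            )
        if not tracing:
            break

        # pop the next bifurcation, skipping regions already fused
        started_new = False
        while queue:
            sort_queue(queue)
            entry = queue.pop(0)
            pop_spec = SubVolumeSpec(
                entry.point, cfg.size_multiplier * max(entry.radius, 1e-6)
            )
            if already_traced(acc, pop_spec, -999, total_steps, cfg):
                logev("pop_skipped", point=entry.point.copy(), radius=entry.radius)
                continue
            if cfg.nb_max is not None and n_branches >= cfg.nb_max:
                stop_reason = "nb_max"
                tracing = False
                break
            branch_id += 1
            n_branches += 1
            logev("pop", point=entry.point.copy(), radius=entry.radius)
            p = entry.point.copy()
            t = entry.tangent.copy()
            r = r_prev = max(entry.radius, 1e-6)
            prev_point = p - r * t
            chances = 0
            steps_in_branch = 0
            started_new = True
            break
        if not started_new:
            if stop_reason not in ("nb_max", "n_max"):
                stop_reason = "queue_empty"
            break

    return TraceResult(
        accumulator=acc,
        step_log=log,
        centerlines=centerlines,
        seed=seed,
        config=cfg,
        stop_reason=stop_reason,
        n_steps=total_steps,
        n_branches=n_branches,
    )
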
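# vesseltrace

Sequential tracing and segmentation of branched vascular structures in 3D
medical-style image volumes, starting from a **single seed point**.

Building a simulation-suitable vascular model from CT/MR angiography is
usually a manual bottleneck: centerlines are clicked by hand, lumen contours
are segmented slice by slice, and global voxel classifiers (even strong
U-Net variants) tend to produce disconnected blobs that cannot be meshed for
hemodynamic simulation. `vesseltrace` implements the alternative strategy of
*local* sequential segmentation: segment one vessel-sized subvolume at a
time, walk along the vessel, queue bifurcations, and fuse everything into a
single connected segmentation with a surface mesh — so connectivity is built
in by construction, and the local segmenter only ever has to solve an easy,
geometrically self-similar problem.

The package is aimed at researchers in image-based cardiovascular modeling
who want a testable, fully synthetic-data-backed reference implementation of
this tracing loop, with a pluggable local segmenter (a trained 3D CNN can be
dropped in behind a one-method contract; a deterministic intensity oracle is
shipped for development and testing).

## The algorithm

Given a seed `(p_0, t_0, R_0)` — a point on a vessel, its direction, and a
radius estimate — the tracer repeats:

1. **Subvolume**: extract the cube of side `L = 5 (r_i + r_{i-1}) / 2`
   centered on the current point (radius carried over between steps), and
   enlarge it geometrically while the predicted vessel fraction exceeds
   γ\* = 0.5.
2. **Segment**: call the pluggable segmenter, `Y_p = f(X | θ)`, producing a
   per-voxel vessel probability map on the same grid.
3. **Surface & caps**: extract the 0.5-isosurface (marching cubes); the open
   loops where the vessel is cut by the cube faces are its *truncation
   boundaries*; the one nearest the previous stepping point is the source,
   the rest are targets.
4. **Centerline**: solve the eikonal equation `|∇T| F = 1` with the speed
   `F` equal to the distance from the vessel wall (fast marching restricted
   to the mask, `T = 0` at the source), then run gradient descent on `T`
   from each target back to the source. Per-point radii come from the
   distance transform.
5. **Step**: move to the point 80% of the way along each branch. With more
   than one branch, continue along the largest radius and push the rest on
   a radius-sorted bifurcation queue.
6. **Fuse**: blend the local probabilities into the global map with Gaussian
   weights `w = exp(−d²/σ²)`, `σ = L/4`, as a running weighted mean.

Local failures (empty segmentation, a single cap, unreachable targets)
trigger up to three *chances*: advance one radius along the tangent and
retry. Branches end at the image boundary, below the minimum radius
`R_min = 0.5 mm`, after exhausted chances, or when a periodic check finds
the region already traced. Finalization thresholds the fused map at 0.5,
keeps the largest 26-connected body, and smooths the marching-cubes surface
with a windowed-sinc filter (10 iterations, passband 0.01).

Evaluation uses Dice overlap, the symmetric Hausdorff distance between mask
boundaries (in voxels), and centerline overlap (the fraction of the true
centerline inside the prediction), optionally restricted to the region
within six local radii of the true centerline.

Synthetic tubular phantoms (straight, bent, bifurcating, side-branch and
tapering capsule trees with tunable blur and noise, plus exact ground-truth
masks and centerlines) make every stage testable without any external data.

## Worked example

Trace the Y-bifurcation phantom from one seed in the trunk:

```python
from vesseltrace import (
    make_standard_suite, Seed, TracerConfig, run_trace, OracleSegmenter,
    FusionConfig, finalize, dice, centerline_overlap, hausdorff,
)

case = next(c for c in make_standard_suite() if c.name == "y_bifurcation")
point, direction, radius = case.seed_hint
result = run_trace(
    case.image,
    Seed(point, direction, radius),
    OracleSegmenter(threshold=0.5, smooth_sigma=0.5),
    TracerConfig(),
)
print(f"steps: {result.n_steps}, branches: {result.n_branches}, "
      f"stop: {result.stop_reason}")
print("branch end reasons:", result.branch_end_reasons())
binary, mesh = finalize(result.accumulator, FusionConfig())
print(f"Dice:               {dice(binary, case.truth_mask):.3f}")
print(f"Hausdorff (voxels): {hausdorff(binary, case.truth_mask):.2f}")
print(f"Centerline overlap: {centerline_overlap(binary, case.truth_centerline):.3f}")
```

prints

```
steps: 28, branches: 2, stop: queue_empty
branch end reasons: ['out_of_bounds', 'out_of_bounds']
Dice:               0.912
Hausdorff (voxels): 3.61
Centerline overlap: 0.985
```

The trace walks up the trunk, detects the junction (one queue push), follows
the thicker daughter to the volume boundary, then pops the queue and traces
the thinner daughter — both branches end with the boundary stop reason, the
fused segmentation overlaps the exact phantom truth at Dice 0.91 and covers
98.5% of the true centerline.

The same pipeline is available from the shell:

```sh
vesseltrace make-phantom --spec spec.yaml --out-dir phantom/
vesseltrace trace --image phantom/image.nii.gz --seed 16,16,8 \
    --direction 0,0,1 --radius 2 --segmenter oracle --out-dir traced/
vesseltrace evaluate --pred traced/binary.nii.gz --truth phantom/mask.nii.gz \
    --centerline phantom/centerline.json
```

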
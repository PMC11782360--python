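# Methods

This note documents the model and the numerical choices behind
`vesseltrace`, the assumptions they rest on, and what the synthetic-phantom
tests do and do not demonstrate.

## The tracing model

The tracer assumes vasculature is a tree (or near-tree) of roughly tubular
segments embedded in a 3D scalar volume with axis-aligned identity
orientation, and that a local segmenter can classify vessel voxels inside a
cube a few radii wide. Under those assumptions a single seed
(point, unit direction, radius estimate in mm) determines the whole
reachable tree: each local segmentation yields a surface whose open cut
loops on the cube faces ("caps") enumerate the vessel's continuations, and
stepping 80% along each local centerline advances the trace while leaving
enough overlap to detect junctions reliably.

Subvolume sizing couples the cube to the vessel: `L = m (r_i + r_{i-1}) / 2`
with multiplier `m = 5`, averaging with the previous step's radius so one
underestimated radius cannot collapse the window. The fill-fraction guard
(enlarge while more than γ\* of voxels are predicted vessel) protects
against the converse failure, a cube swallowed by a large vessel. γ\* = 0.5
separates the regimes cleanly: a tube of diameter equal to the cube side
fills π/4 ≈ 0.79 of it, a well-sized cube (L = 5r) fills ≈ 0.13. The
enlargement is geometric (factor 1.25, at most 4 rounds) so it is bounded
and total.

### Centerlines by wave propagation

The local centerline is the gradient-descent path of the eikonal arrival
time `|∇T| F = 1`, `T(source) = 0`, with speed `F` = Euclidean distance to
the vessel wall (plus ε = 10⁻³ mm so boundary voxels remain marchable,
zero outside the mask). Because the wave runs fastest along the medial
axis, descending `T` from a target cap pulls the path onto the centerline.

The solver is a second-order upwind fast-marching method on the voxel grid
(first-order fallback where only one aligned known neighbor exists), with
one refinement: arrival times in a 3-voxel ball around the source are
initialized analytically (trapezoidal travel time along the straight ray,
skipped for rays that leave the mask). This removes the well-known
point-source degradation of upwind schemes, which otherwise contaminates
the entire downstream field with several percent of error.

Descent uses trilinearly interpolated gradients with a step of 0.25 × the
minimum voxel spacing, terminates within one voxel of the source, and
declares a stall after 60 consecutive steps without a new minimum of `T`.
Radii along the path are the interpolated distance-transform values of the
binary mask; measuring to the sub-voxel surface instead is available
(`surface_distance_radius`) but the mask transform is the deterministic
default.

**Accuracy and the Dijkstra oracle.** The tests cross-check arrival times
against an independent 26-neighbor Dijkstra shortest path. Two facts shape
that comparison. First, polygonal 26-neighbor paths can only *overestimate*
the continuous travel time, by up to the chamfer factor
(3√3 + √2 + 5)/√106 ≈ 1.1281 (worst near direction (9,4,3)) — so pointwise
agreement to a few percent with any consistent eikonal solver is
mathematically impossible in unlucky directions; the oracle is a bracket,
not a gold standard. Second, at 20³ with a distance-proportional speed, the
one-voxel wall skin (where the speed field itself is unresolved) and the
few-hop neighborhood of the source are dominated by discretization of the
*conditions* rather than of the solver. The oracle tests therefore assert
the provable envelope — fast marching below the Dijkstra times, Dijkstra
within the chamfer factor of fast marching, each with 5% slack for O(h)
scheme error — plus a 5% bound on the median relative difference, evaluated
two voxels off the wall and five voxels from the source. Self-convergence
under grid refinement on smooth speed fields is at the 1–2% level.

### Bifurcations, chances, retracing

More than one target cap means a junction: the largest-radius candidate is
continued, the rest are queued; the queue is re-sorted by radius on every
push so the largest vessels are traced first (stable sort, discovery order
breaks ties). Because caps are detected locally, the same junction can be
seen by several consecutive cubes; a push is suppressed when its point lies
within 2 × max(radius) of any previously queued point, and a step candidate
is dropped when the ball of one radius around it is ≥ 50% covered by fused
segmentation from *other* branches (re-entering the trunk from a daughter).
The periodic retracing check (every 5 steps, cube overlap fraction > 0.9)
compares against fused voxels claimed by other branches or by this branch
more than 3 steps ago — the buffer keeps a branch from tripping on its own
immediately preceding steps. These four constants are declared defaults in
`TracerConfig`; the underlying mechanism (suppress duplicate bifurcations,
detect loops against past branches with a recent-step buffer) is what the
sequential design requires, and the loop/Y phantom tests pin the behavior.

Failures of a single step — empty segmentation, fewer than two caps, no
reachable target, stalled descent — trigger a *chance*: advance one radius
along the current tangent and retry, at most three consecutive times. The
chance counter is per branch and resets on success. Branch termination
reasons are logged (`out_of_bounds`, `r_min`, `chances_exhausted`,
`retraced`); the trace halts when the queue empties or the global budgets
(`N_max = 500` steps, optional `NB_max` branches) run out. Every loop is
bounded, so termination holds for any segmenter on any finite image.

### Fusion and finalization

Overlapping local predictions are fused as a weighted mean with Gaussian
weights `w = exp(−d²/σ²)`, `σ = L/4`: weight 1 at the cube center, e⁻⁴ ≈
0.02 at a face center (predictions degrade toward patch borders). The
weighted mean `Σws/Σw` leaves constant predictions invariant and keeps
fused values in [0, 1]. Finalization thresholds at t = 0.5 (≥ keeps),
retains the largest 26-connected component (the most permissive
connectivity, preserving thin diagonal vessels), extracts a marching-cubes
surface, and smooths it with a windowed-sinc low-pass: a Hamming-windowed
Chebyshev polynomial of degree 10 (the iteration count) in the uniform
neighbor-averaging operator, passband 0.01 on the Laplacian eigenvalue
axis, DC gain renormalized to exactly 1 so the mesh does not shrink.
Vertex count and connectivity are untouched; the ball-phantom test checks
that discrete curvature energy at least halves.

## Training-patch sampler

Training pairs for a local segmenter are cubes drawn along ground-truth
centerlines: side `L = Rα`, `α ~ N(5, 1)` (redrawn below 0.5 so sides stay
positive — a ~5σ event at the defaults), center offset `βRw`,
`β ~ N(0, 0.8)`, with `w` a random in-plane unit vector built by
normalizing `au + bv`, `a, b ~ U[−1, 1]` over an orthonormal basis of the
perpendicular plane. Note this direction law is *not* uniform in angle:
normalizing a uniform square draw concentrates mass toward the diagonals
(angular density ∝ squared distance to the square boundary, corner-to-edge
ratio 2). The sampler keeps the literal square form; the tests verify
perpendicularity, moment recovery (mean side ratio 5 ± Monte-Carlo error,
E β² = 0.8) and the correct analytic angular law. Centerline tangents are
central differences of the polyline. Patches whose cube leaves the volume
are skipped; a fixed seed reproduces the dataset bitwise.

## Intensity normalization and resampling

MR-style volumes are z-scored per image; CT-style volumes are clipped to
the 0.5/99.5 percentiles of vessel-foreground intensities and z-scored with
foreground statistics *pooled across training cases* and held constant at
inference (per-case foreground statistics would not be available at test
time, which is the point of storing them). Percentiles use linear
interpolation between order statistics; a degenerate σ on constant patches
is guarded with ε = 10⁻⁸ rather than an error. Images resample with cubic
splines, label maps with linear interpolation on one-hot classes followed
by argmax (binary: threshold 0.5), on a cell-centered grid covering the
same physical extent.

## The phantom generator

Phantoms are unions of *capsules* (tube segments with hemispherical ends,
so chained and branching segments join watertight), voxelized at voxel
centers, rendered as a two-level intensity field with Gaussian blur and
seeded additive Gaussian noise. The standard suite uses contrast 1, blur
0.4 mm and noise σ = 0.05 at 0.5 mm spacing (0.3 mm blur at 0.4 mm spacing
for the taper, whose distal segments are thinner) — mild, realistic
boundary ambiguity that the intensity-oracle segmenter handles the way a
well-trained network handles clinical data. The truth mask is the unblurred
indicator; the truth centerline is the branch axes (clipped to the volume)
with per-branch constant radii.

What the phantoms deliberately do **not** model: CT/MR acquisition physics,
contrast-bolus dynamics, intensity inhomogeneity, neighboring bright
organs, pathology (aneurysm/stenosis), or non-circular lumina. Passing the
end-to-end phantom tests therefore demonstrates that the *tracing loop* —
stepping, bifurcation handling, stop criteria, fusion, metrics — is
correct, not that any particular learned segmenter is accurate on clinical
images; segmenter quality enters through the plug-in contract and must be
validated on real data.

## Problem sizes in the test suite

The phantom volumes are 64×64×80 to 92×92×160 voxels at 0.4–0.5 mm
spacing (tubes of radius 0.32–2.1 mm), traced in 10–30 steps of
10–20-voxel cubes; the oracle comparisons use 20³ masks and the metric
oracles ≤ 15³ masks. These sizes make every stage's behavior visible
(junctions, taper below `R_min`, boundary stops) while the full suite runs
in well under a minute on one CPU.

## Known limitations

- Identity orientation only; oblique volumes must be resampled upstream.
- The tracer assumes the seed radius is within roughly a factor of two of
  the true radius; wildly wrong seeds fail at the first step (reported as
  `TraceFailedError`).
- Kissing vessels of similar intensity can be bridged by the local
  segmenter and traced as a false junction; the retracing check limits but
  does not eliminate the damage.
- Hausdorff distances are reported in voxel units of the evaluation grid,
  matching common practice, so they are not comparable across grids with
  different spacing.
- The fused map is a weighted mean of probabilities, not a calibrated
  posterior; thresholding at 0.5 is a convention, not an optimum.
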
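import numpy as np
import pytest
from scipy import ndimage

from oracle_utils import CHAMFER_26, dijkstra_arrival_times, random_blob_mask
from vesseltrace.errors import (
    EmptySegmentationError,
    NoOutletError,
    ValidationError,
)
from vesseltrace.image_io import ImageVolume, SegmentationMap, SubVolumeSpec, extract_subvolume
from vesseltrace.local_geometry import (
    TruncationBoundary,
    assign_source_target,
    build_speed,
    estimate_radius,
    extract_surface,
    find_caps,
    smooth_radii,
    solve_eikonal,
    trace_centerline,
)


def _ball_map(n=24, r=8.0):
    idx = np.indices((n, n, n)).reshape(3, -1).T
    ball = (np.linalg.norm(idx - (n - 1) / 2, axis=1) <= r).reshape(n, n, n)
    return SegmentationMap(ball.astype(float), np.ones(3), np.zeros(3))


def _cylinder_map(n=20, r=4.0, spacing=1.0):
    idx = np.indices((n, n, n)).reshape(3, -1).T.astype(float)
    rho = np.linalg.norm((idx[:, :2] - (n - 1) / 2) * spacing, axis=1)
    cyl = (rho <= r).reshape(n, n, n)
    return SegmentationMap(cyl.astype(float), np.full(3, spacing), np.zeros(3))


class TestSurfaceAndCaps:
    def test_sphere_area_matches_analytic(self):
        # sub-voxel probability ramp puts the 0.5 isosurface exactly at d = r
        n, r = 16, 5.0
        idx = np.indices((n, n, n)).reshape(3, -1).T
        d = np.linalg.norm(idx - (n - 1) / 2, axis=1).reshape(n, n, n)
        prob = np.clip(0.5 + (r - d), 0.0, 1.0)
        mesh = extract_surface(SegmentationMap(prob, np.ones(3), np.zeros(3)))
        assert mesh.area() == pytest.approx(4 * np.pi * r**2, rel=0.10)

    def test_empty_map_raises(self):
        with pytest.raises(EmptySegmentationError):
            extract_surface(SegmentationMap(np.zeros((5, 5, 5)), np.ones(3), np.zeros(3)))

    def test_cylinder_has_two_caps_on_opposite_faces(self):
        vol = _cylinder_map()
        mesh = extract_surface(vol)
        caps = find_caps(mesh, vol)
        assert len(caps) == 2
        assert sorted(c.face_id for c in caps) == [4, 5]  # z- and z+

    def test_closed_sphere_has_no_caps(self):
        vol = _ball_map()
        mesh = extract_surface(vol)
        with pytest.raises(NoOutletError):
            find_caps(mesh, vol)

    def test_y_junction_subvolume_has_three_caps(self, suite):
        case = suite["y_bifurcation"]
        sub = extract_subvolume(
            case.truth_mask, SubVolumeSpec(center=(20, 16, 21), side=10.0)
        )
        mesh = extract_surface(SegmentationMap(sub.data.astype(float), sub.spacing, sub.origin))
        caps = find_caps(mesh, sub)
        assert len(caps) == 3


class TestSourceTargetAssignment:
    def test_nearest_cap_becomes_source(self):
        caps = [
            TruncationBoundary(np.array([0]), np.array([0.0, 0, 1.0]), 4),
            TruncationBoundary(np.array([1]), np.array([0.0, 0, 5.0]), 5),
        ]
        source, targets = assign_source_target(caps, previous_point=(0, 0, 0))
        assert source.center[2] == 1.0 and source.role == "source"
        assert len(targets) == 1 and targets[0].role == "target"

    def test_single_cap_is_source_with_no_targets(self):
        caps = [TruncationBoundary(np.array([0]), np.array([1.0, 0, 0]), 0)]
        source, targets = assign_source_target(caps, previous_point=(0, 0, 0))
        assert source is caps[0] and targets == []

    def test_exact_tie_breaks_on_face_id_stably(self):
        caps = [
            TruncationBoundary(np.array([0]), np.array([0.0, 0, +2.0]), 5),
            TruncationBoundary(np.array([1]), np.array([0.0, 0, -2.0]), 4),
        ]
        for _ in range(3):
            source, _ = assign_source_target(list(caps), previous_point=(0, 0, 0))
            assert source.face_id == 4  # equidistant: lower face id wins


class TestSpeedField:
    def test_tube_axis_speed_approximates_radius(self):
        vol = _cylinder_map(n=20, r=4.0)
        F = build_speed(vol)
        c = (20 - 1) // 2
        assert F.data[c, c, 10] == pytest.approx(4.0, abs=1.0)

    def test_boundary_voxel_speed_is_small_and_outside_zero(self):
        vol = _cylinder_map(n=20, r=4.0)
        F = build_speed(vol)
        inside = vol.data > 0.5
        assert np.all(F.data[~inside] == 0.0)
        # lateral wall shell only (border_value=1 keeps the open tube ends)
        shell = inside & ~ndimage.binary_erosion(inside, border_value=1)
        assert F.data[shell].max() <= 1.0 + 0.1  # one voxel from the wall

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            build_speed(SegmentationMap(np.zeros((4, 4, 4)), np.ones(3), np.zeros(3)))


class TestEikonal:
    def test_constant_speed_recovers_euclidean_distance(self):
        F = ImageVolume(np.ones((20, 20, 20)), np.ones(3), np.zeros(3))
        field = solve_eikonal(F, (0.0, 0.0, 0.0))
        idx = np.indices((20, 20, 20)).reshape(3, -1).T
        eu = np.linalg.norm(idx, axis=1).reshape(20, 20, 20)
        assert np.abs(field.T - eu).max() <= 1.0  # within one voxel over the grid

    def test_arrival_times_causal(self):
        vol = _cylinder_map()
        field = solve_eikonal(build_speed(vol), (9.5, 9.5, 0.0))
        T = field.T
        finite = np.isfinite(T)
        # every reached voxel other than the seeded core descends to a
        # strictly earlier 6-neighbor
        src = field.source_index
        idx = np.argwhere(finite)
        dist_src = np.linalg.norm(idx - np.array(src), axis=1)
        for v, d in zip(idx, dist_src):
            if d <= 3.0:
                continue
            neigh = []
            for ax in range(3):
                for s in (-1, 1):
                    n = v.copy(); n[ax] += s
                    if np.all(n >= 0) and np.all(n < T.shape):
                        neigh.append(T[tuple(n)])
            assert min(neigh) < T[tuple(v)] + 1e-12

    def test_dijkstra_envelope_on_random_masks(self):
        """Fast marching and the 26-neighbor Dijkstra oracle bracket each other.

        Polygonal 26-neighbor paths can only overestimate the continuous
        travel time, by at most the chamfer factor 1.1281; the fast-marching
        field must sit below the oracle and within that factor of it (5%
        slack for the schemes' O(h) errors), with median agreement under 5%.
        Compared where the medium is resolved: two voxels off the wall,
        five voxels from the source.
        """
        rng = np.random.default_rng(0)
        for _ in range(3):
            mask = random_blob_mask(rng)
            sm = SegmentationMap(mask.astype(np.uint8), np.ones(3), np.zeros(3))
            F = build_speed(sm)
            edt = ndimage.distance_transform_edt(mask)
            src = tuple(np.argwhere(edt == edt.max())[0])
            field = solve_eikonal(F, np.array(src, float))
            Td = dijkstra_arrival_times(F.data, F.spacing, src)
            idx = np.indices(mask.shape).reshape(3, -1).T.reshape(*mask.shape, 3)
            dist = np.linalg.norm(idx - np.array(src), axis=-1)
            region = (
                np.isfinite(field.T) & np.isfinite(Td) & mask
                & (edt >= 2.0) & (dist >= 5.0) & (Td > 1e-9)
            )
            Tf, Tdd = field.T[region], Td[region]
            assert np.max(Tf / Tdd) <= 1.05
            assert np.max(Tdd / Tf) <= CHAMFER_26 * 1.05
            assert np.median(np.abs(Tf - Tdd) / Tdd) <= 0.05

    def test_unreachable_region_stays_infinite(self):
        two = np.zeros((12, 12, 12))
        two[1:4, 1:4, 1:4] = 1.0
        two[8:11, 8:11, 8:11] = 1.0
        F = build_speed(SegmentationMap(two, np.ones(3), np.zeros(3)))
        field = solve_eikonal(F, (2.0, 2.0, 2.0))
        assert np.isinf(field.T[9, 9, 9])


class TestCenterline:
    def test_straight_tube_path_hugs_the_axis(self):
        vol = _cylinder_map(n=24, r=4.0)
        F = build_speed(vol)
        c = (24 - 1) / 2
        field = solve_eikonal(F, (c, c, 0.0))
        tree = trace_centerline(field, [(c, c, 23.0)])
        assert len(tree.branches) == 1
        pts = tree.branches[0].points
        dev = np.linalg.norm(pts[:, :2] - c, axis=1)
        assert dev.max() <= 1.0  # within one voxel of the true axis

    def test_y_branches_share_their_proximal_portion(self, suite):
        case = suite["y_bifurcation"]
        sub = extract_subvolume(
            case.truth_mask, SubVolumeSpec(center=(20, 16, 22), side=12.0)
        )
        mask = SegmentationMap(sub.data.astype(float), sub.spacing, sub.origin)
        F = build_speed(mask)
        field = solve_eikonal(F, (20.0, 16.0, 16.5))
        mesh = extract_surface(mask)
        caps = find_caps(mesh, sub)
        _, targets = assign_source_target(caps, previous_point=(20, 16, 12))
        tree = trace_centerline(field, [t.center for t in targets])
        assert len(tree.branches) == 2
        src = tree.source_point
        a, b = tree.branches[0].points, tree.branches[1].points
        prox_a = a[np.linalg.norm(a - src, axis=1) < 3.0]
        for p in prox_a:
            assert np.min(np.linalg.norm(b - p, axis=1)) <= 1.0  # 2 voxels @ 0.5 mm

    def test_target_equal_to_source_yields_degenerate_branch(self):
        from vesseltrace.tracer import TracerConfig, choose_step_points

        vol = _cylinder_map()
        F = build_speed(vol)
        field = solve_eikonal(F, (9.5, 9.5, 0.0))
        src = field.speed.index_to_phys(field.source_index)
        tree = trace_centerline(field, [src])
        assert tree.branches[0].length <= 2.0
        # such stubs are rejected as too short, not traced onward
        assert choose_step_points(tree, TracerConfig(), min_length=2.0) == []


class TestRadiusEstimate:
    def test_tube_radius_recovered_mid_branch(self):
        vol = _cylinder_map(n=30, r=3.0, spacing=0.5)
        axis = np.array([[29 / 2 * 0.5, 29 / 2 * 0.5, z] for z in np.linspace(3, 11, 9)])
        r = estimate_radius(axis, vol)
        assert np.all(np.abs(r - 3.0) <= 0.5 * 0.5 + 0.3)

    def test_point_on_surface_has_near_zero_radius(self):
        vol = _cylinder_map(n=20, r=4.0)
        r = estimate_radius(np.array([[9.5 + 4.0, 9.5, 10.0]]), vol)
        assert r[0] <= 1.0

    def test_taper_radii_monotone_after_smoothing(self, suite):
        case = suite["taper"]
        pts = np.concatenate([b.points for b in case.truth_centerline.branches])
        order = np.argsort(pts[:, 2])
        r = estimate_radius(pts[order], case.truth_mask)
        rs = smooth_radii(r, window=5)
        assert np.all(np.diff(rs) <= 0.15)  # nonincreasing up to voxelization
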
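import numpy as np
import pytest

from conftest import step_log_plain
from vesseltrace.assembly import GlobalAccumulator
from vesseltrace.errors import TraceFailedError, ValidationError
from vesseltrace.image_io import ImageVolume, SegmentationMap, SubVolumeSpec
from vesseltrace.local_geometry import CenterlineBranch, CenterlineTree
from vesseltrace.local_segmentation import Segmenter
from vesseltrace.tracer import (
    Seed,
    StepCandidate,
    TracerConfig,
    already_traced,
    choose_step_points,
    enlarge_until_ok,
    next_side_length,
    run_trace,
    sort_queue,
    take_chance,
    update_queue,
    QueueEntry,
)


class ConstantSegmenter(Segmenter):
    def __init__(self, value: float):
        self.value = value

    def segment(self, subvolume):
        return SegmentationMap(
            np.full(subvolume.shape, self.value), subvolume.spacing,
            subvolume.origin, subvolume.index_offset,
        )


class TestSideLength:
    def test_carried_radius_average(self):
        assert next_side_length(2.0, 2.0) == pytest.approx(10.0)
        assert next_side_length(1.0, 3.0) == pytest.approx(10.0)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValidationError):
            next_side_length(0.0, 1.0)


def test_take_chance_advances_one_radius():
    np.testing.assert_allclose(
        take_chance(np.zeros(3), np.array([1.0, 0, 0]), 2.0), [2.0, 0, 0]
    )


class TestQueueDiscipline:
    def test_largest_radius_continues_rest_queued(self):
        cands = [
            StepCandidate(np.zeros(3), np.array([0, 0, 1.0]), 3.0),
            StepCandidate(np.ones(3), np.array([0, 0, 1.0]), 1.0),
        ]
        cont, rest = update_queue(cands)
        assert cont.radius == 3.0
        assert [c.radius for c in rest] == [1.0]

    def test_queue_pops_largest_radius_first(self):
        q = [
            QueueEntry(np.zeros(3), np.array([0, 0, 1.0]), 2.0, 0, 0),
            QueueEntry(np.ones(3), np.array([0, 0, 1.0]), 5.0, 0, 1),
        ]
        sort_queue(q)
        assert [e.radius for e in q] == [5.0, 2.0]

    def test_radius_tie_preserves_discovery_order(self):
        q = [
            QueueEntry(np.zeros(3), np.array([0, 0, 1.0]), 2.0, 0, 0),
            QueueEntry(np.ones(3), np.array([0, 0, 1.0]), 2.0, 0, 1),
        ]
        sort_queue(q)
        assert [e.order for e in q] == [0, 1]
        cands = [
            StepCandidate(np.zeros(3), np.array([0, 0, 1.0]), 2.0),
            StepCandidate(np.ones(3), np.array([0, 0, 1.0]), 2.0),
        ]
        cont, _ = update_queue(cands)
        assert cont is cands[0]


class TestStepPointChoice:
    def _branch(self, length, n=21):
        # ordered target -> source, so the source is the LAST point
        z = np.linspace(length, 0.0, n)
        pts = np.stack([np.zeros(n), np.zeros(n), z], axis=1)
        return CenterlineBranch(pts, np.full(n, 1.0))

    def test_point_at_80_percent_arclength_from_source(self):
        tree = CenterlineTree([self._branch(10.0)], source_point=np.zeros(3))
        (cand,) = choose_step_points(tree, TracerConfig())
        assert cand.point[2] == pytest.approx(8.0)
        np.testing.assert_allclose(cand.tangent, [0, 0, 1.0], atol=1e-9)

    def test_two_branches_two_candidates(self):
        tree = CenterlineTree([self._branch(10.0), self._branch(6.0)])
        assert len(choose_step_points(tree, TracerConfig())) == 2

    def test_too_short_branch_dropped_without_crash(self):
        tree = CenterlineTree([self._branch(0.0)])
        assert choose_step_points(tree, TracerConfig(), min_length=1.0) == []


class TestEnlargement:
    def _image(self):
        rng = np.random.default_rng(0)
        return ImageVolume(rng.normal(size=(64, 64, 64)), np.full(3, 0.5), np.zeros(3))

    def test_saturated_segmenter_enlarges_to_the_cap(self):
        cfg = TracerConfig()
        res = enlarge_until_ok(
            ConstantSegmenter(1.0), self._image(), SubVolumeSpec((16, 16, 16), 4.0), cfg
        )
        assert res.n_enlargements == cfg.max_enlargements
        assert res.saturated and res.gamma == 1.0

    def test_empty_prediction_never_enlarges(self):
        res = enlarge_until_ok(
            ConstantSegmenter(0.0), self._image(), SubVolumeSpec((16, 16, 16), 4.0),
            TracerConfig(),
        )
        assert res.n_enlargements == 0 and res.gamma == 0.0

    def test_tight_cube_around_tube_needs_enlargement(self, suite, oracle_seg):
        # a cube of side 2R around a tube is ~ pi/4 = 0.785 vessel -> must grow
        case = suite["straight"]
        res = enlarge_until_ok(
            oracle_seg, case.image, SubVolumeSpec((16, 16, 20), 4.0), TracerConfig()
        )
        assert res.n_enlargements >= 1
        assert res.gamma <= 0.5


class TestRetracingPrevention:
    def _acc_with_cube(self, branch_id=0, step_id=1):
        template = ImageVolume(np.zeros((40, 40, 40)), np.full(3, 0.5), np.zeros(3))
        acc = GlobalAccumulator(template)
        spec = SubVolumeSpec((10, 10, 10), 8.0)
        prob = SegmentationMap(
            np.ones((16, 16, 16)), np.full(3, 0.5), np.array([6.0, 6.0, 6.0]),
            index_offset=(12, 12, 12),
        )
        acc.accumulate(prob, spec, branch_id=branch_id, step_id=step_id)
        return acc

    def test_empty_accumulator_is_never_retraced(self):
        template = ImageVolume(np.zeros((40, 40, 40)), np.full(3, 0.5), np.zeros(3))
        acc = GlobalAccumulator(template)
        assert not already_traced(
            acc, SubVolumeSpec((10, 10, 10), 5.0), 0, 10, TracerConfig()
        )

    def test_cube_inside_other_branchs_fusion_is_retraced(self):
        acc = self._acc_with_cube(branch_id=0, step_id=1)
        assert already_traced(
            acc, SubVolumeSpec((10, 10, 10), 5.0), branch_id=1, current_step=10,
            cfg=TracerConfig(),
        )

    def test_own_recent_steps_are_buffered(self):
        acc = self._acc_with_cube(branch_id=0, step_id=9)
        cfg = TracerConfig(retrace_buffer_steps=3)
        assert not already_traced(
            acc, SubVolumeSpec((10, 10, 10), 5.0), branch_id=0, current_step=10, cfg=cfg
        )
        # the same overlap from long-past own steps does count
        acc2 = self._acc_with_cube(branch_id=0, step_id=1)
        assert already_traced(
            acc2, SubVolumeSpec((10, 10, 10), 5.0), branch_id=0, current_step=10, cfg=cfg
        )


class TestRunTrace:
    def test_seed_outside_image_rejected(self, suite, oracle_seg):
        case = suite["straight"]
        with pytest.raises(ValidationError):
            run_trace(case.image, Seed((999, 0, 0), (0, 0, 1), 2.0), oracle_seg)

    def test_first_step_failure_after_chances_raises(self, suite):
        case = suite["straight"]
        pt, d, r = case.seed_hint
        with pytest.raises(TraceFailedError):
            run_trace(case.image, Seed(pt, d, r), ConstantSegmenter(0.0))

    def test_trace_is_deterministic(self, suite, oracle_seg, straight_trace):
        case = suite["straight"]
        pt, d, r = case.seed_hint
        again = run_trace(case.image, Seed(pt, d, r), oracle_seg, TracerConfig())
        assert step_log_plain(again) == step_log_plain(straight_trace)

    def test_chance_counter_resets_after_success(self, y_trace):
        # the daughter branch needed a chance, then stepped on successfully
        events = y_trace.step_log
        for i, e in enumerate(events):
            if e["event"] == "chance":
                later = [x for x in events[i + 1:] if x["branch"] == e["branch"]]
                if any(x["event"] == "step" for x in later):
                    next_chances = [x for x in later if x["event"] == "chance"]
                    if next_chances:
                        assert next_chances[0]["chances_used"] == 0

    def test_radius_carryover_in_cube_sides(self, straight_trace):
        steps = [e for e in straight_trace.step_log if e["event"] == "step"]
        cfg = straight_trace.config
        for prev, cur in zip(steps, steps[1:]):
            expected = cfg.size_multiplier * (cur["radius"] + prev["radius"]) / 2
            assert cur["side"] == pytest.approx(expected, rel=1e-6)

    def test_step_budget_halts_the_trace(self, suite, oracle_seg):
        case = suite["straight"]
        pt, d, r = case.seed_hint
        res = run_trace(case.image, Seed(pt, d, r), oracle_seg, TracerConfig(n_max=3))
        assert res.stop_reason == "n_max"
        assert res.n_steps <= 3

    def test_branch_budget_halts_the_trace(self, suite, oracle_seg):
        case = suite["y_bifurcation"]
        pt, d, r = case.seed_hint
        res = run_trace(case.image, Seed(pt, d, r), oracle_seg, TracerConfig(nb_max=1))
        assert res.n_branches == 1
        assert res.stop_reason == "nb_max"

    def test_bend_is_followed_around_the_corner(self, suite, oracle_seg):
        case = suite["bend"]
        pt, d, r = case.seed_hint
        res = run_trace(case.image, Seed(pt, d, r), oracle_seg, TracerConfig())
        fused = res.accumulator.fused_map().binarize()
        # the far (x+) end of the bend got segmented
        end = case.truth_centerline.branches[-1].points[-1]
        idx = np.round((end - fused.origin) / fused.spacing).astype(int)
        lo = np.maximum(idx - 4, 0)
        hi = np.minimum(idx + 5, np.array(fused.shape))
        assert fused.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].any()
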
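"""Rotation traces, speeds, sector calls, pattern calls, event flags."""

import numpy as np
import pytest

from gutmorph import (
    EventFlags,
    MorphogenesisSchedule,
    PackingSpec,
    RingRotation,
    RotationTrace,
    SectorMap,
    angular_extent,
    boundary_speed,
    call_rotation_pattern,
    classify_leading_edge,
    detect_events,
    generate_trajectory,
    mirror_frame,
    rotation_trace,
    sample_diagonal_configs,
)


class TestAngularExtent:
    def test_symmetric_r_cell_spans_right_half(self, cross_tube):
        lo, hi = angular_extent(cross_tube.cell("4R"), cross_tube.axis)
        assert lo == pytest.approx(-180.0, abs=1.0) or lo == pytest.approx(
            180.0, abs=1.0
        )
        assert (hi - lo) == pytest.approx(180.0, abs=1.0)


class TestRotationTrace:
    def test_static_trace_is_flat(self, static_frames):
        tr = rotation_trace(static_frames, 3)
        assert np.allclose(tr.theta_boundary_1, tr.theta_boundary_1[0])
        assert np.allclose(tr.theta_boundary_2, tr.theta_boundary_2[0])

    def test_quarter_turn_recovered(self, wt_frames_mode1):
        tr = rotation_trace(wt_frames_mode1, 4)
        assert tr.net_rotation == pytest.approx(90.0, abs=2.0)

    def test_int5_exchange_leaves_angles_unchanged(self, wt_frames_mode1):
        """int5 exchanges its cells anterior-posterior without rotating."""
        tr = rotation_trace(wt_frames_mode1, 5)
        assert abs(tr.net_rotation) <= 2.0

    def test_missing_ring_everywhere_rejected(self, static_frames):
        with pytest.raises(ValueError, match="missing"):
            rotation_trace(static_frames, 8)

    def test_gap_recorded_as_nan(self, static_frames):
        broken = [f.copy() for f in static_frames]
        broken[1].cells = [c for c in broken[1].cells if c.owner.ring != 3]
        tr = rotation_trace(broken, 3)
        assert np.isnan(tr.theta_boundary_1[1])
        assert np.isfinite(tr.theta_boundary_1[0])


class TestBoundarySpeed:
    def test_quarter_turn_arithmetic(self):
        """90 deg over 96 min on a 47 um circumference: (90/360)*47/96."""
        times = np.array([337.0, 385.0, 433.0])
        tr = RotationTrace(
            4, times, np.array([0.0, 45.0, 90.0]), np.array([180.0, 225.0, 270.0])
        )
        assert boundary_speed(tr, 47.0) == pytest.approx(
            (90.0 / 360.0) * 47.0 / 96.0, rel=1e-9
        )

    def test_zero_rotation_zero_speed(self):
        tr = RotationTrace(4, [0.0, 8.0], [10.0, 10.0], [190.0, 190.0])
        assert boundary_speed(tr, 47.0) == 0.0

    def test_linear_in_circumference(self):
        tr = RotationTrace(4, [0.0, 10.0], [0.0, 45.0], [180.0, 225.0])
        assert boundary_speed(tr, 94.0) == pytest.approx(2 * boundary_speed(tr, 47.0))

    def test_zero_elapsed_time_rejected(self):
        tr = RotationTrace(4, [10.0, 10.0], [0.0, 1.0], [180.0, 181.0])
        with pytest.raises(ValueError, match="elapsed|timepoints"):
            boundary_speed(tr, 47.0)


class TestSectorMap:
    def test_default_partitions_circle(self):
        sm = SectorMap()
        assert sm.label(0.0) == "dorsal hyp bz1"
        assert sm.label(45.0) == "left muscle"
        assert sm.label(-45.0) == "right muscle"
        assert sm.label(90.0) == "left dorsal hyp bz2"
        assert sm.label(178.0) == "ventral neurons"
        assert sm.label(-178.0) == "ventral neurons"

    def test_mirrored_swaps_sides(self):
        sm = SectorMap().mirrored()
        assert sm.label(45.0) == "right muscle"
        assert sm.label(-90.0) == "left dorsal hyp bz2"
        assert sm.label(0.0) == "dorsal hyp bz1"

    def test_bad_partition_rejected(self):
        with pytest.raises(ValueError):
            SectorMap ((("a", -180.0, 10.0), ("b", 20.0, 180.0)))


class TestLeadingEdge:
    def test_r_pole_at_midline_is_bz1(self, cross_tube):
        """The symmetric fixture's R cells lead at theta=0: bz1."""
        labels = classify_leading_edge(cross_tube, 4)
        assert labels[cross_tube.cell("4R").owner] == "dorsal hyp bz1"

    def test_wt_terminal_position_is_left_bz2(self, wt_frames_mode1):
        labels = classify_leading_edge(wt_frames_mode1[-1], 4)
        r_label = labels[wt_frames_mode1[-1].cell("4R").owner]
        assert r_label == "left dorsal hyp bz2"

    def test_mirrored_frame_maps_to_right_sectors(self, wt_frames_mode1):
        # mid-rotation frame: the leading pole sits inside a sector, not
        # exactly on a boundary angle
        frame = next(f for f in wt_frames_mode1 if f.time == 417.0)
        labels = classify_leading_edge(frame, 4)
        m = mirror_frame(frame)
        mirrored = classify_leading_edge(m, 4, direction="ccw")
        assert labels[frame.cell("4R").owner] == "left dorsal hyp bz2"
        assert mirrored[m.cell("4L").owner] == "right dorsal hyp bz2"

    def test_undetermined_direction(self, cross_tube):
        labels = classify_leading_edge(cross_tube, 4, direction="undetermined")
        assert set(labels.values()) == {"undetermined"}


def _mk_trace(ring, end_b1, t=(393.0, 441.0)):
    times = np.linspace(t[0] - 60, t[1], 8)
    frac = np.clip((times - t[0] + 30) / (t[1] - t[0] + 30), 0, 1)
    b1 = 0.0 + end_b1 * frac
    return RotationTrace(ring, times, b1, b1 + 180.0)


class TestRotationPattern:
    def test_all_full_cw(self, wt_frames_mode1):
        traces = {r: rotation_trace(wt_frames_mode1, r) for r in (2, 3, 4)}
        pat = call_rotation_pattern(traces)
        assert pat.category == "int2,int3,int4"
        assert all(v == "cw" for v in pat.direction.values())

    def test_no_rotation_is_none_category(self, static_frames):
        # static fixture does not cover the scoring window: undetermined;
        # synthetic flat traces covering it give the all-dash category
        traces = {r: _mk_trace(r, 0.0) for r in (2, 3, 4)}
        pat = call_rotation_pattern(traces)
        assert pat.category == "none"
        assert all(v == "none" for v in pat.per_ring.values())

    def test_int2_only_ccw(self):
        """Reversed int2 with static int3/int4 (guidance-mutant-like)."""
        traces = {2: _mk_trace(2, -90.0), 3: _mk_trace(3, 0.0), 4: _mk_trace(4, 0.0)}
        pat = call_rotation_pattern(traces)
        assert pat.category == "int2"
        assert pat.direction[2] == "ccw"
        assert pat.per_ring == {2: "full", 3: "none", 4: "none"}

    def test_partial_interdigitation(self):
        traces = {2: _mk_trace(2, 25.0), 3: _mk_trace(3, 90.0), 4: _mk_trace(4, 90.0)}
        pat = call_rotation_pattern(traces)
        assert pat.per_ring[2] == "partial"
        assert pat.category == "int3,int4"

    def test_window_not_covered_is_undetermined(self, static_frames):
        traces = {r: rotation_trace(static_frames, r) for r in (2, 3)}
        pat = call_rotation_pattern(traces)
        assert all(v == "undetermined" for v in pat.per_ring.values())


class TestDetectEvents:
    def test_wild_type_mode1(self, wt_frames_mode1):
        flags = detect_events(wt_frames_mode1)
        assert flags.pre_rotation_shift_2L is True
        assert 289.0 <= flags.shift_onset <= 313.0
        assert flags.int2_mode == 1

    def test_wild_type_mode2(self, wt_frames_mode2):
        flags = detect_events(wt_frames_mode2)
        assert flags.int2_mode == 2
        assert flags.pre_rotation_shift_2L is True

    def test_symmetric_static_has_no_shift(self, static_frames):
        flags = detect_events(static_frames)
        assert flags.pre_rotation_shift_2L is False
        assert flags.int2_mode == "undetermined"

    def test_int7_counterclockwise(self):
        spec = PackingSpec(n_rings=8)
        configs = sample_diagonal_configs(spec)
        sched = MorphogenesisSchedule((RingRotation(7, 8.0, 40.0, 30.0, "ccw"),))
        frames = generate_trajectory(spec, sched, 0.0, 48.0, 8.0, configs=configs)
        assert detect_events(frames).int7_direction == "ccw"

    def test_mirror_flips_all_directions(self, wt_frames_mode1):
        sub = wt_frames_mode1[::4]
        mirrored = [mirror_frame(f) for f in sub]
        for ring in (3, 4):
            assert rotation_trace(mirrored, ring).net_rotation == pytest.approx(
                -rotation_trace(sub, ring).net_rotation, abs=1e-6
            )
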
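"""Diagonal-contact classification: calls, tables, transitions."""

import numpy as np
import pandas as pd
import pytest

from gutmorph import (
    CATEGORIES,
    DiagonalCall,
    JunctionConversion,
    MorphogenesisSchedule,
    PackingSpec,
    RingPairCall,
    ScoringMode,
    call_transition_events,
    classify_pair,
    contact_area_timeseries,
    generate_trajectory,
    sample_diagonal_configs,
    tabulate_calls,
)


class TestClassifyPair:
    def test_hexagonal_tube_is_double_ral(self, ral_tube):
        """Posterior pairs of the ideal hexagonal tube make two distinct
        RaL contacts (the R cell touches two faces of the anterior L)."""
        call = classify_pair(None, ral_tube, 6)
        assert call.category == "RaL+RaL"
        assert len(call.areas) == 2 and min(call.areas) > 1.0

    def test_common_vertex_is_double_cross(self, cross_tube):
        call = classify_pair(None, cross_tube, 4)
        assert call.category == "C+C"

    def test_int2_vs_divided_int1_is_ral_plus_lar(self, larval_tube):
        """int2 contacts the 4-cell int1 ring through 2R-1LD (RaL) and
        2L-1RV (LaR)."""
        call = classify_pair(None, larval_tube, 2)
        assert call.category == "RaL+LaR"
        assert call.junctions == {"dorsal": "RaL", "ventral": "LaR"}

    def test_recovers_sampled_ground_truth(self, mixed_tube):
        _, configs, frame = mixed_tube
        short = {"RaL": "RaL", "LaR": "LaR", "Cross": "C"}
        order = {"RaL": 0, "LaR": 1, "C": 2}
        for ring in (2, 4, 9):
            truth = next(c for c in configs if c["interface"] == ring)
            expected = "+".join(
                sorted(
                    (short[truth["dorsal"]], short[truth["ventral"]]),
                    key=order.__getitem__,
                )
            )
            assert classify_pair(None, frame, ring).category == expected

    def test_roof_mode_sees_only_the_dorsal_junction(self, larval_tube):
        """A contact on the ventral side of the tube (the int2-int1 LaR)
        is invisible in roof-plane scoring but present whole-surface."""
        whole = classify_pair(None, larval_tube, 2)
        roof = classify_pair(None, larval_tube, 2, ScoringMode("roof_plane"))
        assert whole.category == "RaL+LaR"
        assert roof.category == "RaL"
        assert len(roof.components) == 1

    def test_missing_ring_reported(self, ral_tube):
        frame = ral_tube.copy()
        frame.cells = [c for c in frame.cells if c.owner.ring != 4]
        with pytest.raises(ValueError, match="4"):
            classify_pair(None, frame, 5)

    def test_rigid_motion_invariance(self, cross_tube):
        import trimesh

        from gutmorph.geometry import TubeAxis

        moved = cross_tube.copy()
        rot = trimesh.transformations.rotation_matrix(0.4, [0, 0, 1])
        for c in moved.cells:
            v = trimesh.transform_points(c.mesh.vertices, rot) + (1.0, 2.0, 3.0)
            c.mesh = trimesh.Trimesh(v, c.mesh.faces, process=False)
        cl = moved.axis.centerline
        cl = trimesh.transform_points(cl, rot) + (1.0, 2.0, 3.0)
        dr = trimesh.transform_points(
            moved.axis.dorsal_ref[None, :], rot, translate=False
        )[0]
        moved.axis = TubeAxis(cl, dr, moved.axis.circumference)
        assert classify_pair(None, moved, 5).category == "C+C"


class TestTabulate:
    @staticmethod
    def _calls_from_configs(configs):
        short = {"RaL": DiagonalCall.RaL, "LaR": DiagonalCall.LaR, "Cross": DiagonalCall.Cross}
        return [
            RingPairCall(
                c["interface"], (short[c["dorsal"]], short[c["ventral"]]), (1.0, 1.0)
            )
            for c in configs
        ]

    def test_degenerate_population_is_100_percent_ral(self):
        spec = PackingSpec(n_rings=3, p_RaL=1.0, p_LaR=0.0, p_Cross=0.0)
        calls = []
        for seed in range(250):
            rng = np.random.default_rng(seed)
            calls += self._calls_from_configs(sample_diagonal_configs(spec, rng))
        table = tabulate_calls(calls).table
        assert (table["RaL+RaL"] == 100.0).all()
        assert (table["n"] == 250).all()

    def test_rows_sum_to_100(self):
        spec = PackingSpec(n_rings=5, p_RaL=0.5, p_LaR=0.25, p_Cross=0.25, seed=3)
        calls = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            calls += self._calls_from_configs(sample_diagonal_configs(spec, rng))
        table = tabulate_calls(calls).table
        assert np.allclose(table[list(CATEGORIES)].sum(axis=1), 100.0)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="no calls"):
            tabulate_calls([])


class TestTimeseries:
    def test_static_frames_give_constant_series(self, static_frames):
        ts = contact_area_timeseries(static_frames, 3)
        assert ts.ral_area.nunique() == 1
        assert ts.lar_area.nunique() == 1

    def test_series_bounded_by_lateral_areas(self, static_frames):
        frame = static_frames[0]
        ts = contact_area_timeseries(static_frames[:1], 3)
        bound = min(
            frame.cell("3R").area, frame.cell("2L").area
        )
        assert ts.ral_area.iloc[0] + ts.lar_area.iloc[0] < bound

    def test_missing_ring_gives_nan(self, static_frames):
        broken = [f.copy() for f in static_frames]
        broken[1].cells = [c for c in broken[1].cells if c.owner.ring != 3]
        ts = contact_area_timeseries(broken, 3)
        assert np.isnan(ts.ral_area.iloc[1])
        assert np.isfinite(ts.ral_area.iloc[0])


@pytest.fixture(scope="module")
def conversion_frames():
    """Small tube whose ring-2/3 interface converts LaR -> RaL."""
    spec = PackingSpec(n_rings=3)
    configs = [
        {"interface": 2, "dorsal": "LaR", "ventral": "LaR"},
        {"interface": 3, "dorsal": "LaR", "ventral": "LaR"},
    ]
    sched = MorphogenesisSchedule(
        (JunctionConversion(3, "both", "RaL", 16.0, 48.0),)
    )
    return generate_trajectory(spec, sched, 0.0, 64.0, 8.0, configs=configs)


class TestTransitions:
    def test_lar_to_ral_passes_through_cross_once(self, conversion_frames):
        ev = call_transition_events(conversion_frames, 3)
        calls = ev.call.tolist()
        assert calls[0] == "LaR" and calls[-1] == "RaL"
        order = {"LaR": 0, "Cross": 1, "RaL": 2, None: 99}
        ranks = [order[c] for c in calls if c is not None]
        assert ranks == sorted(ranks)  # no reversions

    def test_constant_geometry_constant_calls(self, static_frames):
        ev = call_transition_events(static_frames, 3)
        assert ev.call.nunique() == 1
        assert not ev.detached.any()

    def test_roof_gap_flags_detachment(self, wt_frames_mode1):
        """Before intercalation the int2 cells leave a dorsal gap: the
        within-ring roof contact is absent and the frame is flagged."""
        early = [f for f in wt_frames_mode1 if f.time <= 265.0]
        ev = call_transition_events(early, 2)
        assert ev.detached.all()
        # just after closure (and before the ring rotates the boundary
        # away from the dorsal midline) the partners touch at the roof
        closed = [f for f in wt_frames_mode1 if 353.0 <= f.time <= 361.0]
        ev2 = call_transition_events(closed, 2)
        assert not ev2.detached.any()

    def test_needs_two_frames(self, static_frames):
        with pytest.raises(ValueError, match="2 frames"):
            call_transition_events(static_frames[:1], 3)
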
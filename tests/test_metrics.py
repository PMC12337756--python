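"""Sinuosity, flight speed and time-budget metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flutterpath.metrics import (
    DegenerateSegmentError,
    SegmentGeometry,
    flight_speed,
    segment_geometry,
    sinuosity,
    summarize_track,
    time_budget,
    weighted_sinuosity,
)
from flutterpath.stops import consolidate
from flutterpath.trajectory import StopEvent
from tests.conftest import make_traj


def seg(p, c, b):
    return SegmentGeometry(np.array([p]), np.array([math.acos(min(c, 1.0))]),
                           p=p, c=c, b=b)


class TestSegmentGeometry:
    def test_straight_east(self):
        pts = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        g = segment_geometry(pts)
        assert g.p == 1.0
        assert g.c == 1.0
        assert g.b == 0.0
        np.testing.assert_allclose(g.turning_angles, 0.0, atol=1e-12)

    def test_alternating_right_angles(self):
        # unit steps E, N, E, N ... alternating +-90 degrees
        xs = [0, 1, 1, 2, 2, 3]
        ys = [0, 0, 1, 1, 2, 2]
        g = segment_geometry(np.column_stack([xs, ys]).astype(float))
        assert g.c == pytest.approx(0.0, abs=1e-12)
        assert g.b == 0.0

    def test_matches_bruteforce_trigonometry(self, rng):
        """Steps and angles equal an independent per-point
        recomputation to 1e-12."""
        pts = np.cumsum(rng.normal(0, 1, size=(50, 2)), axis=0)
        g = segment_geometry(pts)
        steps, headings = [], []
        for i in range(49):
            dx, dy = pts[i + 1] - pts[i]
            steps.append(math.sqrt(dx * dx + dy * dy))
            headings.append(math.atan2(dy, dx))
        angles = []
        for i in range(48):
            a = headings[i + 1] - headings[i]
            while a <= -math.pi:
                a += 2 * math.pi
            while a > math.pi:
                a -= 2 * math.pi
            angles.append(a)
        np.testing.assert_allclose(g.step_lengths, steps, atol=1e-12)
        np.testing.assert_allclose(g.turning_angles, angles, atol=1e-12)
        assert g.p == pytest.approx(np.mean(steps), abs=1e-12)
        assert g.c == pytest.approx(np.mean(np.cos(angles)), abs=1e-12)
        assert g.b == pytest.approx(np.std(steps) / np.mean(steps), abs=1e-12)

    def test_duplicate_fixes_merged(self):
        pts = np.array([[0, 0], [1, 0], [1, 0], [2, 0], [2, 1]], dtype=float)
        g = segment_geometry(pts)
        assert len(g.step_lengths) == 3  # duplicate collapsed

    def test_single_point_degenerate(self):
        with pytest.raises(DegenerateSegmentError):
            segment_geometry(np.array([[0.0, 0.0]]))


class TestSinuosity:
    @pytest.mark.parametrize("p,c,b,expected", [
        (1.0, 0.0, 0.0, 2.0),
        (4.0, 0.0, 0.0, 1.0),
        (1.0, 0.5, 0.0, 2.0 * 3.0**-0.5),
    ])
    def test_closed_forms(self, p, c, b, expected):
        assert sinuosity(seg(p, c, b)) == pytest.approx(expected, rel=1e-12)

    def test_straight_path_limit_zero(self):
        assert sinuosity(seg(1.0, 1.0, 0.0)) == 0.0

    @given(st.floats(0.1, 10), st.floats(-0.9, 0.95), st.floats(0, 2))
    @settings(max_examples=150, deadline=None)
    def test_monotone_decreasing_in_c_and_p(self, p, c, b):
        base = sinuosity(seg(p, c, b))
        assert sinuosity(seg(p, min(c + 0.01, 0.96), b)) < base
        assert sinuosity(seg(p * 1.1, c, b)) < base

    def test_scale_law(self, rng):
        """Scaling coordinates by k scales sinuosity by k^(-1/2)."""
        pts = np.cumsum(rng.normal(0, 1, size=(60, 2)), axis=0)
        s1 = sinuosity(segment_geometry(pts))
        s4 = sinuosity(segment_geometry(4.0 * pts))
        assert s4 == pytest.approx(s1 / 2.0, rel=1e-10)


class TestWeightedSinuosity:
    def test_single_segment_identity(self):
        g = seg(1.0, 0.0, 0.0)
        assert weighted_sinuosity([(g, 12.0)]) == sinuosity(g)

    def test_two_segment_weighted_mean(self):
        g1 = seg(1.0, 0.0, 0.0)    # Sin = 2.0
        g4 = seg(4.0, 0.0, 0.0)    # Sin = 1.0
        # 2.0 over 10 m and 1.0 over 30 m -> 1.25
        assert weighted_sinuosity([(g1, 10.0), (g4, 30.0)]) == pytest.approx(1.25)

    def test_matches_explicit_sum(self, rng):
        segs = [(seg(float(rng.uniform(0.5, 3)), float(rng.uniform(-0.3, 0.9)), 0.2),
                 float(rng.uniform(1, 50))) for _ in range(8)]
        expected = (sum(sinuosity(g) * w for g, w in segs)
                    / sum(w for _, w in segs))
        assert weighted_sinuosity(segs) == pytest.approx(expected, abs=1e-12)

    def test_all_degenerate_errors(self):
        bad = SegmentGeometry(np.array([1.0]), np.array([]), p=1.0, c=float("nan"), b=0.0)
        with pytest.raises(DegenerateSegmentError):
            weighted_sinuosity([(bad, 5.0)])


class TestFlightSpeedAndBudget:
    def _stopped_track(self):
        """600 s: flight 0-149, stop [150, 449] (300 s), flight 450-600.
        Flight at 0.3 m/s."""
        t = np.arange(601)
        x = np.where(t < 150, 0.3 * t,
                     np.where(t <= 450, 45.0, 45.0 + 0.3 * (t - 450)))
        traj = make_traj(t, x.astype(float), np.zeros(601))
        events = [StopEvent(150, 450, "nectaring")]
        return consolidate(traj, events)

    def test_flight_speed_excludes_stop_time(self):
        pt = self._stopped_track()
        assert flight_speed(pt) == pytest.approx(0.3, rel=1e-9)

    def test_gross_speed_divides_total_duration(self):
        pt = self._stopped_track()
        assert flight_speed(pt, gross=True) == pytest.approx(90.0 / 600.0, rel=1e-9)

    def test_adding_stop_leaves_flight_speed_unchanged(self):
        t = np.arange(101)
        traj = make_traj(t, t.astype(float), np.zeros(101))
        v0 = flight_speed(consolidate(traj, []))
        # freeze the middle 20 s at one location
        x = np.where(t <= 40, t.astype(float), np.where(t <= 60, 40.0, t - 20.0))
        traj2 = make_traj(t, x, np.zeros(101))
        v1 = flight_speed(consolidate(traj2, [StopEvent(40, 60)]))
        assert v1 == pytest.approx(v0, rel=1e-9)

    def test_time_budget_example(self):
        """600 s with 300 s stopped; nectaring 120 s within it."""
        t = np.arange(601)
        x = np.where(t < 100, t.astype(float),
                     np.where(t <= 400, 100.0,
                              np.where(t < 420, 100.0 + (t - 400),
                                       np.where(t <= 520, 120.0, 120.0 + t - 520)))).astype(float)
        events = [StopEvent(100, 220, "nectaring"), StopEvent(220, 400, "unknown")]
        # overlapping at 220 not allowed; shift
        events = [StopEvent(100, 220, "nectaring"), StopEvent(221, 400, "resting"),
                  StopEvent(420, 520, "basking")]
        pt = consolidate(make_traj(t, x, np.zeros(601)), events)
        stopping, nectaring, resting = time_budget(pt)
        assert stopping == pytest.approx((120 + 179 + 100) / 600)
        assert nectaring == pytest.approx(120 / 600)
        assert resting == pytest.approx(179 / 600)

    def test_no_stops_zero_shares(self, straight_track):
        pt = consolidate(straight_track, [])
        assert time_budget(pt) == (0.0, 0.0, 0.0)

    def test_budget_matches_per_second_enumeration(self, rng):
        """Shares equal a brute-force per-second classification."""
        from flutterpath.simulate import TrackSimConfig, simulate_track
        for k in range(10):
            cfg = TrackSimConfig(n_steps=120, stop_rate=6.0, stop_duration_mean_s=8.0,
                                 gap_prob=0.02)
            traj, events, _ = simulate_track(cfg, seed=900 + k)
            pt = consolidate(traj, events)
            stopping, nectaring, resting = time_budget(pt)
            t0, t1 = int(pt.t[0]), int(pt.t[-1])
            n_stop = n_nect = n_rest = 0
            for s in range(t0, t1):
                for ev in events:
                    if ev.start_s <= s < ev.end_s:
                        n_stop += 1
                        if ev.activity.value == "nectaring":
                            n_nect += 1
                        if ev.activity.value == "resting":
                            n_rest += 1
                        break
            dur = t1 - t0
            assert stopping == pytest.approx(n_stop / dur, abs=1e-12)
            assert nectaring == pytest.approx(n_nect / dur, abs=1e-12)
            assert resting == pytest.approx(n_rest / dur, abs=1e-12)

    def test_budget_ordering_invariant(self, track_with_stop):
        traj, events = track_with_stop
        stopping, nectaring, resting = time_budget(consolidate(traj, events))
        assert 0.0 <= nectaring + resting <= stopping <= 1.0


class TestSummarizeTrack:
    def test_scale_law_speed(self, rng):
        from flutterpath.simulate import TrackSimConfig, simulate_track
        traj, events, _ = simulate_track(TrackSimConfig(n_steps=150, gap_prob=0.0), seed=3)
        s1 = summarize_track(consolidate(traj, events))
        traj2 = traj.with_coords(traj.x * 4.0, traj.y * 4.0)
        s2 = summarize_track(consolidate(traj2, events))
        # geometric-median tolerance is absolute (1e-4 m), so stop
        # centres are not exactly scale-covariant; allow that slack
        assert s2.flight_speed == pytest.approx(4.0 * s1.flight_speed, rel=1e-4)
        assert s2.sinuosity == pytest.approx(s1.sinuosity / 2.0, rel=1e-4)

    def test_duration_weighting_switch(self, rng):
        from flutterpath.simulate import TrackSimConfig, simulate_track
        traj, events, _ = simulate_track(TrackSimConfig(n_steps=200, gap_prob=0.05), seed=11)
        pt = consolidate(traj, events)
        a = summarize_track(pt, weight="length")
        d = summarize_track(pt, weight="duration")
        assert a.sinuosity > 0 and d.sinuosity > 0
        with pytest.raises(ValueError):
            summarize_track(pt, weight="area")
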
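"""Track readers, projection accuracy, gap detection and splitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flutterpath.trajectory import (
    Gap,
    StopEvent,
    TrackParseError,
    TrackValidationError,
    detect_gaps,
    read_events,
    read_track,
    read_transect,
    split_on_gaps,
    write_track,
)
from tests.conftest import make_traj


# --- independent geodesic oracle (Vincenty inverse, WGS84) ----------------

def vincenty_distance(lon1, lat1, lon2, lat2):
    a, f = 6378137.0, 1 / 298.257223563
    b = a * (1 - f)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - f) * math.tan(math.radians(lat1)))
    U2 = math.atan((1 - f) * math.tan(math.radians(lat2)))
    sinU1, cosU1, sinU2, cosU2 = math.sin(U1), math.cos(U1), math.sin(U2), math.cos(U2)
    lam = L
    for _ in range(200):
        sinl, cosl = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sinl, cosU1 * sinU2 - sinU1 * cosU2 * cosl)
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cosl
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sinl / sin_sigma
        cos2_alpha = 1 - sin_alpha**2
        cos_2sm = cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha if cos2_alpha else 0.0
        C = f / 16 * cos2_alpha * (4 + f * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * f * sin_alpha * (
            sigma + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1 + 2 * cos_2sm**2))
        )
        if abs(lam - lam_prev) < 1e-12:
            break
    u2 = cos2_alpha * (a**2 - b**2) / b**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    d_sigma = B * sin_sigma * (cos_2sm + B / 4 * (
        cos_sigma * (-1 + 2 * cos_2sm**2)
        - B / 6 * cos_2sm * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos_2sm**2)))
    return b * A * (sigma - d_sigma)


class TestReadTrack:
    def test_identity_read(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("t,x,y\n0,0,0\n1,1,0\n2,2,0\n")
        traj = read_track(p, sex="female")
        assert traj.n_points == 3
        assert traj.duration == 2
        np.testing.assert_array_equal(traj.x, [0, 1, 2])

    def test_shuffled_rows_sorted(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("t,x,y\n2,2,0\n0,0,0\n1,1,0\n")
        traj = read_track(p, sex="female")
        np.testing.assert_array_equal(traj.t, [0, 1, 2])
        np.testing.assert_array_equal(traj.x, [0, 1, 2])

    def test_duplicate_timestamp_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("t,x,y\n0,0,0\n1,1,0\n1,2,0\n")
        with pytest.raises(TrackValidationError, match="duplicate"):
            read_track(p)

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("t,x,y\n0,0,0\n1,oops,0\n")
        with pytest.raises(TrackParseError, match="line 3"):
            read_track(p)

    def test_roundtrip_preserves_geometry(self, tmp_path, rng):
        t = np.arange(40)
        x = rng.normal(0, 30, 40)
        y = rng.normal(0, 30, 40)
        traj = make_traj(t, x, y)
        write_track(traj, tmp_path / "w.csv")
        back = read_track(tmp_path / "w.csv", sex="female")
        np.testing.assert_array_equal(back.t, t)
        np.testing.assert_allclose(back.x, x, atol=1e-6)
        np.testing.assert_allclose(back.y, y, atol=1e-6)

    def test_lonlat_projection_matches_geodesic(self, tmp_path, rng):
        """Projected step lengths agree with Vincenty within 0.1%
        for a ~100-m lon/lat track."""
        lon0, lat0 = 13.3, 52.5  # Berlin-ish
        lons = lon0 + np.cumsum(rng.normal(0, 2e-5, 30))
        lats = lat0 + np.cumsum(rng.normal(0, 1.2e-5, 30))
        lines = ["t,lon,lat"] + [f"{i},{lo:.12f},{la:.12f}" for i, (lo, la) in
                                 enumerate(zip(lons, lats))]
        p = tmp_path / "geo.csv"
        p.write_text("\n".join(lines))
        traj = read_track(p, sex="female")
        assert traj.crs.startswith("local-tangent")
        for i in range(29):
            proj = math.hypot(traj.x[i + 1] - traj.x[i], traj.y[i + 1] - traj.y[i])
            geo = vincenty_distance(lons[i], lats[i], lons[i + 1], lats[i + 1])
            assert proj == pytest.approx(geo, rel=1e-3)

    def test_geojson_input(self, tmp_path):
        import json
        feats = [{"type": "Feature", "properties": {"t": i},
                  "geometry": {"type": "Point", "coordinates": [13.3 + i * 1e-5, 52.5]}}
                 for i in range(5)]
        p = tmp_path / "t.geojson"
        p.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
        traj = read_track(p, sex="female")
        assert traj.n_points == 5
        # ~0.68 m per 1e-5 deg lon at 52.5N
        assert np.all(np.diff(traj.x) > 0.5)


class TestEventAndTransectReaders:
    def test_events_roundtrip(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("start_s,end_s,activity\n10,20,nectaring\n30,35,resting\n")
        events = read_events(p)
        assert [e.duration for e in events] == [10, 5]

    def test_transect_contiguity_enforced(self, tmp_path):
        p = tmp_path / "tr.csv"
        p.write_text("segment,np_cover_pct\n1,10\n3,20\n")
        with pytest.raises(TrackValidationError, match="contiguous"):
            read_transect(p)


class TestGaps:
    def test_continuous_sampling_no_gaps(self, straight_track):
        assert detect_gaps(straight_track, 5) == []

    def test_single_hole_counted(self):
        t = np.concatenate([np.arange(10), np.arange(40, 50)])
        traj = make_traj(t, t.astype(float), np.zeros(20))
        gaps = detect_gaps(traj, 5)
        assert gaps == [Gap(after_t=9, missing_duration=30)]

    def test_threshold_below_two_rejected(self, straight_track):
        with pytest.raises(ValueError):
            detect_gaps(straight_track, 1)

    @given(st.lists(st.integers(1, 8), min_size=3, max_size=40),
           st.integers(2, 6))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_scan(self, deltas, threshold):
        """Gap set identical to a brute-force scan of every interval."""
        t = np.concatenate([[0], np.cumsum(deltas)])
        traj = make_traj(t, np.arange(len(t), dtype=float), np.zeros(len(t)))
        expected = [Gap(int(t[i]), int(t[i + 1] - t[i]) - 1)
                    for i in range(len(t) - 1) if t[i + 1] - t[i] >= threshold]
        assert detect_gaps(traj, threshold) == expected

    @given(st.lists(st.integers(1, 8), min_size=3, max_size=40),
           st.integers(2, 6))
    @settings(max_examples=60, deadline=None)
    def test_split_partitions_points(self, deltas, threshold):
        t = np.concatenate([[0], np.cumsum(deltas)])
        traj = make_traj(t, np.arange(len(t), dtype=float), np.zeros(len(t)))
        gaps = detect_gaps(traj, threshold)
        segs = split_on_gaps(traj, gaps)
        assert len(segs) == len(gaps) + 1
        flat = [i for seg in segs for i in seg]
        assert flat == list(range(traj.n_points))

    def test_no_gap_single_segment(self, straight_track):
        segs = split_on_gaps(straight_track, [])
        assert segs == [range(0, 60)]


class TestTrajectoryInvariants:
    def test_nonmonotone_time_rejected(self):
        with pytest.raises(TrackValidationError):
            make_traj([0, 2, 1], [0, 1, 2], [0, 0, 0])

    def test_too_few_points_rejected(self):
        with pytest.raises(TrackValidationError):
            make_traj([0], [0.0], [0.0])

    def test_overlong_track_warns_not_errors(self):
        t = np.array([0, 800])
        with pytest.warns(UserWarning, match="protocol maximum"):
            traj = make_traj(t, [0.0, 1.0], [0.0, 0.0])
        assert traj.duration == 800

    def test_overlapping_events_invalid_via_matching(self):
        from flutterpath.stops import match_stops
        traj = make_traj(np.arange(30), np.zeros(30), np.zeros(30))
        with pytest.raises(ValueError, match="overlap"):
            match_stops(traj, [StopEvent(5, 10), StopEvent(8, 12)])
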
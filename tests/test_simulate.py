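"""Synthetic-data generators: determinism, closed-form targets,
round-trips through the readers, and end-to-end metric recovery."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from flutterpath.covariates import class_sealing_means, impute_sealing, zonal_urbanization
from flutterpath.metrics import summarize_track
from flutterpath.simulate import (
    StudySimConfig,
    TrackSimConfig,
    kappa_for_mean_cos,
    mean_cos_von_mises,
    simulate_landscape,
    simulate_study,
    simulate_track,
    simulate_transect,
    theoretical_sinuosity,
)
from flutterpath.stops import consolidate
from flutterpath.trajectory import read_events, read_track, read_transect, write_events, write_track, write_transect


class TestVonMisesTargets:
    @pytest.mark.parametrize("c", [0.0, 0.3, 0.5, 0.8, 0.95])
    def test_kappa_inversion_roundtrip(self, c):
        assert mean_cos_von_mises(kappa_for_mean_cos(c)) == pytest.approx(c, abs=1e-8)

    def test_sample_mean_cos_matches(self, rng):
        kappa = kappa_for_mean_cos(0.5)
        draws = rng.vonmises(0.0, kappa, size=200_000)
        assert np.cos(draws).mean() == pytest.approx(0.5, abs=0.005)


class TestSimulateTrack:
    def test_deterministic_under_seed(self):
        cfg = TrackSimConfig(n_steps=150)
        t1, e1, g1 = simulate_track(cfg, seed=9)
        t2, e2, g2 = simulate_track(cfg, seed=9)
        np.testing.assert_array_equal(t1.x, t2.x)
        assert e1 == e2 and g1 == g2

    def test_no_stops_when_rate_zero(self):
        cfg = TrackSimConfig(n_steps=200, stop_rate=0.0, gap_prob=0.0)
        traj, events, truth = simulate_track(cfg, seed=4)
        assert events == []
        assert truth["stopping_share"] == 0.0
        assert traj.n_points == 201

    def test_near_straight_limit(self):
        """kappa -> large gives near-zero estimated sinuosity."""
        cfg = TrackSimConfig(n_steps=300, turn_kappa=5000.0, step_cv_b=0.0,
                             stop_rate=0.0, gap_prob=0.0)
        traj, events, _ = simulate_track(cfg, seed=5)
        s = summarize_track(consolidate(traj, events))
        assert s.sinuosity < 0.05 * theoretical_sinuosity(1.0, 0.0, 0.0)

    def test_roundtrip_through_readers(self, tmp_path):
        cfg = TrackSimConfig(n_steps=120, sex="female")
        traj, events, _ = simulate_track(cfg, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # round-trip must be warning-free
            write_track(traj, tmp_path / "t.csv")
            back = read_track(tmp_path / "t.csv", sex="female")
            write_events(events, tmp_path / "e.csv")
            read_events(tmp_path / "e.csv")
        np.testing.assert_array_equal(back.t, traj.t)
        np.testing.assert_allclose(back.x, traj.x, atol=1e-6)

    def test_end_to_end_share_recovery_exact(self):
        """The pipeline recovers the event log's shares exactly."""
        for k in range(5):
            cfg = TrackSimConfig(n_steps=200, stop_rate=4.0)
            traj, events, truth = simulate_track(cfg, seed=40 + k)
            pt = consolidate(traj, events)
            s = summarize_track(pt)
            assert s.stopping == pytest.approx(truth["stopping_share"], abs=1e-12)
            assert s.nectaring == pytest.approx(truth["nectaring_share"], abs=1e-12)
            assert s.resting == pytest.approx(truth["resting_share"], abs=1e-12)

    def test_speed_recovery(self):
        cfg = TrackSimConfig(n_steps=400, stop_rate=2.0, gap_prob=0.0, jitter_sd=0.05)
        vals = []
        for k in range(20):
            traj, events, truth = simulate_track(cfg, seed=100 + k)
            s = summarize_track(consolidate(traj, events))
            vals.append(s.flight_speed - truth["speed"])
        assert abs(np.mean(vals)) < 0.01


class TestSimulateTransect:
    def test_constant_coverage(self):
        recs = simulate_transect(5, 9.2, seed=0)
        assert [r.np_cover for r in recs] == [9.2] * 5
        assert recs[0].segment_index == 1

    def test_single_segment(self):
        recs = simulate_transect(1, 33.0, seed=0)
        assert len(recs) == 1 and recs[0].np_cover == 33.0

    def test_lln_mean(self):
        dist = sps.beta(2.0, 8.0)  # mean 0.2 -> scaled below
        recs = simulate_transect(10_000, sps.uniform(10, 20), seed=1)
        mean = np.mean([r.np_cover for r in recs])
        assert mean == pytest.approx(20.0, abs=1.0)

    def test_roundtrip(self, tmp_path):
        recs = simulate_transect(30, sps.uniform(0, 40), seed=2)
        write_transect(recs, tmp_path / "tr.csv")
        back = read_transect(tmp_path / "tr.csv")
        assert [r.segment_index for r in back] == [r.segment_index for r in recs]
        np.testing.assert_allclose([r.np_cover for r in back],
                                   [r.np_cover for r in recs], rtol=1e-12)


class TestSimulateLandscape:
    def test_full_coverage_makes_imputation_identity(self):
        land, _ = simulate_landscape(coverage_fraction=1.0, seed=3)
        out = impute_sealing(land.sealing, land.biotopes)
        np.testing.assert_array_equal(out.data, land.sealing.data)

    def test_class_means_recovered(self):
        land, truth = simulate_landscape(n_classes=3, coverage_fraction=0.7,
                                         noise_sd=2.0, seed=4)
        means = class_sealing_means(land.sealing, land.biotopes)
        for cls, m in means.items():
            true_m = truth["class_means"][cls]
            n_cells = int(((land.biotopes.data == cls) & land.sealing.mask).sum())
            se = 2.0 / np.sqrt(n_cells)
            # clipping at [0,100] can shift extreme classes slightly
            assert m == pytest.approx(true_m, abs=max(2 * se, 0.5))

    def test_monocentric_nested_radii(self):
        land, _ = simulate_landscape(monocentric=True, coverage_fraction=1.0,
                                     grid=(200, 200), seed=5)
        center = land.site_centers["S01"]
        u_in = zonal_urbanization(land.sealing, center, 40.0)
        u_out = zonal_urbanization(land.sealing, center, 160.0)
        assert u_in >= u_out

    def test_deterministic(self):
        l1, t1 = simulate_landscape(seed=6)
        l2, t2 = simulate_landscape(seed=6)
        np.testing.assert_array_equal(l1.sealing.data, l2.sealing.data)
        assert t1["class_means"] == t2["class_means"]


class TestSimulateStudy:
    def test_schema_matches_pipeline(self):
        summ, cov, _ = simulate_study(StudySimConfig(n_sites=5, n_per_site=3), seed=7)
        assert {"individual_id", "species", "sex", "site", "duration_s",
                "flight_speed", "stopping", "nectaring", "resting",
                "sinuosity"} <= set(summ.columns)
        assert {"site_id", "np_cov", "urbanization_2000", "habitat_area"} <= set(cov.columns)
        assert len(summ) == 15

    def test_deterministic(self):
        s1, c1, _ = simulate_study(StudySimConfig(n_sites=5, n_per_site=3), seed=8)
        s2, c2, _ = simulate_study(StudySimConfig(n_sites=5, n_per_site=3), seed=8)
        assert s1.equals(s2) and c1.equals(c2)

    def test_site_variance_monotone_in_random_sd(self):
        """Doubling the site random SD inflates the estimated
        between-site variance."""
        from tests.test_glmm import fit_study

        def est(sd, seed):
            cfg = StudySimConfig(n_sites=40, n_per_site=8,
                                 random_sd={"habitat_area": 0.0, "duration_s": 0.0,
                                            "site": sd})
            summ, cov, _ = simulate_study(cfg, seed=seed)
            tab = summ.merge(cov.drop(columns=["habitat_area", "np_cov"]),
                             left_on="site", right_on="site_id")
            tab = tab.rename(columns={"urbanization_2000": "urbanization"})
            fit = fit_study(tab)
            return fit.vc["site"] + fit.vc["habitat_area"]

        assert est(0.6, 9) > est(0.15, 9)
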
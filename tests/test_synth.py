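"""Synthetic-track generators: exactness, round trips, populations."""

import numpy as np
import pytest

from mcswim import (PopulationSpec, fit_helix, make_double_helix_track,
                    make_helix_track, make_population,
                    make_reorientation_track)


class TestHelixTrack:
    def test_noiseless_points_satisfy_helix_equation(self):
        tr = make_helix_track(1.7, 5.3, 0.046, axis=(0, 0, 1), duration=0.3,
                              fps=1640, noise=0.0)
        t = tr.times
        r, w = 0.85, 2 * np.pi / 0.046
        expect = np.stack([r * np.cos(w * t), r * np.sin(w * t),
                           5.3 * t / 0.046], axis=1)
        expect -= expect[0]
        np.testing.assert_allclose(tr.positions, expect, atol=1e-12)

    def test_zero_diameter_gives_straight_line(self):
        tr = make_helix_track(0.0, 5.0, 0.05, axis=(1, 0, 0), duration=0.3,
                              fps=400)
        v = tr.velocities()
        np.testing.assert_allclose(v[:, 0], 100.0, rtol=1e-9)
        np.testing.assert_allclose(v[:, 1:], 0.0, atol=1e-9)

    def test_round_trip_with_fit(self):
        tr = make_helix_track(1.7, 5.3, 0.046, axis=(0.3, 0.1, 0.95),
                              duration=0.5, fps=1640)
        f = fit_helix(tr)
        truth = tr.meta["truth"]
        assert f.diameter == pytest.approx(truth["diameter"], rel=0.01)
        assert f.pitch == pytest.approx(truth["pitch"], rel=0.01)
        assert f.period == pytest.approx(truth["period"], rel=0.01)

    def test_undersampled_period_rejected(self):
        with pytest.raises(ValueError, match="under-sampled"):
            make_helix_track(1.7, 5.3, 0.01, duration=0.5, fps=400)


class TestDoubleHelixTrack:
    def test_zero_small_radius_reduces_to_single_helix(self):
        d = make_double_helix_track(0.85, 5.3, 0.046, 0.0, 0.01,
                                    duration=0.3, fps=1640)
        s = make_helix_track(1.7, 5.3, 0.046, duration=0.3, fps=1640)
        np.testing.assert_allclose(d.positions, s.positions, atol=1e-12)

    def test_velocity_matches_analytic_derivative(self):
        T_l, T_s = 0.072, 0.0144
        tr = make_double_helix_track(1.0, 4.0, T_l, 0.125, T_s,
                                     duration=0.3, fps=1640)
        t = tr.times
        wl, ws = 2 * np.pi / T_l, 2 * np.pi / T_s
        v_true = np.stack([
            -1.0 * wl * np.sin(wl * t) - 0.125 * ws * np.sin(ws * t),
            1.0 * wl * np.cos(wl * t) + 0.125 * ws * np.cos(ws * t),
            np.full_like(t, 4.0 / T_l),
        ], axis=1)
        v_num = tr.velocities()
        # central value: compare mid-frame analytic velocity, O(1/fps) accurate
        v_mid = 0.5 * (v_true[1:] + v_true[:-1])
        assert np.abs(v_num - v_mid).max() < 60.0 / 1640 * 50

    def test_speed_maxima_count_per_large_period(self):
        # |v|^2 = const + 2 r_l w_l r_s w_s cos((w_s - w_l) t): the speed
        # beats at 1/T_s - 1/T_l, i.e. T_l/T_s - 1 = 4 maxima per large
        # period for the ratio-5 reference track
        tr = make_double_helix_track(1.0, 4.0, 0.072, 0.125, 0.0144,
                                     duration=0.288, fps=1640)
        speed = np.linalg.norm(tr.velocities(), axis=1)
        peaks = np.flatnonzero((speed[1:-1] > speed[:-2])
                               & (speed[1:-1] > speed[2:])) + 1
        per_period = len(peaks) / (0.288 / 0.072)
        assert per_period == pytest.approx(4.0, abs=0.5)


class TestReorientationTrack:
    def test_single_event_detected_at_right_time(self):
        from mcswim import detect_reorientations
        h = {"diameter": 1.7, "pitch": 5.3, "period": 0.046, "axis": (0, 0, 1)}
        h2 = dict(h, axis=(1, 0, 0))
        tr = make_reorientation_track([(h, 0.25), (h2, 0.25)], [0.004],
                                      fps=1640, seed=5)
        evs = detect_reorientations(tr)
        assert len(evs) == 1
        truth = tr.meta["truth"]["events"][0]
        assert evs[0].time == pytest.approx(truth["time"], abs=0.002)
        assert evs[0].angle == pytest.approx(truth["angle"], abs=3.0)
        assert evs[0].duration <= 0.006

    def test_no_events_gives_plain_helix(self):
        h = {"diameter": 1.7, "pitch": 5.3, "period": 0.046, "axis": (0, 0, 1)}
        tr = make_reorientation_track([(h, 0.4)], [], fps=1640)
        ref = make_helix_track(1.7, 5.3, 0.046, duration=0.4, fps=1640)
        f1, f2 = fit_helix(tr), fit_helix(ref)
        assert f1.period == pytest.approx(f2.period, rel=0.01)
        assert f1.diameter == pytest.approx(f2.diameter, rel=0.01)

    def test_position_continuous_across_event(self):
        h = {"diameter": 1.7, "pitch": 5.3, "period": 0.046, "axis": (0, 0, 1)}
        h2 = dict(h, axis=(0, 1, 0))
        tr = make_reorientation_track([(h, 0.2), (h2, 0.2)], [0.003],
                                      fps=1640)
        step = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
        assert step.max() < 3.0 * np.median(step)

    def test_overlapping_events_rejected(self):
        h = {"diameter": 1.7, "pitch": 5.3, "period": 0.046, "axis": (0, 0, 1)}
        with pytest.raises(ValueError, match="overlap"):
            make_reorientation_track([(h, 0.05), (dict(h, axis=(1, 0, 0)), 0.2)],
                                     [0.08], fps=1640)


class TestPopulation:
    def test_same_seed_reproduces_population(self):
        spec = PopulationSpec(n_tracks=5, seed=42, event_rate=2.0)
        a = make_population(spec)
        b = make_population(spec)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)

    def test_ground_truth_attached(self):
        spec = PopulationSpec(n_tracks=4, seed=1)
        for tr in make_population(spec):
            assert "truth" in tr.meta

    def test_pitch_mean_recovered(self):
        # n = 65 tracks with the measured spreads; the fitted sample mean of
        # the pitch must sit within ~3 SE (0.4 µm) of the 5.3 µm centre
        spec = PopulationSpec(n_tracks=65, seed=7, noise=0.05, fps=1640,
                              duration_range=(0.4, 0.6))
        fitted = []
        truths = []
        for tr in make_population(spec):
            truths.append(tr.meta["truth"]["pitch"])
            try:
                fitted.append(fit_helix(tr).pitch)
            except Exception:
                pass
        assert len(fitted) > 55
        assert abs(np.mean(fitted) - 5.3) < 0.4
        assert abs(np.mean(fitted) - np.mean(truths)) < 0.25

    def test_zero_event_rate_population_has_no_events(self):
        from mcswim import detect_reorientations
        spec = PopulationSpec(n_tracks=4, seed=3, event_rate=0.0, noise=0.0,
                              duration_range=(0.4, 0.5))
        n_ev = 0
        for tr in make_population(spec):
            try:
                n_ev += len(detect_reorientations(tr))
            except Exception:
                pass
        assert n_ev == 0
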
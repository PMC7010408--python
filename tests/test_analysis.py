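"""Track analysis: smoothing, QC, helix fits, equivariance, projection."""

import numpy as np
import pytest

from mcswim import (HelixNotFoundError, Track, fit_double_helix, fit_helix,
                    qc_filter, smooth)
from mcswim.analysis import segment_axis
from mcswim.geometry import rotation_between
from mcswim.synth import make_double_helix_track, make_helix_track


# ------------------------------------------------------------------ smoothing

class TestSmooth:
    def test_window_one_is_identity(self):
        tr = make_helix_track(1.7, 5.3, 0.046, duration=0.2, fps=400,
                              noise=0.05, seed=1)
        np.testing.assert_array_equal(smooth(tr, 1).positions, tr.positions)

    def test_constant_track_unchanged(self):
        t = np.arange(50) / 100.0
        pos = np.tile([1.0, 2.0, 3.0], (50, 1))
        tr = Track(t, pos, 100.0)
        np.testing.assert_allclose(smooth(tr, 5).positions, pos, atol=1e-14)

    def test_sinusoid_attenuated_by_dirichlet_factor(self):
        # moving average of window w on period-N samples scales the amplitude
        # by sin(w pi/N) / (w sin(pi/N))
        N, w = 10, 5
        n = 400
        t = np.arange(n) / 1000.0
        x = np.sin(2 * np.pi * np.arange(n) / N)
        tr = Track(t, np.stack([x, 0 * x, 0 * x], 1), 1000.0)
        sm = smooth(tr, w).positions[:, 0]
        expected = np.sin(w * np.pi / N) / (w * np.sin(np.pi / N))
        # compare amplitudes away from the edges, at the sampled phases
        amp = np.abs(sm[50:-50]).max() / np.abs(x[50:-50]).max()
        assert amp == pytest.approx(expected, rel=1e-3)

    def test_length_preserved_and_edges_shrink(self):
        tr = make_helix_track(1.7, 5.3, 0.046, duration=0.2, fps=400)
        sm = smooth(tr, 5)
        assert len(sm) == len(tr)
        np.testing.assert_array_equal(sm.positions[0], tr.positions[0])

    @pytest.mark.parametrize("window", [0, 2, 4, 10001])
    def test_invalid_windows_rejected(self, window):
        tr = make_helix_track(1.7, 5.3, 0.046, duration=0.2, fps=400)
        with pytest.raises(ValueError):
            smooth(tr, window)


# ------------------------------------------------------------------ QC filter

def _straight_track(duration, speed, fps=400.0):
    n = int(duration * fps) + 1
    t = np.arange(n) / fps
    pos = np.outer(t * speed, np.array([1.0, 0, 0]))
    return Track(t, pos, fps)


class TestQCFilter:
    def test_good_track_passes(self):
        # 0.5 s, net displacement 5 µm -> squared displacement 25 µm²
        res = qc_filter(_straight_track(0.5, 10.0))
        assert res.passed and res.reasons == []
        assert res.metrics["msd"] == pytest.approx(25.0)

    def test_short_track_fails_duration(self):
        res = qc_filter(_straight_track(0.3, 20.0))
        assert "duration" in res.reasons and not res.passed

    def test_small_displacement_fails_msd(self):
        res = qc_filter(_straight_track(0.5, 5.0))  # 2.5 µm -> 6.25 µm²
        assert res.reasons == ["msd"]

    def test_random_walk_fails_angle(self):
        rng = np.random.default_rng(0)
        n = 200
        steps = rng.standard_normal((n, 3))
        pos = np.cumsum(steps, axis=0) + np.outer(np.arange(n), [0.03, 0, 0])
        pos = pos * 0.5 + np.outer(np.arange(n) * 0.02, [1.0, 0, 0])
        t = np.arange(n) / 400.0
        res = qc_filter(Track(t, pos, 400.0))
        assert "angle" in res.reasons

    def test_helix_passes_all_rules(self):
        tr = make_helix_track(1.7, 5.3, 0.046, duration=0.5, fps=400)
        assert qc_filter(tr).passed


# ------------------------------------------------------------------ single fit

class TestFitHelix:
    def test_noiseless_recovery_within_one_percent(self):
        tr = make_helix_track(1.7, 5.3, 0.046, axis=(0.2, -0.4, 0.89),
                              duration=0.5, fps=1640, noise=0.0, seed=0)
        truth = tr.meta["truth"]
        f = fit_helix(tr)
        assert f.diameter == pytest.approx(1.7, rel=0.01)
        assert f.pitch == pytest.approx(5.3, rel=0.01)
        assert f.period == pytest.approx(0.046, rel=0.01)
        assert f.v_z == pytest.approx(truth["v_z"], rel=0.01)
        # arc-length speed: sqrt((pi D)^2 + P^2)/T
        assert f.v_t == pytest.approx(truth["v_t"], rel=0.01)
        assert abs(np.dot(f.axis, truth["axis"])) > 0.9999

    def test_noisy_recovery_within_ten_percent(self):
        tr = make_helix_track(1.7, 5.3, 0.046, axis=(0.2, -0.4, 0.89),
                              duration=0.5, fps=1640, noise=0.05, seed=4)
        f = fit_helix(tr)
        assert f.diameter == pytest.approx(1.7, rel=0.10)
        assert f.pitch == pytest.approx(5.3, rel=0.10)
        assert f.period == pytest.approx(0.046, rel=0.10)
        assert f.v_t == pytest.approx(tr.meta["truth"]["v_t"], rel=0.10)

    def test_straight_line_raises(self):
        tr = make_helix_track(0.0, 5.0, 0.05, duration=0.5, fps=400)
        with pytest.raises(HelixNotFoundError):
            fit_helix(tr)

    def test_rigid_motion_equivariance(self):
        tr = make_helix_track(1.7, 5.3, 0.046, duration=0.5, fps=1640, seed=2)
        f0 = fit_helix(tr)
        R = rotation_between(np.array([0, 0, 1.0]),
                             np.array([0.48, -0.6, 0.64]))
        moved = tr.with_positions(tr.positions @ R.T + np.array([5.0, -3.0, 9.0]))
        f1 = fit_helix(moved)
        for attr in ("diameter", "pitch", "period", "v_z", "v_t"):
            assert getattr(f1, attr) == pytest.approx(getattr(f0, attr),
                                                      rel=1e-6)
        np.testing.assert_allclose(np.abs(np.dot(f1.axis, R @ f0.axis)), 1.0,
                                   atol=1e-6)


# ------------------------------------------------------------------ double fit

FIG2 = dict(r_l=1.0, p_l=4.0, T_l=0.072, r_s=0.125, T_s=0.0144)


class TestFitDoubleHelix:
    def test_recovery_within_two_percent_noiseless(self):
        tr = make_double_helix_track(**FIG2, duration=0.3, fps=1640, seed=0)
        f = fit_double_helix(tr)
        assert not f.fallback
        assert f.r_l == pytest.approx(FIG2["r_l"], rel=0.02)
        assert f.p_l == pytest.approx(FIG2["p_l"], rel=0.02)
        assert f.T_l == pytest.approx(FIG2["T_l"], rel=0.02)
        assert f.r_s == pytest.approx(FIG2["r_s"], rel=0.02)
        assert f.T_s == pytest.approx(FIG2["T_s"], rel=0.02)

    def test_recovery_within_ten_percent_at_30nm_noise(self):
        tr = make_double_helix_track(**FIG2, duration=0.3, fps=1640,
                                     noise=0.030, seed=11)
        f = fit_double_helix(tr)
        assert not f.fallback
        for key, attr in [("r_l", "r_l"), ("p_l", "p_l"), ("T_l", "T_l"),
                          ("r_s", "r_s"), ("T_s", "T_s")]:
            assert getattr(f, attr) == pytest.approx(FIG2[key], rel=0.10)

    def test_pure_single_helix_falls_back(self):
        tr = make_double_helix_track(1.0, 4.0, 0.072, 0.0, 0.0144,
                                     duration=0.3, fps=1640, seed=5)
        f = fit_double_helix(tr)
        assert f.fallback
        assert f.r_s == 0.0

    def test_downsampling_hides_small_helix_keeps_large(self):
        hi = make_double_helix_track(**FIG2, duration=0.3, fps=1640, seed=7)
        idx = np.arange(0, len(hi), 4)  # 410 fps
        lo = Track(hi.times[idx], hi.positions[idx], 1640 / 4,
                   source="synthetic")
        f_lo = fit_double_helix(lo)
        # small helix unresolved at 400 fps; large parameters survive
        f_hi = fit_double_helix(hi)
        assert f_lo.diameter == pytest.approx(2 * FIG2["r_l"], rel=0.05)
        assert f_lo.period == pytest.approx(FIG2["T_l"], rel=0.05)
        assert f_lo.pitch == pytest.approx(FIG2["p_l"], rel=0.05)
        assert not f_hi.fallback


# ------------------------------------------------------------------ projection

def test_2d_projection_distorts_apparent_parameters():
    """Identical 3D helices viewed along z give different apparent periods
    once the axis direction changes - while the 3D fits agree."""
    common = dict(diameter=1.7, pitch=5.3, period=0.046, duration=0.4,
                  fps=1640)
    pre = make_helix_track(axis=(1.0, 0.0, 0.0), seed=0, **common)
    post = make_helix_track(axis=(0.25, 0.25, 0.93), seed=0, **common)
    f3_pre, f3_post = fit_helix(pre), fit_helix(post)
    assert f3_pre.period == pytest.approx(f3_post.period, rel=0.02)

    def apparent_period(track):
        # a 2D pipeline reads the period off the projected-speed oscillation
        # (velocity maxima of the planar track)
        v2 = np.diff(track.positions[:, :2], axis=0) * track.fps
        speed = np.linalg.norm(v2, axis=1)
        spec = np.abs(np.fft.rfft(speed - speed.mean()))
        freqs = np.fft.rfftfreq(len(speed), d=1.0 / track.fps)
        spec[0] = 0.0
        return 1.0 / freqs[np.argmax(spec)]

    p_pre = apparent_period(pre)
    p_post = apparent_period(post)
    assert abs(p_pre - p_post) / max(p_pre, p_post) > 0.10


def test_segment_axis_orthogonal_segments():
    t = np.arange(100) / 400.0
    a = np.outer(t, [1.0, 0, 0])
    b = np.outer(t, [0, 1.0, 0])
    ax_a = segment_axis(a, t)
    ax_b = segment_axis(b, t)
    angle = np.degrees(np.arccos(np.clip(np.dot(ax_a, ax_b), -1, 1)))
    assert angle == pytest.approx(90.0, abs=1e-9)


def test_frenet_fit_recovers_partial_turn():
    """Differential-geometry estimator works below one helix turn,
    where spectral estimators cannot resolve a period."""
    from mcswim import fit_helix_frenet
    tr = make_helix_track(3.9, 19.1, 3.65, duration=0.95,
                          fps=5000 * 3.65 / 46, noise=0.0)
    f = fit_helix_frenet(tr)
    assert f.diameter == pytest.approx(3.9, rel=0.02)
    assert f.pitch == pytest.approx(19.1, rel=0.02)
    assert f.period == pytest.approx(3.65, rel=0.02)
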
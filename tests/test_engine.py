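"""Integrator and protocol machinery (short, desk-scale runs)."""

import numpy as np
import pytest

from mcswim import (ModelParams, Protocol, Trajectory, build_swimmer,
                    rk2_step, simulate)


class TestProtocol:
    def test_schedule_must_cover_duration(self):
        with pytest.raises(ValueError, match="cover"):
            Protocol(duration=0.1,
                     sense_schedule=[(0.0, 0.05, ("CCW", "CW"))])

    def test_schedule_must_be_contiguous(self):
        with pytest.raises(ValueError, match="contiguous"):
            Protocol(duration=0.1,
                     sense_schedule=[(0.0, 0.04, ("CCW", "CW")),
                                     (0.05, 0.1, ("CCW", "CCW"))])

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Protocol(duration=0.1,
                     sense_schedule=[(0.0, 0.0, ("CCW", "CW")),
                                     (0.0, 0.1, ("CCW", "CW"))])


class TestStepping:
    def test_rest_state_is_fixed_point_without_drive(self, rng):
        p = ModelParams(motor_torque=0.0)
        st = build_swimmer(p)
        out = rk2_step(st, p, n_steps=2000)
        assert np.linalg.norm(out.body_position - st.body_position) < 1e-12
        for f in range(2):
            assert np.abs(out.bead_positions[f]
                          - st.bead_positions[f]).max() < 1e-10

    def test_undriven_swimmer_does_not_translate(self):
        p = ModelParams(motor_torque=0.0)
        traj = simulate(p, Protocol(duration=0.004, transient=0.0,
                                    sample_interval=1e-3))
        disp = np.linalg.norm(traj.positions[-1] - traj.positions[0])
        assert disp < 0.01

    def test_bond_strain_stays_small_under_drive(self, default_params):
        st = build_swimmer(default_params)
        _, final = simulate(default_params,
                            Protocol(duration=0.008, transient=0.0,
                                     sample_interval=1e-3),
                            return_state=True)
        for f in range(2):
            bonds = np.linalg.norm(np.diff(final.bead_positions[f], axis=0),
                                   axis=1)
            assert np.abs(bonds / default_params.bond_length - 1).max() < 0.02

    def test_quaternion_stays_normalised(self, default_params):
        traj = simulate(default_params,
                        Protocol(duration=0.004, transient=0.0,
                                 sample_interval=1e-3))
        norms = np.linalg.norm(traj.quaternions, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)


class TestDeterminism:
    def test_identical_inputs_identical_trajectory(self, default_params):
        proto = Protocol(duration=0.003, transient=0.0, sample_interval=1e-4)
        a = simulate(default_params, proto)
        b = simulate(default_params, proto)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.quaternions, b.quaternions)


class TestMirrorSymmetry:
    def test_flipping_senses_and_handedness_reflects_trajectory(self):
        """Chirality: the mirror swimmer traces the mirrored path."""
        proto = Protocol(duration=0.004, transient=0.0, sample_interval=2e-4)
        p1 = ModelParams()  # (CCW, CW), left-handed
        p2 = ModelParams(rotation_sense=("CW", "CCW"),
                         helix_handedness="right")
        t1 = simulate(p1, proto)
        t2 = simulate(p2, proto)
        mirrored = t1.positions * np.array([1.0, -1.0, 1.0])
        np.testing.assert_allclose(t2.positions, mirrored, atol=1e-6)


class TestTrajectoryIO:
    def test_tsv_round_trip(self, default_params, tmp_path):
        traj = simulate(default_params,
                        Protocol(duration=0.003, transient=0.0,
                                 sample_interval=1e-3))
        path = tmp_path / "traj.tsv"
        traj.save_tsv(path)
        import pandas as pd
        df = pd.read_csv(path, sep="\t", comment="#")
        assert list(df.columns)[:4] == ["t", "x", "y", "z"]
        np.testing.assert_allclose(df["x"], traj.positions[:, 0], rtol=1e-8)

    def test_h5_round_trip(self, default_params, tmp_path):
        traj = simulate(default_params,
                        Protocol(duration=0.003, transient=0.0,
                                 sample_interval=1e-3))
        path = tmp_path / "traj.h5"
        traj.save_h5(path)
        import h5py
        with h5py.File(path) as h5:
            np.testing.assert_array_equal(h5["positions"][...],
                                          traj.positions)

    def test_transient_discarded(self, default_params):
        traj = simulate(default_params,
                        Protocol(duration=0.006, transient=0.004,
                                 sample_interval=1e-3))
        assert traj.times[0] >= 0.004 - 1e-12

    def test_to_track(self, default_params):
        traj = simulate(default_params,
                        Protocol(duration=0.003, transient=0.0,
                                 sample_interval=1e-4))
        tr = traj.to_track()
        assert tr.source == "simulated"
        assert tr.fps == pytest.approx(1e4, rel=1e-6)


class TestSweep:
    def test_invalid_axis_rejected(self):
        from mcswim import sweep
        with pytest.raises(ValueError, match="unknown sweep axis"):
            sweep(ModelParams(), "viscosity", [1e-3])

    def test_rows_and_error_recording(self):
        """One row per value; per-cell failures are recorded and the sweep
        continues (the invalid opening angle cannot even be built)."""
        from mcswim import sweep
        proto = Protocol(duration=0.06, transient=0.02)
        df = sweep(ModelParams(), "opening_angle", [60.0, 500.0],
                   protocol=proto)
        assert list(df["value"]) == [60.0, 500.0]
        ok = df.iloc[0]
        assert ok["error"] == "" and ok["D"] > 0 and ok["V_t"] > 0
        assert df.iloc[1]["error"] != ""
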
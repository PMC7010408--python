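"""Mobility: Rotne-Prager pair tensors, assembly properties, kinematics."""

import numpy as np
import pytest

from mcswim import (ModelParams, build_mobility, build_swimmer,
                    rpy_pair_mobility, solve_kinematics)

from conftest import perturbed_state

ETA = 1.0e-3


def _rpy_reference(r_vec, a1, a2, eta):
    """Independent transcription of the RPY tensor for non-overlapping
    unequal spheres (used as the closed-form oracle)."""
    r = np.linalg.norm(r_vec)
    e = np.outer(r_vec, r_vec) / r**2
    pref = 1.0 / (8 * np.pi * eta * r)
    s2 = (a1**2 + a2**2) / r**2
    return pref * ((1 + s2 / 3) * np.eye(3) + (1 - s2) * e)


def test_far_field_reduces_to_oseen():
    r = np.array([400.0, 30.0, -100.0])
    M = rpy_pair_mobility(r, np.zeros(3), 0.025, 0.025, ETA)
    rn = np.linalg.norm(r)
    oseen = (np.eye(3) + np.outer(r, r) / rn**2) / (8 * np.pi * ETA * rn)
    assert np.abs(M - oseen).max() / np.abs(oseen).max() < 1e-4


def test_symmetric_under_particle_exchange():
    ri = np.array([0.3, -0.2, 0.1])
    rj = np.array([-0.1, 0.4, 0.25])
    Mij = rpy_pair_mobility(ri, rj, 0.025, 0.65, ETA)
    Mji = rpy_pair_mobility(rj, ri, 0.65, 0.025, ETA)
    np.testing.assert_allclose(Mij, Mji.T, rtol=0, atol=1e-12)
    np.testing.assert_allclose(Mij, Mij.T, rtol=0, atol=1e-12)


def test_matches_closed_form_at_three_radii_separation():
    a = 0.025
    r = np.array([3 * a, 0.0, 0.0])
    M = rpy_pair_mobility(r, np.zeros(3), a, a, ETA)
    np.testing.assert_allclose(M, _rpy_reference(r, a, a, ETA), rtol=1e-12)


def test_overlap_branch_continuity():
    ai, aj = 0.65, 0.025
    for d in (ai + aj, abs(ai - aj)):
        lo = rpy_pair_mobility(np.array([d * (1 - 1e-9), 0, 0]), np.zeros(3),
                               ai, aj, ETA)
        hi = rpy_pair_mobility(np.array([d * (1 + 1e-9), 0, 0]), np.zeros(3),
                               ai, aj, ETA)
        assert np.abs(lo - hi).max() / np.abs(hi).max() < 1e-6


def test_coincident_centres_rejected():
    with pytest.raises(ValueError):
        rpy_pair_mobility(np.zeros(3), np.zeros(3), 0.1, 0.1, ETA)


def test_assembly_symmetric_positive_definite(default_params):
    for seed in range(25):
        state = perturbed_state(default_params, scale_pos=0.05, seed=seed)
        asm = build_mobility(state, default_params)
        assert asm.is_symmetric()
        assert asm.min_eigenvalue() > 0.0


def test_assembly_block_diagonal_without_coupling(default_params, rest_state):
    asm = build_mobility(rest_state, default_params, coupling=False)
    M = asm.matrix
    K = M.shape[0] // 3
    off = M.copy()
    for i in range(K):
        off[3 * i:3 * i + 3, 3 * i:3 * i + 3] = 0.0
    assert np.abs(off).max() == 0.0


def test_dissipation_non_negative(default_params, rng):
    state = perturbed_state(default_params, seed=1)
    asm = build_mobility(state, default_params)
    for _ in range(50):
        F = rng.standard_normal(asm.matrix.shape[0])
        assert F @ asm.apply(F) >= 0.0


def test_single_bead_local_drag(default_params, rest_state):
    """With coupling off, a tangential force moves a bead at F/(gamma_par l0)."""
    p = default_params
    forces = {"body": np.zeros(3),
              "beads": [np.zeros((20, 3)), np.zeros((20, 3))]}
    # unit force along the local tangent of an interior bead of filament 0
    pos = rest_state.bead_positions[0]
    tangent = pos[6] - pos[4]
    tangent /= np.linalg.norm(tangent)
    forces["beads"][0][5] = tangent
    torques = {"body": np.zeros(3), "bead_spin": []}
    out = solve_kinematics(forces, torques, rest_state, p, coupling=False)
    v = out["bead_velocities"][0][5]
    expect = 1.0 / (p.gamma_par * p.bond_length)
    assert np.dot(v, tangent) == pytest.approx(expect, rel=1e-9)
    assert np.linalg.norm(v - np.dot(v, tangent) * tangent) < 1e-9 * expect


def test_body_rotation_stokes_law(default_params, rest_state):
    tau = np.array([0.0, 0.0, 12.0])
    out = solve_kinematics({"body": np.zeros(3),
                            "beads": [np.zeros((20, 3)), np.zeros((20, 3))]},
                           {"body": tau, "bead_spin": []},
                           rest_state, default_params)
    expect = 12.0 / (8 * np.pi * ETA * 0.65**3)
    assert out["body_angular_velocity"][2] == pytest.approx(expect, rel=1e-12)


def test_two_bead_entrainment_exceeds_uncoupled(default_params, rest_state):
    """Equal forces along the separation: coupling speeds both beads up,
    by exactly the pair RPY coupling term."""
    p = default_params
    pos = rest_state.bead_positions[0]
    sep = pos[10] - pos[5]
    sep /= np.linalg.norm(sep)
    forces = {"body": np.zeros(3),
              "beads": [np.zeros((20, 3)), np.zeros((20, 3))]}
    forces["beads"][0][5] = sep
    forces["beads"][0][10] = sep
    torques = {"body": np.zeros(3), "bead_spin": []}
    v_c = solve_kinematics(forces, torques, rest_state, p, coupling=True)
    v_u = solve_kinematics(forces, torques, rest_state, p, coupling=False)
    s_c = np.dot(v_c["bead_velocities"][0][5], sep)
    s_u = np.dot(v_u["bead_velocities"][0][5], sep)
    assert s_c > s_u
    pair = rpy_pair_mobility(pos[5], pos[10], p.bead_radius, p.bead_radius,
                             p.viscosity)
    # entrainment = coupling tensor applied to the partner force, minus the
    # other couplings (body + remaining beads), which are much smaller here
    gain_direct = sep @ pair @ sep
    assert s_c - s_u == pytest.approx(gain_direct, rel=0.35)


def test_spin_rates_use_local_rotational_friction(default_params, rest_state):
    torques = {"body": np.zeros(3), "bead_spin": [np.ones(19), np.zeros(19)]}
    out = solve_kinematics({"body": np.zeros(3),
                            "beads": [np.zeros((20, 3)), np.zeros((20, 3))]},
                           torques, rest_state, default_params)
    np.testing.assert_allclose(out["bead_spin_rates"][0],
                               1.0 / default_params.gamma_rot)


def test_assembly_dump_round_trip(default_params, rest_state, tmp_path):
    asm = build_mobility(rest_state, default_params)
    path = tmp_path / "mobility.tsv"
    asm.dump(path)
    back = np.loadtxt(path)
    np.testing.assert_allclose(back, asm.matrix, rtol=1e-10)
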
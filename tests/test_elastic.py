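"""Elastic-rod energetics: exact gradients, spring laws, momentum conservation."""

import numpy as np
import pytest

from mcswim import ModelParams, build_swimmer
from mcswim.elastic import flagellum_energy, flagellum_forces, _scratch
from mcswim.swimmer import elastic_forces, total_internal

from conftest import perturbed_state


def _energy_of(state, params, f=0):
    geo = state.geometry[f]
    return flagellum_energy(
        state.bead_positions[f], state.theta[f], geo.anchor_axis_body,
        geo.anchor_dir_body, params.bond_length, params.k_stretch,
        params.kappa_bend, params.kappa_twist, geo.omega_bar, geo.m_bar,
        geo.clamp_cos0, params.hook_stiffness_eff,
    )


def test_forces_match_central_difference_gradient(default_params):
    """Elastic force field is the exact negative energy gradient."""
    state = perturbed_state(default_params, seed=7)
    geo = state.geometry[0]
    pos = state.bead_positions[0]
    th = state.theta[0]
    args = (geo.anchor_axis_body, geo.anchor_dir_body,
            default_params.bond_length, default_params.k_stretch,
            default_params.kappa_bend, default_params.kappa_twist,
            geo.omega_bar, geo.m_bar, geo.clamp_cos0,
            default_params.hook_stiffness_eff)
    n = pos.shape[0]
    F = np.zeros((n, 3))
    Tth = np.zeros(n - 1)
    abar = np.zeros(3)
    dbar = np.zeros(3)
    flagellum_forces(pos, th, *args[:2], *args[2:], F, Tth, abar, dbar,
                     *_scratch(n - 1))

    def E(p, t):
        return flagellum_energy(p, t, *args)

    h = 1e-6
    Fn = np.zeros_like(F)
    for i in range(n):
        for d in range(3):
            pp = pos.copy(); pp[i, d] += h
            pm = pos.copy(); pm[i, d] -= h
            Fn[i, d] = -(E(pp, th) - E(pm, th)) / (2 * h)
    assert np.abs(F - Fn).max() / np.abs(Fn).max() < 1e-6

    Tn = np.zeros_like(Tth)
    for j in range(n - 1):
        tp = th.copy(); tp[j] += h
        tm = th.copy(); tm[j] -= h
        Tn[j] = -(E(pos, tp) - E(pos, tm)) / (2 * h)
    assert np.abs(Tth - Tn).max() / np.abs(Tn).max() < 1e-6


def test_single_stretched_bond_linear_law():
    """A bond at 1.1 l0 pulls back with ks * 0.1 = 100 pN."""
    ell0, ks = 0.2, 1000.0
    pos = np.array([[0, 0, 0.85], [0, 0, 1.05], [0, 0, 1.25 + 0.1 * ell0]])
    th = np.zeros(2)
    a = np.array([0.0, 0.0, 1.0])
    d1 = np.array([1.0, 0.0, 0.0])
    n = 3
    F = np.zeros((n, 3)); Tth = np.zeros(2); ab = np.zeros(3); db = np.zeros(3)
    # straight intrinsic shape: zero curvature/twist, aligned clamp
    flagellum_forces(pos, th, a, d1, ell0, ks, 7.0, 7.0, 0.0, 0.0, 1.0, 35.0,
                     F, Tth, ab, db, *_scratch(2))
    assert F[2, 2] == pytest.approx(-100.0, rel=1e-12)
    assert F[1, 2] == pytest.approx(+100.0, rel=1e-12)


def test_internal_forces_and_torques_sum_to_zero(default_params):
    """Momentum conservation: |sum F| and |sum tau| below 1e-8."""
    for seed in range(3):
        state = perturbed_state(default_params, seed=seed)
        Ftot, Ttot = total_internal(state, default_params)
        assert np.linalg.norm(Ftot) < 1e-8
        assert np.linalg.norm(Ttot) < 1e-8


def test_rejects_invalid_states(default_params, rest_state):
    bad = rest_state.copy()
    bad.bead_positions[0][5] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        elastic_forces(bad, default_params)
    bad2 = rest_state.copy()
    bad2.bead_positions[1][3] = bad2.bead_positions[1][2]
    with pytest.raises(ValueError, match="coincident"):
        elastic_forces(bad2, default_params)


def test_straightened_filament_bending_energy_closed_form(default_params):
    """A straight chain with helical rest shape carries the closed-form
    frustration energy of the preferred-curvature and twist deviations."""
    state = build_swimmer(default_params)
    geo = state.geometry[0]
    n = geo.n_beads
    ell0 = default_params.bond_length
    a = geo.anchor_axis_body
    pos = state.bead_positions[0][0] + np.outer(np.arange(n) * ell0, a)
    th = np.linspace(0, geo.m_bar * (n - 2), n - 1)  # keep twist at intrinsic
    E = flagellum_energy(pos, th, a, geo.anchor_dir_body, ell0,
                         default_params.k_stretch, default_params.kappa_bend,
                         default_params.kappa_twist, geo.omega_bar, geo.m_bar,
                         geo.clamp_cos0, default_params.hook_stiffness_eff)
    kb = default_params.kappa_bend
    expected = ((n - 2) * 0.5 * kb / ell0 * geo.omega_bar**2       # vertices
                + 0.5 * default_params.hook_stiffness_eff
                * (1.0 - geo.clamp_cos0)**2)                        # hook
    assert E == pytest.approx(expected, rel=1e-12)
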
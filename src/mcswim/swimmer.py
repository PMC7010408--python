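"""Force and torque evaluation on the assembled swimmer (library surface).

These wrappers expose the individual force contributions — elastic,
motor, magnetic, excluded-volume — on a :class:`~mcswim.geometry.SwimmerState`
for inspection and testing.  The integration kernel evaluates the same
ingredients in fused form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .elastic import flagellum_forces, _scratch
from .geometry import SwimmerState, quat_to_matrix
from .params import ModelParams, sense_sign

__all__ = [
    "ElasticForces", "elastic_forces", "motor_torques", "magnetic_torque",
    "excluded_volume_forces", "moment_direction_body", "total_internal",
]


@dataclass
class ElasticForces:
    bead_forces: List[np.ndarray]     # per flagellum (n, 3), pN
    twist_torques: List[np.ndarray]   # per flagellum (n-1,), pN·µm about bonds
    body_force: np.ndarray            # (3,), pN (bead-0 transfer)
    body_torque: np.ndarray           # (3,), pN·µm about the body centre
    energy: float                     # pN·µm


def elastic_forces(state: SwimmerState, params: ModelParams) -> ElasticForces:
    """Stretching + bending + twisting forces; exact energy gradients.

    The total internal force, and the total internal torque about any point
    (bead forces plus the body reaction), vanish identically.
    """
    R = quat_to_matrix(state.body_orientation)
    X = state.body_position
    bead_forces = []
    twist_torques = []
    body_force = np.zeros(3)
    body_torque = np.zeros(3)
    energy = 0.0
    for f, geo in enumerate(state.geometry):
        pos = np.ascontiguousarray(state.bead_positions[f], dtype=float)
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"non-finite bead positions in flagellum {f}")
        bonds = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        if np.any(bonds < 1e-12):
            raise ValueError(f"coincident adjacent beads in flagellum {f}")
        th = np.ascontiguousarray(state.theta[f], dtype=float)
        a_lab = R @ geo.anchor_axis_body
        d_lab = R @ geo.anchor_dir_body
        n = len(pos)
        F = np.zeros((n, 3))
        Tth = np.zeros(n - 1)
        abar = np.zeros(3)
        dbar = np.zeros(3)
        energy += flagellum_forces(
            pos, th, a_lab, d_lab, params.bond_length, params.k_stretch,
            params.kappa_bend, params.kappa_twist, geo.omega_bar, geo.m_bar,
            geo.clamp_cos0, params.hook_stiffness_eff, F, Tth, abar, dbar,
            *_scratch(n - 1),
        )
        bead_forces.append(F)
        twist_torques.append(Tth)
        # bead 0 rides on the body: transfer force + lever torque + frame reaction
        body_force += F[0]
        body_torque += np.cross(pos[0] - X, F[0])
        body_torque -= np.cross(a_lab, abar) + np.cross(d_lab, dbar)
    return ElasticForces(bead_forces, twist_torques, body_force, body_torque,
                         energy)


def motor_torques(state: SwimmerState, params: ModelParams,
                  schedule: Sequence[str] | None = None):
    """Motor torque vectors at the flagellar bases and the body counter-torque.

    Each motor applies ``±Tm`` about the current base tangent (sign from the
    rotation sense, CCW positive viewed from the tip toward the body); the
    body receives the exact opposite torque, so the pair sums to zero.
    """
    if schedule is None:
        schedule = params.rotation_sense
    if len(schedule) != 2:
        raise ValueError("schedule must contain exactly two senses")
    mags = params.motor_torques_pair
    base_torques = []
    counter = np.zeros(3)
    for f, geo in enumerate(state.geometry):
        sgn = sense_sign(schedule[f])
        pos = state.bead_positions[f]
        t0 = pos[1] - pos[0]
        t0 = t0 / np.linalg.norm(t0)
        tau = sgn * mags[f] * t0
        base_torques.append(tau)
        counter -= tau
    return base_torques, counter


def moment_direction_body(params: ModelParams) -> np.ndarray:
    """Unit magnetic-moment direction in the body frame.

    The bisector of the two anchor axes is the body z axis; the default rule
    places the moment perpendicular to it, rotated by ``moment_azimuth`` from
    the flagellar (x-z) plane.
    """
    az = np.deg2rad(params.moment_azimuth)
    if params.moment_rule == "perpendicular_to_bisector":
        return np.array([np.cos(az), np.sin(az), 0.0])
    return np.array([0.0, 0.0, 1.0])


def magnetic_torque(body_orientation: np.ndarray, params: ModelParams,
                    B: Sequence[float] | None = None) -> np.ndarray:
    """Torque m × B on the body, pN·µm (B in mT, m in A·m²)."""
    if B is None:
        B = params.B_field
    R = quat_to_matrix(np.asarray(body_orientation, dtype=float))
    m_lab = R @ (params.moment_eff * moment_direction_body(params))
    return np.cross(m_lab, np.asarray(B, dtype=float))


def excluded_volume_forces(state: SwimmerState, params: ModelParams):
    """WCA (truncated, shifted Lennard-Jones) repulsion between particles.

    Pairs: free beads of both filaments excluding neighbours along a chain,
    and free beads against the body.  Forces are pairwise equal-and-opposite
    and vanish beyond the 2^{1/6}σ cutoff.
    """
    eps = params.wca_epsilon
    sig_bb = params.bead_diameter
    sig_body = params.body_radius + params.bead_radius
    bead_forces = [np.zeros_like(p) for p in state.bead_positions]
    body_force = np.zeros(3)

    parts = []  # (flagellum, index, position)
    for f, pos in enumerate(state.bead_positions):
        for i in range(1, len(pos)):
            parts.append((f, i, pos[i]))
    for a in range(len(parts)):
        fa, ia, pa = parts[a]
        # body pair
        fvec = _wca_force(pa - state.body_position, sig_body, eps)
        bead_forces[fa][ia] += fvec
        body_force -= fvec  # central force through the body centre: no torque
        for b in range(a + 1, len(parts)):
            fb, ib, pb = parts[b]
            if fa == fb and abs(ia - ib) <= 1:
                continue
            fvec = _wca_force(pa - pb, sig_bb, eps)
            bead_forces[fa][ia] += fvec
            bead_forces[fb][ib] -= fvec
    return bead_forces, body_force


def _wca_force(d: np.ndarray, sigma: float, eps: float) -> np.ndarray:
    r2 = float(np.dot(d, d))
    rc2 = (2 ** (1 / 6) * sigma) ** 2
    if r2 >= rc2:
        return np.zeros(3)
    if r2 < 1e-20:
        raise ValueError("exact particle overlap in excluded-volume evaluation")
    s2 = sigma * sigma / r2
    s6 = s2**3
    return 24.0 * eps * (2.0 * s6 * s6 - s6) / r2 * d


def wca_energy(r: float, sigma: float, eps: float) -> float:
    """Pair potential: 4ε[(σ/r)^12 − (σ/r)^6] + ε below 2^{1/6}σ, else 0."""
    rc = 2 ** (1 / 6) * sigma
    if r >= rc:
        return 0.0
    s6 = (sigma / r) ** 6
    return 4.0 * eps * (s6 * s6 - s6) + eps


def total_internal(state: SwimmerState, params: ModelParams):
    """Sum of internal forces and torques (elastic + excluded volume).

    Both must vanish for a momentum-conserving force field.
    """
    el = elastic_forces(state, params)
    ev_beads, ev_body = excluded_volume_forces(state, params)
    Ftot = el.body_force.copy() + ev_body
    Ttot = el.body_torque.copy()
    X = state.body_position
    for f in range(2):
        Ffree = el.bead_forces[f][1:] + ev_beads[f][1:]
        Ftot += Ffree.sum(axis=0)
        Ttot += np.cross(state.bead_positions[f][1:] - X, Ffree).sum(axis=0)
    # excluded-volume body force acts at the body centre: no extra torque
    return Ftot, Ttot
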
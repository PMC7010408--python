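"""Grand mobility of the swimmer: local anisotropic drag plus Rotne-Prager.

Self-mobilities come from the printed local frictions (anisotropic slender-
body drag per bead, Stokes drag for the body); the Rotne-Prager(-Yamakawa)
tensor supplies only the translation-translation cross-coupling blocks,
including the overlap-regularised branch for unequal radii.  Rotational
cross-coupling is omitted; bead spin and body rotation use the local
rotational frictions directly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import ModelParams

__all__ = [
    "rpy_pair_mobility",
    "MobilityAssembly",
    "build_mobility",
    "solve_kinematics",
]


@njit(cache=True, fastmath=True)
def _rpy_pair(dx, dy, dz, ai, aj, eta, out):
    """Rotne-Prager-Yamakawa translational coupling for unequal radii."""
    r2 = dx * dx + dy * dy + dz * dz
    r = np.sqrt(r2)
    pi = np.pi
    if r < 1e-14:
        raise ValueError("coincident particle centres in RPY pair mobility")
    ex = dx / r
    ey = dy / r
    ez = dz / r
    e = (ex, ey, ez)
    if r >= ai + aj:
        pref = 1.0 / (8.0 * pi * eta * r)
        s2 = (ai * ai + aj * aj) / r2
        ci = pref * (1.0 + s2 / 3.0)
        ce = pref * (1.0 - s2)
    elif r > abs(ai - aj):
        d2 = (ai - aj) * (ai - aj)
        pref = 1.0 / (6.0 * pi * eta * ai * aj)
        ci = pref * (16.0 * r2 * r * (ai + aj) - (d2 + 3.0 * r2) ** 2) / (32.0 * r2 * r)
        ce = pref * (3.0 * (d2 - r2) ** 2) / (32.0 * r2 * r)
    else:
        big = ai if ai > aj else aj
        ci = 1.0 / (6.0 * pi * eta * big)
        ce = 0.0
    for a in range(3):
        for b in range(3):
            out[a, b] = ce * e[a] * e[b]
        out[a, a] += ci


def rpy_pair_mobility(r_i, r_j, a_i, a_j, viscosity) -> np.ndarray:
    """3x3 translational coupling tensor between spheres i and j.

    Symmetric under particle exchange; reduces to the Oseen tensor at large
    separation and stays positive definite through the overlap branch.
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    d = r_i - r_j
    out = np.empty((3, 3))
    _rpy_pair(d[0], d[1], d[2], float(a_i), float(a_j), float(viscosity), out)
    return out


@njit(cache=True, fastmath=True)
def build_mobility_matrix(centers, radii, tangents, is_bead, gpar_l, gperp_l,
                          gbt, eta, coupling):
    """Dense translational grand mobility for body + free beads.

    ``centers``: (K,3); index 0 is the body.  ``tangents`` holds the local
    filament tangent per particle (ignored for the body).  Self blocks are the
    local drags; off-diagonal blocks are RPY.
    """
    K = centers.shape[0]
    M = np.zeros((3 * K, 3 * K))
    blk = np.empty((3, 3))
    for i in range(K):
        if is_bead[i] == 0:
            mi = 1.0 / gbt
            for d in range(3):
                M[3 * i + d, 3 * i + d] = mi
        else:
            tpar = 1.0 / gpar_l
            tperp = 1.0 / gperp_l
            tx = tangents[i, 0]
            ty = tangents[i, 1]
            tz = tangents[i, 2]
            tv = (tx, ty, tz)
            for a in range(3):
                for b in range(3):
                    M[3 * i + a, 3 * i + b] = (tpar - tperp) * tv[a] * tv[b]
                M[3 * i + a, 3 * i + a] += tperp
    if coupling:
        for i in range(K):
            for j in range(i + 1, K):
                _rpy_pair(
                    centers[i, 0] - centers[j, 0],
                    centers[i, 1] - centers[j, 1],
                    centers[i, 2] - centers[j, 2],
                    radii[i], radii[j], eta, blk,
                )
                for a in range(3):
                    for b in range(3):
                        M[3 * i + a, 3 * j + b] = blk[a, b]
                        M[3 * j + b, 3 * i + a] = blk[a, b]
    return M


class MobilityAssembly:
    """Block mobility over body translation/rotation and bead translations/spins.

    Translational velocities come from a dense symmetric matrix; rotations are
    purely local (``gamma_rot`` per bead spin, ``8πηRb³`` for the body).
    """

    def __init__(self, M: np.ndarray, params: ModelParams):
        self.M = M
        self.params = params

    @property
    def matrix(self) -> np.ndarray:
        return self.M

    def is_symmetric(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.M, self.M.T, atol=tol, rtol=0.0))

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.M).min())

    def apply(self, forces_flat: np.ndarray) -> np.ndarray:
        return self.M @ forces_flat

    def dump(self, path) -> None:
        np.savetxt(path, self.M, fmt="%.12e", delimiter="\t")


def _particle_arrays(state, params: ModelParams):
    """Stack body + free beads (bead 0 of each filament is rigid with the body)."""
    centers = [state.body_position]
    radii = [params.body_radius]
    tangents = [np.zeros(3)]
    is_bead = [0]
    for pos in state.bead_positions:
        e = np.diff(pos, axis=0)
        t = e / np.linalg.norm(e, axis=1)[:, None]
        for i in range(1, len(pos)):
            centers.append(pos[i])
            radii.append(params.bead_radius)
            # bead tangent: mean of adjacent bond tangents (single bond at the tip)
            if i < len(pos) - 1:
                tb = t[i - 1] + t[i]
                tb = tb / np.linalg.norm(tb)
            else:
                tb = t[i - 1]
            tangents.append(tb)
            is_bead.append(1)
    return (np.array(centers), np.array(radii), np.array(tangents),
            np.array(is_bead, dtype=np.int64))


def build_mobility(state, params: ModelParams, coupling: bool = True) -> MobilityAssembly:
    centers, radii, tangents, is_bead = _particle_arrays(state, params)
    M = build_mobility_matrix(
        centers, radii, tangents, is_bead,
        params.gamma_par * params.bond_length,
        params.gamma_perp * params.bond_length,
        params.gamma_body_trans, params.viscosity, coupling,
    )
    return MobilityAssembly(M, params)


def solve_kinematics(forces, torques, state, params: ModelParams,
                     coupling: bool = True):
    """Velocities and angular velocities from forces and torques.

    ``forces``: dict with keys ``body`` (3,) and ``beads`` (list of (n,3) per
    flagellum; row 0, the body-rigid bead, is ignored here — fold it into the
    body force/torque first).  ``torques``: dict with ``body`` (3,) and
    ``bead_spin`` (list of (n-1,) axial torques).

    Returns a dict with ``body_velocity``, ``body_angular_velocity``,
    ``bead_velocities`` (same layout as input) and ``bead_spin_rates``.
    """
    asm = build_mobility(state, params, coupling=coupling)
    if not np.all(np.isfinite(forces["body"])):
        raise ValueError("non-finite body force")
    flat = [np.asarray(forces["body"], dtype=float)]
    for fb in forces["beads"]:
        if not np.all(np.isfinite(fb)):
            raise ValueError("non-finite bead forces")
        flat.append(np.asarray(fb[1:], dtype=float).ravel())
    F = np.concatenate([f.ravel() for f in flat])
    V = asm.apply(F)
    out_beads = []
    off = 3
    for fb in forces["beads"]:
        n = fb.shape[0]
        vb = np.zeros((n, 3))
        vb[1:] = V[off:off + 3 * (n - 1)].reshape(n - 1, 3)
        out_beads.append(vb)
        off += 3 * (n - 1)
    spin = [np.asarray(t, dtype=float) / params.gamma_rot
            for t in torques.get("bead_spin", [])]
    return {
        "body_velocity": V[:3],
        "body_angular_velocity": np.asarray(torques["body"], dtype=float)
        / params.gamma_body_rot,
        "bead_velocities": out_beads,
        "bead_spin_rates": spin,
        "assembly": asm,
    }
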
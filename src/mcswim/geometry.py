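"""Swimmer geometry: discrete helical filaments anchored on a spherical body.

The cell body is a rigid sphere.  Two filaments are anchored on one
hemisphere, their anchor axes separated by the opening angle and symmetric
about the body axis (+z in the body frame, the bisector).  Each filament is a
chain of beads whose rest shape is a helix; the first bead is rigid with the
body, one body radius plus one bond length from the centre along the anchor
axis, and the first bond is elastically clamped to the anchor axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .params import ModelParams, sense_sign


# ---------------------------------------------------------------- quaternions

def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix (body -> lab) from a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


def quat_from_rotvec(phi: np.ndarray) -> np.ndarray:
    angle = float(np.linalg.norm(phi))
    if angle < 1e-300:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = phi / angle
    half = 0.5 * angle
    s = np.sin(half)
    return np.array([np.cos(half), s * axis[0], s * axis[1], s * axis[2]])


def rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector u to unit vector v."""
    c = float(np.dot(u, v))
    if c < -1.0 + 1e-12:
        raise ValueError("rotation_between undefined for antiparallel vectors")
    r = np.cross(u, v)
    k = 1.0 / (1.0 + c)
    K = np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]])
    return np.eye(3) + K + k * (K @ K)


def parallel_transport(u: np.ndarray, v: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Transport x by the minimal rotation taking unit vector u to v."""
    c = float(np.dot(u, v))
    r = np.cross(u, v)
    k = 1.0 / (1.0 + c)
    return c * x + np.cross(r, x) + k * float(np.dot(r, x)) * r


# ---------------------------------------------------------------- rest helix

def helix_chord_step(radius: float, pitch: float, bond: float) -> float:
    """Phase increment per bond so that chord length equals the bond length."""
    b = pitch / (2.0 * np.pi)
    # solve (b dphi)^2 + 2 R^2 (1 - cos dphi) = bond^2 by Newton iteration
    arc = np.sqrt(radius * radius + b * b)
    dphi = bond / arc  # arc-length guess
    for _ in range(60):
        f = (b * dphi) ** 2 + 2 * radius**2 * (1 - np.cos(dphi)) - bond**2
        df = 2 * b * b * dphi + 2 * radius**2 * np.sin(dphi)
        step = f / df
        dphi -= step
        if abs(step) < 1e-15:
            break
    if not (dphi > 0):
        raise ValueError("degenerate helix geometry")
    return float(dphi)


def helix_template(n: int, radius: float, pitch: float, handedness: str,
                   bond: float) -> np.ndarray:
    """n bead positions on a helix with exact chord spacing ``bond``.

    Right-handed: (R cos φ, R sin φ, b φ); left-handed mirrors y.
    """
    dphi = helix_chord_step(radius, pitch, bond)
    b = pitch / (2.0 * np.pi)
    sign = 1.0 if handedness == "right" else -1.0
    phi = dphi * np.arange(n)
    pts = np.stack(
        [radius * np.cos(phi), sign * radius * np.sin(phi), b * phi], axis=1
    )
    return pts


@dataclass
class FlagellumGeometry:
    """Per-flagellum rest-shape data fixed at build time."""

    n_beads: int
    anchor_axis_body: np.ndarray      # unit vector, body frame
    anchor_dir_body: np.ndarray       # material director at the base, body frame
    omega_bar: float                  # intrinsic discrete curvature |kb| per vertex
    m_bar: float                      # intrinsic discrete twist per vertex, rad
    clamp_cos0: float                 # hook equilibrium cos(angle) of t0 vs anchor
    tilt: float                       # hook equilibrium offset, rad
    motor_torque: float               # pN·µm
    sense: float                      # +1 CCW, -1 CW
    rest_positions_body: np.ndarray   # (n, 3), body frame
    rest_theta: np.ndarray            # (n-1,), rad


@dataclass
class SwimmerState:
    """Full mechanical state of body plus two bead-chain flagella."""

    body_position: np.ndarray         # (3,), µm
    body_orientation: np.ndarray      # unit quaternion (w, x, y, z)
    bead_positions: List[np.ndarray]  # per flagellum (n, 3), lab frame, µm
    theta: List[np.ndarray]           # per flagellum (n-1,), twist angles, rad
    time: float = 0.0
    geometry: List[FlagellumGeometry] = field(default_factory=list)

    @property
    def motor_phase(self) -> np.ndarray:
        """Accumulated material spin of the base bond per flagellum, rad."""
        return np.array([th[0] for th in self.theta])

    def bead_frames(self) -> List[np.ndarray]:
        """Orthonormal material triads (d1, d2, t) per bond, lab frame."""
        R = quat_to_matrix(self.body_orientation)
        out = []
        for f, geo in enumerate(self.geometry):
            pos = self.bead_positions[f]
            th = self.theta[f]
            a_lab = R @ geo.anchor_axis_body
            d1 = R @ geo.anchor_dir_body
            e = np.diff(pos, axis=0)
            ln = np.linalg.norm(e, axis=1)
            t = e / ln[:, None]
            frames = np.zeros((len(th), 3, 3))
            u = parallel_transport(a_lab, t[0], d1)
            prev = t[0]
            for j in range(len(th)):
                if j > 0:
                    u = parallel_transport(prev, t[j], u)
                    prev = t[j]
                w = np.cross(t[j], u)
                m1 = np.cos(th[j]) * u + np.sin(th[j]) * w
                m2 = np.cross(t[j], m1)
                frames[j, 0] = m1
                frames[j, 1] = m2
                frames[j, 2] = t[j]
            out.append(frames)
        return out

    def copy(self) -> "SwimmerState":
        return SwimmerState(
            body_position=self.body_position.copy(),
            body_orientation=self.body_orientation.copy(),
            bead_positions=[p.copy() for p in self.bead_positions],
            theta=[t.copy() for t in self.theta],
            time=self.time,
            geometry=self.geometry,
        )


def build_flagellum_geometry(params: ModelParams, index: int) -> FlagellumGeometry:
    """Rest geometry of one filament: helix coaxial with its anchor axis.

    The filament lies on a cylinder whose axis is parallel to the anchor
    axis and offset by the helix radius, so that motor rotation cranks the
    filament compactly about the anchor like a balanced corkscrew.  The hook
    clamp prefers the helix's natural tangent-to-axis angle (a cone clamp,
    free to spin), optionally offset by the per-flagellum tilt.
    """
    half = np.deg2rad(params.opening_angle) / 2.0
    side = 1.0 if index == 0 else -1.0
    anchor_axis = np.array([side * np.sin(half), 0.0, np.cos(half)])
    n = params.n_beads_per_flagellum[index]
    ell0 = params.bond_length

    template = helix_template(
        n, params.helix_radius, params.helix_pitch, params.helix_handedness, ell0
    )
    template = template - template[0]     # helix axis along +z, start at origin
    Rz = rotation_between(np.array([0.0, 0.0, 1.0]), anchor_axis)
    # phase the helix offset outward, in the flagellar plane, for clearance
    # (mirror-symmetric under reflection of that plane)
    phase = 0.0 if side > 0 else np.pi
    Rphase = quat_to_matrix(quat_from_rotvec(phase * np.array([0.0, 0.0, 1.0])))
    rest = (template @ Rphase.T) @ Rz.T
    anchor_pos = (params.body_radius + ell0) * anchor_axis
    rest = anchor_pos + rest

    # base material director: unit vector perpendicular to the anchor axis
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(np.dot(ref, anchor_axis))) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    d1 = ref - float(np.dot(ref, anchor_axis)) * anchor_axis
    d1 /= np.linalg.norm(d1)

    omega_bar, m_bar, theta = _intrinsic_from_rest(rest, anchor_axis, d1)
    t0 = rest[1] - rest[0]
    t0 /= np.linalg.norm(t0)
    chi0 = float(np.arccos(np.clip(np.dot(t0, anchor_axis), -1.0, 1.0)))
    tilt = np.deg2rad(params.tilt_offsets[index])
    return FlagellumGeometry(
        n_beads=n,
        anchor_axis_body=anchor_axis,
        anchor_dir_body=d1,
        omega_bar=omega_bar,
        m_bar=m_bar,
        clamp_cos0=float(np.cos(chi0 + tilt)),
        tilt=tilt,
        motor_torque=params.motor_torques_pair[index],
        sense=sense_sign(params.rotation_sense[index]),
        rest_positions_body=rest,
        rest_theta=theta,
    )


def _intrinsic_from_rest(rest: np.ndarray, anchor_axis: np.ndarray,
                         d1: np.ndarray) -> Tuple[float, float, np.ndarray]:
    """Intrinsic curvature/twist making the laid-out chain an exact minimum.

    With space-parallel-transported reference directors, the material twist is
    carried entirely by the per-bond angles.  The helix is discretely uniform,
    so a single curvature magnitude and twist increment describe it; the bond
    angles are chosen so the material normal at each interior vertex points
    along the measured curvature binormal.
    """
    e = np.diff(rest, axis=0)
    ln = np.linalg.norm(e, axis=1)
    t = e / ln[:, None]
    nb = len(t)
    # transported reference directors
    u = np.zeros((nb, 3))
    u[0] = parallel_transport(anchor_axis, t[0], d1)
    for j in range(1, nb):
        u[j] = parallel_transport(t[j - 1], t[j], u[j - 1])

    theta = np.zeros(nb)
    kb_mags = []
    for i in range(1, nb):
        kb = 2.0 * np.cross(t[i - 1], t[i]) / (1.0 + float(np.dot(t[i - 1], t[i])))
        mag = np.linalg.norm(kb)
        kb_mags.append(mag)
        if mag < 1e-14:
            theta[i - 1] = theta[i - 2] if i >= 2 else 0.0
            continue
        kh = kb / mag
        w = np.cross(t[i - 1], u[i - 1])
        # require m2_{i-1} parallel to kb: m2 = cos θ w - sin θ u
        theta[i - 1] = float(np.arctan2(-np.dot(kh, u[i - 1]), np.dot(kh, w)))
    # unwrap to a monotone twist profile
    theta[: nb - 1] = np.unwrap(theta[: nb - 1])
    if nb >= 3:
        increments = np.diff(theta[: nb - 1])
        m_bar = float(np.median(increments)) if len(increments) else 0.0
    else:
        m_bar = 0.0
    theta[nb - 1] = theta[nb - 2] + m_bar
    omega_bar = float(np.median(kb_mags)) if kb_mags else 0.0
    return omega_bar, m_bar, theta


def build_swimmer(params: ModelParams) -> SwimmerState:
    """Construct the swimmer in its elastic rest configuration at the origin.

    Raises ``ValueError`` for geometries where filaments would interpenetrate
    the body or each other at rest.
    """
    geos = [build_flagellum_geometry(params, i) for i in range(2)]
    state = SwimmerState(
        body_position=np.zeros(3),
        body_orientation=np.array([1.0, 0.0, 0.0, 0.0]),
        bead_positions=[g.rest_positions_body.copy() for g in geos],
        theta=[g.rest_theta.copy() for g in geos],
        time=0.0,
        geometry=geos,
    )
    _check_overlap(state, params)
    return state


def _check_overlap(state: SwimmerState, params: ModelParams) -> None:
    body_contact = params.body_radius + params.bead_radius
    bead_contact = params.bead_diameter
    for f, pos in enumerate(state.bead_positions):
        d_body = np.linalg.norm(pos[1:] - state.body_position, axis=1)
        if np.any(d_body < body_contact):
            raise ValueError(
                f"flagellum {f} interpenetrates the body at rest "
                f"(min distance {d_body.min():.3f} µm < {body_contact:.3f} µm)"
            )
    p0, p1 = state.bead_positions
    d = np.linalg.norm(p0[:, None, :] - p1[None, :, :], axis=2)
    if d.min() < bead_contact:
        raise ValueError(
            f"flagella interpenetrate each other at rest "
            f"(min distance {d.min():.4f} µm < {bead_contact:.4f} µm)"
        )
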
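"""Time integration and the standard simulation protocols.

``simulate`` runs the midpoint integrator over a :class:`Protocol`
(piecewise-constant rotation-sense and field schedules) and samples the body
pose plus flagellar diagnostics.  On top of it sit the protocol drivers:
``reorientation_experiment`` (transient synchronous rotation),
``field_experiment`` (strong homogeneous field) and ``sweep`` (parameter
scans with helix analysis per cell).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import kernels
from .analysis import HelixNotFoundError, fit_helix, segment_axis
from .geometry import SwimmerState, build_swimmer, quat_to_matrix
from .params import ModelParams, sense_sign
from .swimmer import moment_direction_body
from .tracks import Track

log = logging.getLogger("mcswim")

__all__ = ["Protocol", "Trajectory", "simulate", "rk2_step",
           "reorientation_experiment", "field_experiment", "sweep"]


@dataclass
class Protocol:
    """A complete run description.

    Schedules are lists of ``(t_start, t_end, value)`` segments that must be
    contiguous and cover [0, duration]; ``None`` means constant (senses from
    the parameter set, field from ``params.B_field``).
    """

    duration: float
    sense_schedule: Optional[List[Tuple[float, float, Tuple[str, str]]]] = None
    b_schedule: Optional[List[Tuple[float, float, Tuple[float, float, float]]]] = None
    sample_interval: float = 1.0e-4
    transient: float = 0.020
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.sample_interval <= 0:
            raise ValueError("duration and sample_interval must be positive")
        for sched in (self.sense_schedule, self.b_schedule):
            if sched is None:
                continue
            if abs(sched[0][0]) > 1e-12 or abs(sched[-1][1] - self.duration) > 1e-9:
                raise ValueError("schedule must cover [0, duration]")
            for (a0, a1, _), (b0, b1, _) in zip(sched, sched[1:]):
                if abs(a1 - b0) > 1e-12:
                    raise ValueError("schedule segments must be contiguous")
            for a0, a1, _ in sched:
                if a1 <= a0:
                    raise ValueError("empty schedule segment")


@dataclass
class Trajectory:
    """Sampled output of one run."""

    times: np.ndarray          # (n,), s
    positions: np.ndarray      # (n, 3), body centre, µm
    quaternions: np.ndarray    # (n, 4)
    flagella: np.ndarray       # (n, 2, 3) first free bead of each filament
    crank: np.ndarray          # (n, 2) bundle azimuth about its anchor, rad
    twist0: np.ndarray         # (n, 2) material spin angle of the base bond
    params: ModelParams = None
    protocol: Protocol = None

    def __len__(self):
        return len(self.times)

    def to_track(self) -> Track:
        fps = 1.0 / float(np.median(np.diff(self.times)))
        return Track(self.times.copy(), self.positions.copy(), fps,
                     source="simulated", meta={})

    def bundle_rotation_hz(self) -> np.ndarray:
        """Mean material spin rate of each bundle (motor rotation), Hz."""
        dt = self.times[-1] - self.times[0]
        return np.abs(self.twist0[-1] - self.twist0[0]) / (2 * np.pi * dt)

    def bundle_precession_hz(self) -> np.ndarray:
        """Mean revolution rate of the bundle position about its anchor, Hz."""
        un = np.unwrap(self.crank, axis=0)
        dt = self.times[-1] - self.times[0]
        return np.abs(un[-1] - un[0]) / (2 * np.pi * dt)

    def save_tsv(self, path) -> None:
        cols = {
            "t": self.times,
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "z": self.positions[:, 2],
            "qw": self.quaternions[:, 0], "qx": self.quaternions[:, 1],
            "qy": self.quaternions[:, 2], "qz": self.quaternions[:, 3],
            "fb1x": self.flagella[:, 0, 0], "fb1y": self.flagella[:, 0, 1],
            "fb1z": self.flagella[:, 0, 2],
            "fb2x": self.flagella[:, 1, 0], "fb2y": self.flagella[:, 1, 1],
            "fb2z": self.flagella[:, 1, 2],
        }
        df = pd.DataFrame(cols)
        with open(path, "w") as fh:
            if self.params is not None:
                import yaml
                snap = yaml.safe_dump(
                    {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in self.params.__dict__.items()},
                    default_flow_style=True, width=10**6,
                ).strip().replace("\n", "; ")
                fh.write(f"# params: {snap}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.9g")

    def save_h5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            for name in ("times", "positions", "quaternions", "flagella",
                         "crank", "twist0"):
                h5.create_dataset(name, data=getattr(self, name))


# ------------------------------------------------------------------ packing

_PAR_KEYS = {}


def _pack(params: ModelParams, state: SwimmerState):
    par = np.zeros(kernels.P_NPAR)
    par[kernels.P_ELL0] = params.bond_length
    par[kernels.P_KS] = params.k_stretch
    par[kernels.P_KBEND] = params.kappa_bend
    par[kernels.P_KTWIST] = params.kappa_twist
    par[kernels.P_GR] = params.gamma_rot
    par[kernels.P_GPARL] = params.gamma_par * params.bond_length
    par[kernels.P_GPERPL] = params.gamma_perp * params.bond_length
    par[kernels.P_GBT] = params.gamma_body_trans
    par[kernels.P_GBR] = params.gamma_body_rot
    par[kernels.P_ETA] = params.viscosity
    par[kernels.P_RB] = params.body_radius
    par[kernels.P_ABEAD] = params.bead_radius
    par[kernels.P_EPS] = params.wca_epsilon
    par[kernels.P_SIGBB] = params.bead_diameter
    par[kernels.P_SIGBODY] = params.body_radius + params.bead_radius
    par[kernels.P_DT] = params.dt
    par[kernels.P_ADIST] = params.body_radius + params.bond_length
    par[kernels.P_KHOOK] = params.hook_stiffness_eff

    geos = state.geometry
    nb = np.array([g.n_beads for g in geos], dtype=np.int64)
    nmax = int(nb.max())
    pos = np.zeros((2, nmax, 3))
    theta = np.zeros((2, max(nmax - 1, 1)))
    for f in range(2):
        pos[f, :nb[f]] = state.bead_positions[f]
        theta[f, :nb[f] - 1] = state.theta[f]
    anchors = np.stack([g.anchor_axis_body for g in geos])
    adirs = np.stack([g.anchor_dir_body for g in geos])
    obar = np.array([g.omega_bar for g in geos])
    mbar = np.array([g.m_bar for g in geos])
    c0cl = np.array([g.clamp_cos0 for g in geos])
    return par, nb, pos, theta, anchors, adirs, obar, mbar, c0cl


def _signed_torques(params: ModelParams, senses: Sequence[str]) -> np.ndarray:
    mags = params.motor_torques_pair
    return np.array([sense_sign(senses[f]) * mags[f] for f in range(2)])


def _unpack(state: SwimmerState, pos, theta, nb) -> None:
    for f in range(2):
        state.bead_positions[f][:] = pos[f, :nb[f]]
        state.theta[f][:] = theta[f, :nb[f] - 1]


def _crank_angles(state_X, q, pos, nb, anchors, adirs) -> np.ndarray:
    """Azimuth of a mid-filament bead about its anchor axis, body frame."""
    R = quat_to_matrix(q)
    out = np.zeros(2)
    for f in range(2):
        i = min(int(nb[f]) - 1, 6)
        v = R.T @ (pos[f, i] - state_X)
        a = anchors[f]
        d1 = adirs[f]
        d2 = np.cross(a, d1)
        w = v - np.dot(v, a) * a
        out[f] = math.atan2(float(np.dot(w, d2)), float(np.dot(w, d1)))
    return out


# ------------------------------------------------------------------ simulate

def rk2_step(state: SwimmerState, params: ModelParams,
             senses: Optional[Sequence[str]] = None,
             B: Optional[Sequence[float]] = None,
             n_steps: int = 1) -> SwimmerState:
    """Advance a state by ``n_steps`` midpoint steps (dt from params)."""
    senses = tuple(senses) if senses is not None else params.rotation_sense
    B = np.asarray(B if B is not None else params.B_field, dtype=float)
    out = state.copy()
    par, nb, pos, theta, anchors, adirs, obar, mbar, c0cl = _pack(params, out)
    Tm = _signed_torques(params, senses)
    mvec = params.moment_eff * moment_direction_body(params)
    mob_every = max(1, int(round(params.mobility_update_interval / params.dt)))
    status = kernels.run_steps(
        out.body_position, out.body_orientation, pos, theta, nb, anchors,
        adirs, obar, mbar, c0cl, Tm, mvec, B, par, n_steps, mob_every,
        1 if params.hydro_coupling else 0, 0,
    )
    _raise_status(status, out)
    _unpack(out, pos, theta, nb)
    out.time = state.time + n_steps * params.dt
    return out


def _raise_status(status: int, state: SwimmerState) -> None:
    if status == kernels.STATUS_STRAIN:
        raise RuntimeError(
            "time-step instability: bond strain exceeded 10% "
            f"(t={state.time:.6g} s); reduce dt or stiffness"
        )
    if status == kernels.STATUS_NONFINITE:
        raise RuntimeError(
            f"non-finite state during integration (t={state.time:.6g} s)"
        )


def simulate(params: ModelParams, protocol: Protocol,
             initial_state: Optional[SwimmerState] = None,
             keep_transient: bool = False,
             ramp_rate: float = 2.4e3, return_state: bool = False):
    """Run a full protocol; deterministic for identical inputs.

    The initial transient (default 20 ms) is discarded from the returned
    samples unless ``keep_transient`` is set.
    """
    state = (initial_state or build_swimmer(params)).copy()
    par, nb, pos, theta, anchors, adirs, obar, mbar, c0cl = _pack(params, state)
    mvec = params.moment_eff * moment_direction_body(params)
    mob_every = max(1, int(round(params.mobility_update_interval / params.dt)))
    coupling = 1 if params.hydro_coupling else 0

    dt = params.dt
    si = protocol.sample_interval
    n_samples = int(round(protocol.duration / si))

    sense_sched = protocol.sense_schedule or \
        [(0.0, protocol.duration, params.rotation_sense)]
    b_sched = protocol.b_schedule or \
        [(0.0, protocol.duration, params.B_field)]

    # synchronous rotation (both bundles same sense) drives a much faster
    # body roll; those stretches, and a short relaxation window after every
    # sense switch, are integrated with a finer step
    fine_dt = min(dt, 3.0e-8)
    relax = 0.006

    def chunk_dt(t_mid):
        for t0s, t1s, senses in sense_sched:
            if t0s - 1e-12 <= t_mid < t1s - 1e-12:
                if senses[0] == senses[1]:
                    return fine_dt
                if t_mid - t0s < relax and t0s > 1e-12:
                    return fine_dt
        return dt

    def lookup(sched, t):
        for t0, t1, v in sched:
            if t0 - 1e-12 <= t < t1 - 1e-12:
                return v
        return sched[-1][2]

    times = np.zeros(n_samples + 1)
    P = np.zeros((n_samples + 1, 3))
    Q = np.zeros((n_samples + 1, 4))
    FB = np.zeros((n_samples + 1, 2, 3))
    CR = np.zeros((n_samples + 1, 2))
    TW = np.zeros((n_samples + 1, 2))

    def record(k, t):
        times[k] = t
        P[k] = state.body_position
        Q[k] = state.body_orientation
        FB[k, 0] = pos[0, 1]
        FB[k, 1] = pos[1, 1]
        CR[k] = _crank_angles(state.body_position, state.body_orientation,
                              pos, nb, anchors, adirs)
        TW[k, 0] = theta[0, 0]
        TW[k, 1] = theta[1, 0]

    record(0, 0.0)
    step0 = 0
    # motor torque is rate-limited (spin-up / reversal ramp): the crank load
    # equilibrates over ~1 ms, so instantaneous application overwinds the
    # twist field and destabilises the filament
    current_Tm = np.zeros(2)
    startup = True
    for k in range(1, n_samples + 1):
        t_mid = (k - 0.5) * si
        senses = lookup(sense_sched, t_mid)
        Bval = np.asarray(lookup(b_sched, t_mid), dtype=float)
        dt_k = chunk_dt(t_mid)
        par[kernels.P_DT] = dt_k
        inner = max(1, int(round(si / dt_k)))
        mob_every = max(1, int(round(params.mobility_update_interval / dt_k)))
        target_Tm = _signed_torques(params, senses)
        if np.allclose(current_Tm, target_Tm):
            current_Tm = target_Tm
            startup = False
            status = kernels.run_steps(
                state.body_position, state.body_orientation, pos, theta, nb,
                anchors, adirs, obar, mbar, c0cl, current_Tm, mvec, Bval,
                par, inner, mob_every, coupling, step0,
            )
            state.time = k * si
            _raise_status(status, state)
            step0 += inner
        else:
            nsub = 10
            sub = max(1, inner // nsub)
            done = 0
            # sense reversals run at the fine step and tolerate a much
            # faster ramp than the initial spin-up from rest
            rate = ramp_rate if startup else 10.0 * ramp_rate
            while done < inner:
                n_now = min(sub, inner - done)
                dmax = rate * n_now * dt_k
                delta = np.clip(target_Tm - current_Tm, -dmax, dmax)
                current_Tm = current_Tm + delta
                status = kernels.run_steps(
                    state.body_position, state.body_orientation, pos, theta,
                    nb, anchors, adirs, obar, mbar, c0cl, current_Tm, mvec,
                    Bval, par, n_now, mob_every, coupling, step0,
                )
                state.time = k * si
                _raise_status(status, state)
                step0 += n_now
                done += n_now
        record(k, k * si)
        if k % max(1, 10000 // inner * 10) == 0:
            log.info("simulate: t = %.4f / %.4f s", k * si, protocol.duration)
    _unpack(state, pos, theta, nb)

    keep = times >= (0.0 if keep_transient else protocol.transient) - 1e-12
    traj = Trajectory(
        times=times[keep], positions=P[keep], quaternions=Q[keep],
        flagella=FB[keep], crank=CR[keep], twist0=TW[keep],
        params=params, protocol=protocol,
    )
    if return_state:
        return traj, state
    return traj


# ------------------------------------------------------------------ protocols

def reorientation_experiment(params: ModelParams,
                             switch_duration: float = 0.004,
                             n_replicates: int = 20, seed: int = 0,
                             jitter: float = 0.012,
                             axis_window: float = 0.066,
                             guard: float = 0.002,
                             transient: float = 0.024,
                             shared_run: bool = True) -> List[float]:
    """Turning angles of the transient synchronous-rotation protocol.

    Each replicate runs the push-pull mode (CCW+CW), switches both bundles
    to CCW for ``switch_duration``, and continues in push-pull mode; only
    the run time between switches varies (by ``U(0, jitter)``, seeded).  The
    turning angle is the angle between the helix-axis directions of the
    segments before and after the switch (one ``axis_window`` each, one
    large-helix period by default, separated from the switch by ``guard``).

    With ``shared_run`` (default) all replicates live in one continuous
    simulation, each inter-switch segment serving as the post-segment of one
    event and the pre-segment of the next; this halves the simulated time
    without changing the protocol seen by any single replicate.
    """
    if switch_duration < 0:
        raise ValueError("switch_duration must be non-negative")
    rng = np.random.default_rng(seed)
    si = 1e-4
    spacing_min = axis_window + 2 * guard

    def seg_axis(traj, lo, hi, rep):
        m = (traj.times >= lo - 1e-9) & (traj.times <= hi + 1e-9)
        if m.sum() < 10:
            log.warning("replicate %d: segment too short to fit an axis", rep)
            return None
        return segment_axis(traj.positions[m], traj.times[m])

    def turn(traj, ts, t2, rep):
        a_pre = seg_axis(traj, ts - guard - axis_window, ts - guard, rep)
        a_post = seg_axis(traj, ts + t2 + guard,
                          ts + t2 + guard + axis_window, rep)
        if a_pre is None or a_post is None:
            return float("nan")
        ang = float(np.degrees(np.arccos(np.clip(np.dot(a_pre, a_post),
                                                 -1.0, 1.0))))
        log.info("replicate %d: turning angle %.1f deg", rep, ang)
        return ang

    t2 = round(switch_duration / si) * si
    if shared_run:
        sched = []
        switches = []
        prev = 0.0
        t = transient + axis_window + guard + float(rng.uniform(0.0, jitter))
        for _ in range(n_replicates):
            t = round(t / si) * si
            sched.append((prev, t, ("CCW", "CW")))
            if t2 > 0:
                sched.append((t, t + t2, ("CCW", "CCW")))
            switches.append(t)
            prev = t + t2
            t = prev + spacing_min + float(rng.uniform(0.0, jitter))
        duration = round((prev + spacing_min) / si) * si
        sched.append((prev, duration, ("CCW", "CW")))
        proto = Protocol(duration=duration, sense_schedule=sched,
                         sample_interval=si, transient=0.0, seed=seed)
        traj = simulate(params, proto, keep_transient=True)
        return [turn(traj, ts, t2, k) for k, ts in enumerate(switches)]

    angles = []
    for rep in range(n_replicates):
        t1 = transient + axis_window + guard + float(rng.uniform(0.0, jitter))
        t1 = round(t1 / si) * si
        duration = round((t1 + t2 + spacing_min) / si) * si
        if t2 > 0:
            sched = [(0.0, t1, ("CCW", "CW")),
                     (t1, t1 + t2, ("CCW", "CCW")),
                     (t1 + t2, duration, ("CCW", "CW"))]
        else:
            sched = [(0.0, duration, ("CCW", "CW"))]
        proto = Protocol(duration=duration, sense_schedule=sched,
                         sample_interval=si, transient=0.0, seed=seed)
        traj = simulate(params, proto, keep_transient=True)
        angles.append(turn(traj, t1, t2, rep))
    return angles


def field_experiment(params: ModelParams, B_magnitude: float = 3.0,
                     moment_rule: str = "perpendicular_to_bisector",
                     duration: float = 1.2,
                     direction: Sequence[float] = (0.0, 0.0, 1.0),
                     sample_interval: float = 2.0e-4) -> Trajectory:
    """Swimming in a strong homogeneous field (hyper-helix regime)."""
    if B_magnitude < 0:
        raise ValueError("B_magnitude must be non-negative")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    p = params.replace(B_field=tuple(B_magnitude * d),
                       moment_rule=moment_rule)
    proto = Protocol(duration=duration, sample_interval=sample_interval)
    return simulate(p, proto)


_SWEEP_AXES = {
    "opening_angle": "opening_angle",
    "torque_ratio": "torque_ratio",
    "length_ratio": "length_ratio",
    "motor_torque": "motor_torque",
    "tilt_offsets": "tilt_offsets",
}


def sweep(params: ModelParams, axis: str, values: Sequence,
          protocol: Optional[Protocol] = None,
          periods: float = 5.0, transient: float = 0.020) -> pd.DataFrame:
    """One simulation + helix analysis per value of one model parameter.

    Columns mirror the result tables: value, D (µm), P (µm), T (ms),
    V_z (µm/s), V_t (µm/s).  Per-cell failures are recorded in an ``error``
    column and the sweep continues.
    """
    if axis not in _SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; one of {sorted(_SWEEP_AXES)}")
    rows = []
    for v in values:
        row = {"value": v if not isinstance(v, tuple) else str(v)}
        try:
            p = params.replace(**{_SWEEP_AXES[axis]: v})
            proto = protocol
            if proto is None:
                period_guess = _period_guess(p)
                dur = transient + periods * period_guess
                proto = Protocol(duration=round(dur, 3), transient=transient)
            traj = simulate(p, proto)
            fit = fit_helix(traj.to_track())
            row.update({"D": fit.diameter, "P": fit.pitch,
                        "T": fit.period_ms, "V_z": fit.v_z, "V_t": fit.v_t,
                        "error": ""})
        except (RuntimeError, ValueError, HelixNotFoundError) as exc:
            row.update({"D": np.nan, "P": np.nan, "T": np.nan,
                        "V_z": np.nan, "V_t": np.nan, "error": str(exc)})
            log.warning("sweep cell %s=%r failed: %s", axis, v, exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _period_guess(params: ModelParams) -> float:
    """Rough large-helix period estimate for sizing sweep runs.

    Scales the 59 ms default-geometry period with opening angle (larger
    angles precess faster) and inversely with motor torque.
    """
    base = 0.059 * (12.0 / max(params.motor_torque, 1e-6))
    ang = np.deg2rad(params.opening_angle)
    return float(np.clip(base * (np.sin(np.deg2rad(60)) / max(np.sin(ang), 0.2)) ** 1.5,
                         0.02, 0.30))
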
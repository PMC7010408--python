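"""Trajectory analysis: smoothing, QC, helix fits, re-orientation detection.

The helix extractor works in two stages: a non-parametric initialiser
(smoothed centreline for the axis, spectral peak of the transverse residual
for the period, RMS transverse radius for the diameter) followed by a
nonlinear least-squares polish of the explicit helix model.  The double-helix
fit uses the superposition model

    x(t) = [ r_l cos(2πt/T_l) + r_s cos(2πt/T_s),
             r_l sin(2πt/T_l) + r_s sin(2πt/T_s),  p_l t/T_l ]

in the axis-aligned frame, initialised from the two dominant peaks of the
complex transverse spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.optimize import least_squares

from .tracks import Track

__all__ = [
    "HelixFit", "ReorientationEvent", "QCResult", "HelixNotFoundError",
    "smooth", "qc_filter", "fit_helix", "fit_double_helix",
    "fit_helix_frenet",
    "detect_reorientations", "segment_axis",
]


class HelixNotFoundError(ValueError):
    """Raised when a track shows no significant helical component."""


@dataclass
class HelixFit:
    """Extracted helix descriptors.

    Periods are stored in seconds; the ``*_ms`` properties report
    milliseconds as used in the result tables.
    """

    diameter: float            # µm
    pitch: float               # µm
    period: float              # s
    axis: np.ndarray           # unit 3-vector
    v_z: float                 # effective axial velocity, µm/s
    v_t: float                 # instantaneous path speed, µm/s
    residual_rms: float = np.nan
    # double-helix components (NaN when fitted as a single helix)
    r_l: float = np.nan
    p_l: float = np.nan
    T_l: float = np.nan
    r_s: float = np.nan
    T_s: float = np.nan
    small_pitch: float = np.nan   # axial advance per small period
    fallback: bool = False        # double-helix fit fell back to single

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n > 0:
            self.axis = self.axis / n
        for name in ("diameter", "pitch", "period", "v_z", "v_t"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def period_ms(self) -> float:
        return 1e3 * self.period

    @property
    def T_l_ms(self) -> float:
        return 1e3 * self.T_l

    @property
    def T_s_ms(self) -> float:
        return 1e3 * self.T_s


@dataclass
class ReorientationEvent:
    time: float                # s, centre of the event
    duration: float            # s
    angle: float               # degrees in [0, 180]
    pre_axis: np.ndarray
    post_axis: np.ndarray
    pre_fit: Optional[HelixFit] = None
    post_fit: Optional[HelixFit] = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if not (0.0 <= self.angle <= 180.0):
            raise ValueError("turning angle must lie in [0, 180] degrees")


@dataclass
class QCResult:
    passed: bool
    reasons: List[str]
    metrics: dict


# ------------------------------------------------------------------ smoothing

def smooth(track: Track, window: int) -> Track:
    """Centred moving average; edges use shrinking windows; length preserved."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    n = len(track)
    if window >= n:
        raise ValueError(f"window {window} must be smaller than track length {n}")
    return track.with_positions(_moving_average(track.positions, window))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window == 1:
        return x.copy()
    n = len(x)
    half = window // 2
    cs = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    out = np.empty_like(x, dtype=float)
    idx = np.arange(n)
    h = np.minimum(np.minimum(idx, n - 1 - idx), half)
    lo = idx - h
    hi = idx + h + 1
    out = (cs[hi] - cs[lo]) / (hi - lo)[:, None]
    return out


# ------------------------------------------------------------------ QC filter

def qc_filter(track: Track, min_duration: float = 0.4, min_msd: float = 10.0,
              max_mean_turn: float = 60.0) -> QCResult:
    """The three track-quality rules used before any parameter extraction.

    duration >= 0.4 s; squared net displacement >= 10 µm²; mean angle
    between consecutive velocity vectors (raw track) < 60°.
    """
    reasons = []
    duration = track.duration
    if duration < min_duration:
        reasons.append("duration")
    msd = float(np.sum((track.positions[-1] - track.positions[0]) ** 2))
    if msd < min_msd:
        reasons.append("msd")
    v = track.velocities()
    nv = np.linalg.norm(v, axis=1)
    ok = nv > 0
    vv = v[ok] / nv[ok, None]
    cosang = np.clip(np.sum(vv[1:] * vv[:-1], axis=1), -1.0, 1.0)
    mean_turn = float(np.degrees(np.arccos(cosang)).mean()) if len(cosang) else 0.0
    if not mean_turn < max_mean_turn:
        reasons.append("angle")
    return QCResult(
        passed=not reasons, reasons=reasons,
        metrics={"duration": duration, "msd": msd, "mean_turn": mean_turn},
    )


# ------------------------------------------------------------------ helpers

def segment_axis(positions: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Drift direction of a segment from the linear regression slope.

    Over an integer number of helix periods the circular component averages
    out exactly, so the slope direction equals the helix axis.
    """
    t = times - times.mean()
    denom = float(np.dot(t, t))
    slope = (positions * t[:, None]).sum(axis=0) / denom
    n = np.linalg.norm(slope)
    if n == 0:
        raise ValueError("degenerate segment: no net drift")
    return slope / n


def _orthonormal_frame(axis: np.ndarray) -> np.ndarray:
    """Rows: two transverse directions and the axis."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return np.vstack([e1, e2, axis])


def _dominant_frequency(w: np.ndarray, fps: float, nskip: int = 1):
    """Signed frequency and amplitude of the dominant complex spectral peak."""
    n = len(w)
    spec = np.fft.fft(w - w.mean())
    freqs = np.fft.fftfreq(n, d=1.0 / fps)
    mag = np.abs(spec)
    mag[0] = 0.0
    k = int(np.argmax(mag))
    # quadratic interpolation on log-magnitude around the peak
    km, kp = (k - 1) % n, (k + 1) % n
    a, b, c = mag[km], mag[k], mag[kp]
    denom = a - 2 * b + c
    delta = 0.5 * (a - c) / denom if abs(denom) > 1e-30 else 0.0
    delta = float(np.clip(delta, -0.5, 0.5))
    df = fps / n
    fk = freqs[k]
    f = fk + delta * df * (1.0 if fk >= 0 else 1.0)
    return f, mag[k] / n, mag


def _axis_angles(axis: np.ndarray):
    theta = float(np.arccos(np.clip(axis[2], -1, 1)))
    phi = float(np.arctan2(axis[1], axis[0]))
    return theta, phi


def _axis_from_angles(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


# ------------------------------------------------------------------ single fit

def fit_helix(track: Track, refine: bool = True,
              min_periods: float = 1.5) -> HelixFit:
    """Extract (D, P, T, axis, V_z, V_t) from a helical track.

    Raises :class:`HelixNotFoundError` when no significant transverse
    oscillation is present (straight or irregular tracks).
    """
    pos = track.positions
    t = track.times - track.times[0]
    n = len(pos)
    fps = track.fps

    # instantaneous speed on the lightly smoothed path
    w5 = min(5, n - 1 if (n - 1) % 2 == 1 else n - 2)
    w5 = max(w5, 1)
    light = _moving_average(pos, w5)
    seg = np.linalg.norm(np.diff(light, axis=0), axis=1)
    v_t = float(seg.sum() / (t[-1] - t[0]))

    axis = segment_axis(pos, t)
    period = None
    centered = pos - pos.mean(axis=0)
    for _ in range(3):
        frame = _orthonormal_frame(axis)
        q = centered @ frame.T
        w = q[:, 0] + 1j * q[:, 1]
        f, amp, mag = _dominant_frequency(w, fps)
        if abs(f) < 0.5 / (t[-1] - t[0]):
            raise HelixNotFoundError("no transverse periodicity detected")
        period = 1.0 / abs(f)
        win = int(round(period * fps))
        win = max(3, win + (1 - win % 2))
        if win >= n:
            win = n - 1 if (n - 1) % 2 == 1 else n - 2
        center = _moving_average(pos, win)
        axis_new = segment_axis(center, t)
        if np.dot(axis_new, axis) < 0:
            axis_new = -axis_new
        axis = axis_new

    # significance: transverse variance explained by the dominant band
    frame = _orthonormal_frame(axis)
    q = (pos - center) @ frame.T
    w = q[:, 0] + 1j * q[:, 1]
    f, amp, mag = _dominant_frequency(w, fps)
    total = float(np.sum(np.abs(mag) ** 2))
    k = int(np.argmax(mag))
    band = float(np.sum(mag[max(0, k - 2):k + 3] ** 2))
    radius = float(np.sqrt(np.mean(np.abs(w) ** 2)))
    if total <= 0 or band / total < 0.2 or radius < 1e-4:
        raise HelixNotFoundError("no significant helical component")
    period = 1.0 / abs(f)
    if (t[-1] - t[0]) < min_periods * period:
        raise HelixNotFoundError("track shorter than the minimum period count")

    qa = pos @ frame.T
    vz = float(segment_axis_1d(qa[:, 2], t))
    pitch = abs(vz) * period
    fit = HelixFit(
        diameter=2 * radius, pitch=pitch, period=period, axis=axis,
        v_z=abs(vz), v_t=v_t,
    )
    if refine:
        fit = _refine_single(track, fit)
        fit.v_t = v_t
    return fit


def segment_axis_1d(x: np.ndarray, t: np.ndarray) -> float:
    tc = t - t.mean()
    return float(np.dot(x, tc) / np.dot(tc, tc))


def _helix_model(params, t, frame0):
    th, ph, cx, cy, z0, r, omega, phi0, vz = params
    axis = _axis_from_angles(th, ph)
    frame = _orthonormal_frame(axis)
    x = cx + r * np.cos(omega * t + phi0)
    y = cy + r * np.sin(omega * t + phi0)
    z = z0 + vz * t
    return np.stack([x, y, z], axis=1) @ frame


def _refine_single(track: Track, init: HelixFit) -> HelixFit:
    pos = track.positions
    t = track.times - track.times[0]
    frame = _orthonormal_frame(init.axis)
    q = (pos - pos.mean(axis=0)) @ frame.T
    w = q[:, 0] + 1j * q[:, 1]
    f, amp, _ = _dominant_frequency(w, track.fps)
    omega0 = 2 * np.pi * f
    # initial phase from the demodulated signal
    dem = (w - w.mean()) * np.exp(-1j * omega0 * t)
    phi0 = float(np.angle(dem.mean()))
    th, ph = _axis_angles(init.axis)
    p0 = np.array([
        th, ph, float(w.real.mean()), float(w.imag.mean()),
        float(q[0, 2]), 0.5 * init.diameter, omega0, phi0,
        init.v_z * np.sign(segment_axis_1d(q[:, 2], t) or 1.0),
    ])
    mean = pos.mean(axis=0)

    def resid(p):
        return (_helix_model(p, t, None) - (pos - mean)).ravel()

    sol = least_squares(resid, p0, method="lm", max_nfev=400)
    th, ph, cx, cy, z0, r, omega, phi0, vz = sol.x
    axis = _axis_from_angles(th, ph)
    if vz < 0:
        axis, vz, z0 = -axis, -vz, -z0
        # re-express: flipping the axis flips the axial coordinate
    period = 2 * np.pi / abs(omega)
    rms = float(np.sqrt(np.mean(sol.fun**2) * 3))
    return HelixFit(
        diameter=2 * abs(r), pitch=abs(vz) * period, period=period,
        axis=axis, v_z=abs(vz), v_t=init.v_t, residual_rms=rms,
    )


def fit_helix_frenet(track: Track, arc_step: float = 0.5) -> HelixFit:
    """Helix descriptors from local differential geometry of a smooth path.

    Works on arcs shorter than one turn (where spectral estimators fail):
    the path is resampled at ``arc_step`` (µm) spacing, discrete Frenet
    curvature κ and torsion τ are averaged along it, and the helix radius
    and pitch follow from R = κ/(κ²+τ²), b = τ/(κ²+τ²).  Intended for
    heavily smoothed centrelines (e.g. the hyper-helix of a field run).
    """
    pos = track.positions
    t = track.times
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n_pts = max(int(total / arc_step) + 1, 8)
    s_grid = np.linspace(0, total, n_pts)
    rs = np.stack([np.interp(s_grid, s, pos[:, d]) for d in range(3)], axis=1)
    ds = total / (n_pts - 1)
    tang = np.diff(rs, axis=0)
    tang /= np.linalg.norm(tang, axis=1)[:, None]
    # curvature from consecutive tangent angles
    dots = np.clip(np.sum(tang[1:] * tang[:-1], axis=1), -1, 1)
    kappa = np.arccos(dots) / ds
    # torsion from the dihedral angle between consecutive binormals
    bn = np.cross(tang[:-1], tang[1:])
    nb = np.linalg.norm(bn, axis=1)
    ok = nb > 1e-12
    bn[ok] = bn[ok] / nb[ok, None]
    cosb = np.clip(np.sum(bn[1:] * bn[:-1], axis=1), -1, 1)
    signs = np.sign(np.sum(bn[:-1] * tang[2:], axis=1))
    tau = signs * np.arccos(cosb) / ds
    k = float(np.median(kappa))
    tu = float(np.median(np.abs(tau)))
    denom = k * k + tu * tu
    if denom <= 0 or k <= 0:
        raise HelixNotFoundError("degenerate arc: no curvature")
    radius = k / denom
    b = tu / denom
    v_s = total / (t[-1] - t[0])
    omega = v_s * np.sqrt(denom)
    period = 2 * np.pi / omega
    v_z = v_s * tu / np.sqrt(denom)
    axis = segment_axis(pos, t) if np.linalg.norm(pos[-1] - pos[0]) > 0 \
        else np.array([0.0, 0.0, 1.0])
    return HelixFit(diameter=2 * radius, pitch=2 * np.pi * b, period=period,
                    axis=axis, v_z=v_z, v_t=v_s)


# ------------------------------------------------------------------ double fit

def _double_model(params, t):
    th, ph, cx, cy, z0, vz, rl, wl, pl0, rs, ws, ps0 = params
    axis = _axis_from_angles(th, ph)
    frame = _orthonormal_frame(axis)
    wcomp = (cx + 1j * cy
             + rl * np.exp(1j * (wl * t + pl0))
             + rs * np.exp(1j * (ws * t + ps0)))
    z = z0 + vz * t
    return np.stack([wcomp.real, wcomp.imag, z], axis=1) @ frame


def fit_double_helix(track: Track, min_small_samples: float = 8.0) -> HelixFit:
    """Fit the two-helix superposition model; falls back to a single helix.

    The large and small components are initialised from the two dominant
    peaks of the complex transverse spectrum in the axis frame; the fit is
    accepted when it reduces the residual RMS by at least 25% relative to
    the single-helix fit.
    """
    single = fit_helix(track)
    pos = track.positions
    t = track.times - track.times[0]
    fps = track.fps
    frame = _orthonormal_frame(single.axis)
    mean = pos.mean(axis=0)
    q = (pos - mean) @ frame.T
    w = q[:, 0] + 1j * q[:, 1]

    n = len(w)
    spec = np.fft.fft(w - w.mean())
    freqs = np.fft.fftfreq(n, d=1.0 / fps)
    mag = np.abs(spec)
    mag[0] = 0.0
    k1 = int(np.argmax(mag))
    # mask a band around the first peak, find the second
    mask = np.ones(n, bool)
    lo = max(0, k1 - max(2, n // 50))
    hi = min(n, k1 + max(2, n // 50) + 1)
    mask[lo:hi] = False
    if k1 > n // 2:
        pass
    mag2 = np.where(mask, mag, 0.0)
    k2 = int(np.argmax(mag2))
    f1, a1 = freqs[k1], mag[k1] / n
    f2, a2 = freqs[k2], mag[k2] / n

    resolvable = (a2 > 0.02 * a1) and fps / abs(f2) >= min_small_samples \
        and abs(abs(f2) - abs(f1)) > 1.0 / (t[-1] - t[0])
    if not resolvable:
        out = _as_double(single, fallback=True)
        return out
    # large component = larger amplitude
    if a2 > a1:
        (f1, a1), (f2, a2) = (f2, a2), (f1, a1)
    th, ph = _axis_angles(single.axis)
    phl = float(np.angle(np.mean((w - w.mean()) * np.exp(-1j * 2 * np.pi * f1 * t))))
    phs = float(np.angle(np.mean((w - w.mean()) * np.exp(-1j * 2 * np.pi * f2 * t))))
    p0 = np.array([
        th, ph, float(w.real.mean()), float(w.imag.mean()), float(q[0, 2]),
        segment_axis_1d(q[:, 2], t),
        a1, 2 * np.pi * f1, phl, a2, 2 * np.pi * f2, phs,
    ])

    def resid(p):
        return (_double_model(p, t) - (pos - mean)).ravel()

    sol = least_squares(resid, p0, method="lm", max_nfev=600)
    rms = float(np.sqrt(np.mean(sol.fun**2) * 3))
    if not (rms <= 0.75 * max(single.residual_rms, 1e-12)):
        return _as_double(single, fallback=True)
    th, ph, cx, cy, z0, vz, rl, wl, pl0, rs, ws, ps0 = sol.x
    if min(abs(rl), abs(rs)) < max(1e-3, 5e-3 * max(abs(rl), abs(rs))):
        # the second component is spectral leakage, not a real helix
        return _as_double(single, fallback=True)
    axis = _axis_from_angles(th, ph)
    if vz < 0:
        axis, vz = -axis, -vz
    T_l = 2 * np.pi / abs(wl)
    T_s = 2 * np.pi / abs(ws)
    rl, rs = abs(rl), abs(rs)
    if rl < rs:  # keep the large helix first
        rl, rs, T_l, T_s = rs, rl, T_s, T_l
    p_l = vz * T_l
    return HelixFit(
        diameter=2 * rl, pitch=p_l, period=T_l, axis=axis, v_z=vz,
        v_t=single.v_t, residual_rms=rms, r_l=rl, p_l=p_l, T_l=T_l,
        r_s=rs, T_s=T_s, small_pitch=vz * T_s, fallback=False,
    )


def _as_double(single: HelixFit, fallback: bool) -> HelixFit:
    return HelixFit(
        diameter=single.diameter, pitch=single.pitch, period=single.period,
        axis=single.axis, v_z=single.v_z, v_t=single.v_t,
        residual_rms=single.residual_rms, r_l=0.5 * single.diameter,
        p_l=single.pitch, T_l=single.period, r_s=0.0, T_s=np.nan,
        small_pitch=np.nan, fallback=fallback,
    )


# ------------------------------------------------------- re-orientation events

def _local_axes(track: Track, window: int) -> np.ndarray:
    """Sliding mean-velocity direction over a centred window (NaN at edges)."""
    v = track.velocities()
    cs = np.vstack([np.zeros(3), np.cumsum(v, axis=0)])
    nv = len(v)
    half = window // 2
    axes = np.full((nv, 3), np.nan)
    for i in range(half, nv - half):
        s = cs[i + half + 1] - cs[i - half]
        nrm = np.linalg.norm(s)
        if nrm > 0:
            axes[i] = s / nrm
    return axes


def _estimate_period(track: Track) -> float:
    """Dominant wobble period from the velocity-direction autocorrelation.

    Velocities are pre-smoothed over ~4 ms so localisation noise does not
    masquerade as a fast wobble.
    """
    v = track.velocities()
    w = max(3, int(round(0.004 * track.fps)) | 1)
    if w < len(v):
        v = _moving_average(v, w)
    nv = np.linalg.norm(v, axis=1)
    ok = nv > 0
    u = np.zeros_like(v)
    u[ok] = v[ok] / nv[ok, None]
    n = len(u)
    max_lag = min(n - 2, int(0.3 * track.fps))
    c = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        c[lag - 1] = np.mean(np.sum(u[lag:] * u[:-lag], axis=1))
    # first substantial local minimum, then the next local maximum
    min_lag = max(2, w)
    lag_min = None
    for i in range(min_lag, len(c) - 1):
        if c[i] < c[i - 1] and c[i] <= c[i + 1]:
            lag_min = i
            break
    if lag_min is None:
        raise HelixNotFoundError("no periodic wobble found")
    for i in range(lag_min + 1, len(c) - 1):
        if c[i] >= c[i - 1] and c[i] > c[i + 1]:
            return (i + 1) / track.fps
    raise HelixNotFoundError("no periodic wobble found")


def detect_reorientations(track: Track, angle_threshold: float = 30.0,
                          max_duration: float = 0.010, guard: float = 0.005,
                          period: Optional[float] = None,
                          fit_segments: bool = False) -> List[ReorientationEvent]:
    """Find abrupt changes of the local helix-axis direction.

    An event is an interval where the axis direction (estimated from mean
    velocities over one helix period on either side, excluding the event
    ± ``guard``) changes by more than ``angle_threshold`` degrees.  The
    duration is the 10-90% rise time of the direction change, measured on a
    lightly smoothed velocity-direction signal.
    """
    fps = track.fps
    if period is None:
        period = _estimate_period(track)
    win = max(3, int(round(period * fps)))
    gskip = int(round(guard * fps))
    axes = _local_axes(track, win + (1 - win % 2))
    nv = len(axes)
    half = (win + (1 - win % 2)) // 2
    off = half + gskip

    # separation angle between pre- and post-windows around each instant
    sep = np.full(nv, np.nan)
    for i in range(off, nv - off):
        a0 = axes[i - off]
        a1 = axes[i + off]
        if np.any(np.isnan(a0)) or np.any(np.isnan(a1)):
            continue
        sep[i] = np.degrees(np.arccos(np.clip(np.dot(a0, a1), -1, 1)))

    events: List[ReorientationEvent] = []
    above = sep > angle_threshold
    i = 0
    v = track.velocities()
    nvn = np.linalg.norm(v, axis=1)
    u = np.zeros_like(v)
    okv = nvn > 0
    u[okv] = v[okv] / nvn[okv, None]
    usm = _moving_average(u, 3)
    usm /= np.maximum(np.linalg.norm(usm, axis=1)[:, None], 1e-30)
    while i < nv:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < nv and above[j]:
            j += 1
        # centre the event on the angular-speed pulse of the direction signal,
        # which is sharply localised at the turn; use the midpoint of the
        # near-maximal plateau (constant-rate turns give a flat-topped pulse)
        omega = np.degrees(np.arccos(np.clip(
            np.sum(usm[i:j] * usm[i - 1:j - 1], axis=1), -1, 1)))
        high = np.flatnonzero(omega >= 0.9 * omega.max())
        kpeak = i + int(round(0.5 * (high[0] + high[-1])))
        kpeak = min(max(kpeak, off), nv - off - 1)
        pre = axes[kpeak - off]
        post = axes[kpeak + off]
        angle = float(np.degrees(np.arccos(np.clip(np.dot(pre, post), -1, 1))))
        dur = _event_duration(usm, kpeak, fps, max_duration)
        if dur is not None and dur <= max_duration + 1e-12:
            tev = float(track.times[kpeak])
            events.append(ReorientationEvent(
                time=tev, duration=dur, angle=angle,
                pre_axis=pre.copy(), post_axis=post.copy(),
            ))
        i = j + max(1, int(0.5 * win))
    if fit_segments and events:
        _attach_segment_fits(track, events, guard)
    return events


def _event_duration(usm, kpeak, fps, max_duration):
    """Duration from the angular-speed pulse of the velocity direction.

    During a re-orientation the direction turns at a rate well above the
    helix-wobble baseline; the duration is the width of the angular-speed
    pulse at half its prominence (full width at half maximum), which for a
    constant-rate axis rotation equals the rotation time.
    """
    omega = np.degrees(
        np.arccos(np.clip(np.sum(usm[1:] * usm[:-1], axis=1), -1, 1))
    ) * fps  # deg/s between consecutive frames
    n = len(omega)
    baseline = float(np.median(omega))
    span = int(round(2.0 * max_duration * fps)) + 2
    lo = max(0, kpeak - span)
    hi = min(n, kpeak + span)
    if hi - lo < 3:
        return None
    window = omega[lo:hi]
    kmax = lo + int(np.argmax(window))
    peak = omega[kmax]
    if peak <= baseline:
        return None
    thr = baseline + 0.5 * (peak - baseline)
    a = kmax
    while a > lo and omega[a - 1] > thr:
        a -= 1
    b = kmax
    while b < hi - 1 and omega[b + 1] > thr:
        b += 1
    return max(b - a + 1, 1) / fps


def _attach_segment_fits(track, events, guard):
    bounds = [0.0] + [e.time for e in events] + [track.times[-1]]
    for k, ev in enumerate(events):
        t0 = bounds[k] + (guard if k > 0 else 0.0)
        t1 = ev.time - guard
        t2 = ev.time + guard
        t3 = bounds[k + 2] - (guard if k + 1 < len(events) else 0.0)
        for (a, b, attr) in ((t0, t1, "pre_fit"), (t2, t3, "post_fit")):
            m = (track.times >= a) & (track.times <= b)
            if m.sum() < 20:
                continue
            sub = Track(track.times[m], track.positions[m], track.fps,
                        track.source, {})
            try:
                setattr(ev, attr, fit_helix(sub))
            except (HelixNotFoundError, ValueError):
                pass
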
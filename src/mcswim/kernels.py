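"""Fused integration kernel for the swimmer equations of motion.

A midpoint (second-order Runge-Kutta) step advances body pose and bead
positions explicitly; the bond twist angles, whose relaxation time
(γr·ℓ0/κt ~ 1e-8 s) sits below the 1e-7 s time step, are advanced with a
Crank-Nicolson step that treats the stiff linear twist Laplacian implicitly
(tridiagonal solve) and everything else at the explicit stage value.  The
dense translational mobility (local drags + Rotne-Prager coupling) is
refreshed on a configurable interval; particle displacements per step
(~1e-5 µm) make it essentially constant between refreshes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .elastic import flagellum_forces
from .hydro import _rpy_pair

# indices into the packed scalar-parameter array
P_ELL0, P_KS, P_KBEND, P_KTWIST, P_GR, P_GPARL, P_GPERPL, P_GBT, P_GBR, \
    P_ETA, P_RB, P_ABEAD, P_EPS, P_SIGBB, P_SIGBODY, P_DT, P_ADIST, \
    P_KHOOK, P_NPAR = range(19)

STATUS_OK = 0
STATUS_STRAIN = 1
STATUS_NONFINITE = 2

WCA_SKIN = 0.15  # µm, candidate-pair skin on top of the WCA cutoff
MAX_PAIRS = 8192


@njit(cache=True, fastmath=True, inline="always")
def _rotate(R, v, out):
    for a in range(3):
        out[a] = R[a, 0] * v[0] + R[a, 1] * v[1] + R[a, 2] * v[2]


@njit(cache=True, fastmath=True)
def _quat_matrix(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1 - 2 * (y * y + z * z)
    R[0, 1] = 2 * (x * y - w * z)
    R[0, 2] = 2 * (x * z + w * y)
    R[1, 0] = 2 * (x * y + w * z)
    R[1, 1] = 1 - 2 * (x * x + z * z)
    R[1, 2] = 2 * (y * z - w * x)
    R[2, 0] = 2 * (x * z - w * y)
    R[2, 1] = 2 * (y * z + w * x)
    R[2, 2] = 1 - 2 * (x * x + y * y)


@njit(cache=True, fastmath=True)
def _quat_rotate_update(q, omega, h, qout):
    """qout = exp-map rotation by omega*h composed with q, normalised."""
    wx = omega[0] * h
    wy = omega[1] * h
    wz = omega[2] * h
    ang = np.sqrt(wx * wx + wy * wy + wz * wz)
    if ang < 1e-300:
        for i in range(4):
            qout[i] = q[i]
        return
    s = np.sin(0.5 * ang) / ang
    dw = np.cos(0.5 * ang)
    dx = s * wx
    dy = s * wy
    dz = s * wz
    aw, ax, ay, az = dw, dx, dy, dz
    bw, bx, by, bz = q[0], q[1], q[2], q[3]
    qout[0] = aw * bw - ax * bx - ay * by - az * bz
    qout[1] = aw * bx + ax * bw + ay * bz - az * by
    qout[2] = aw * by - ax * bz + ay * bw + az * bx
    qout[3] = aw * bz + ax * by - ay * bx + az * bw
    nrm = np.sqrt(qout[0] ** 2 + qout[1] ** 2 + qout[2] ** 2 + qout[3] ** 2)
    for i in range(4):
        qout[i] /= nrm


@njit(cache=True, fastmath=True)
def _fill_particles(X, q, pos, nb, par, centers, radii, tangents, is_bead):
    """Stack body + free beads; update local bead tangents."""
    centers[0, 0] = X[0]
    centers[0, 1] = X[1]
    centers[0, 2] = X[2]
    radii[0] = par[P_RB]
    is_bead[0] = 0
    idx = 1
    for f in range(2):
        n = nb[f]
        for i in range(1, n):
            for d in range(3):
                centers[idx, d] = pos[f, i, d]
            radii[idx] = par[P_ABEAD]
            is_bead[idx] = 1
            # tangent: mean of adjacent bonds (single bond at the tip)
            tx = pos[f, i, 0] - pos[f, i - 1, 0]
            ty = pos[f, i, 1] - pos[f, i - 1, 1]
            tz = pos[f, i, 2] - pos[f, i - 1, 2]
            if i < n - 1:
                tx += pos[f, i + 1, 0] - pos[f, i, 0]
                ty += pos[f, i + 1, 1] - pos[f, i, 1]
                tz += pos[f, i + 1, 2] - pos[f, i, 2]
            nrm = np.sqrt(tx * tx + ty * ty + tz * tz)
            tangents[idx, 0] = tx / nrm
            tangents[idx, 1] = ty / nrm
            tangents[idx, 2] = tz / nrm
            idx += 1


@njit(cache=True, fastmath=True)
def _build_mobility(centers, radii, tangents, is_bead, par, coupling, M):
    K = centers.shape[0]
    blk = np.empty((3, 3))
    M[:, :] = 0.0
    for i in range(K):
        if is_bead[i] == 0:
            mi = 1.0 / par[P_GBT]
            for d in range(3):
                M[3 * i + d, 3 * i + d] = mi
        else:
            tpar = 1.0 / par[P_GPARL]
            tperp = 1.0 / par[P_GPERPL]
            for a in range(3):
                for b in range(3):
                    M[3 * i + a, 3 * i + b] = (
                        (tpar - tperp) * tangents[i, a] * tangents[i, b]
                    )
                M[3 * i + a, 3 * i + a] += tperp
    if coupling != 0:
        for i in range(K):
            for j in range(i + 1, K):
                _rpy_pair(
                    centers[i, 0] - centers[j, 0],
                    centers[i, 1] - centers[j, 1],
                    centers[i, 2] - centers[j, 2],
                    radii[i], radii[j], par[P_ETA], blk,
                )
                for a in range(3):
                    for b in range(3):
                        M[3 * i + a, 3 * j + b] = blk[a, b]
                        M[3 * j + b, 3 * i + a] = blk[a, b]


@njit(cache=True, fastmath=True)
def _build_pairs(centers, is_bead, chain_id, chain_pos, par, pairs):
    """Candidate WCA pairs within cutoff + skin.  Returns pair count."""
    K = centers.shape[0]
    rc_bb = 1.122462048309373 * par[P_SIGBB] + WCA_SKIN
    rc_body = 1.122462048309373 * par[P_SIGBODY] + WCA_SKIN
    np_ = 0
    for i in range(K):
        for j in range(i + 1, K):
            if is_bead[i] == 1 and is_bead[j] == 1:
                if chain_id[i] == chain_id[j] and abs(chain_pos[i] - chain_pos[j]) <= 1:
                    continue
                rc = rc_bb
            else:
                rc = rc_body
            dx = centers[i, 0] - centers[j, 0]
            dy = centers[i, 1] - centers[j, 1]
            dz = centers[i, 2] - centers[j, 2]
            if dx * dx + dy * dy + dz * dz < rc * rc:
                if np_ < MAX_PAIRS:
                    pairs[np_, 0] = i
                    pairs[np_, 1] = j
                    np_ += 1
    return np_


@njit(cache=True, fastmath=True)
def _wca_accumulate(centers, is_bead, pairs, npairs, par, F):
    """Truncated-and-shifted (WCA) repulsion over the candidate pairs."""
    for p in range(npairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        if is_bead[i] == 1 and is_bead[j] == 1:
            sig = par[P_SIGBB]
        else:
            sig = par[P_SIGBODY]
        rc = 1.122462048309373 * sig
        dx = centers[i, 0] - centers[j, 0]
        dy = centers[i, 1] - centers[j, 1]
        dz = centers[i, 2] - centers[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc * rc:
            continue
        if r2 < 1e-20:
            return 1
        s2 = sig * sig / r2
        s6 = s2 * s2 * s2
        fmag = 24.0 * par[P_EPS] * (2.0 * s6 * s6 - s6) / r2
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        F[3 * i + 0] += fx
        F[3 * i + 1] += fy
        F[3 * i + 2] += fz
        F[3 * j + 0] -= fx
        F[3 * j + 1] -= fy
        F[3 * j + 2] -= fz
    return 0


@njit(cache=True, fastmath=True)
def _eval_forces(X, q, pos, theta, nb, anchors, adirs, obar, mbar, c0cl, Tm,
                 mvec, B, par, centers, is_bead, pairs, npairs,
                 F, tau_body, Tth, Ftmp, scr_l, scr_t, scr_u, scr_tb, scr_lb,
                 scr_ub, scr_thb):
    """All forces/torques at the given configuration.

    F is the flat (3K,) translational force vector (body first), tau_body the
    body torque, Tth the per-bond axial twist torques (motor included).
    """
    R = np.empty((3, 3))
    _quat_matrix(q, R)
    F[:] = 0.0
    tau_body[:] = 0.0
    a_lab = np.empty(3)
    d_lab = np.empty(3)
    abar = np.empty(3)
    dbar = np.empty(3)
    rel = np.empty(3)
    tmp = np.empty(3)
    off = 0
    for f in range(2):
        n = nb[f]
        _rotate(R, anchors[f], a_lab)
        _rotate(R, adirs[f], d_lab)
        Ff = Ftmp[:n]
        Ff[:, :] = 0.0
        Tf = Tth[f]
        for j in range(n - 1):
            Tf[j] = 0.0
        abar[:] = 0.0
        dbar[:] = 0.0
        flagellum_forces(pos[f, :n], theta[f, :n - 1], a_lab, d_lab,
                         par[P_ELL0], par[P_KS], par[P_KBEND], par[P_KTWIST],
                         obar[f], mbar[f], c0cl[f], par[P_KHOOK], Ff, Tf,
                         abar, dbar,
                         scr_l[:n - 1], scr_t[:n - 1], scr_u[:n - 1],
                         scr_tb[:n - 1], scr_lb[:n - 1], scr_ub[:n - 1],
                         scr_thb[:n - 1])
        # body-rigid bead 0: transfer force and lever-arm torque
        for d in range(3):
            F[d] += Ff[0, d]
            rel[d] = pos[f, 0, d] - X[d]
        tau_body[0] += rel[1] * Ff[0, 2] - rel[2] * Ff[0, 1]
        tau_body[1] += rel[2] * Ff[0, 0] - rel[0] * Ff[0, 2]
        tau_body[2] += rel[0] * Ff[0, 1] - rel[1] * Ff[0, 0]
        # reaction torque from the body-fixed anchor frame
        _cross(a_lab, abar, tmp)
        for d in range(3):
            tau_body[d] -= tmp[d]
        _cross(d_lab, dbar, tmp)
        for d in range(3):
            tau_body[d] -= tmp[d]
        # motor: torque on the base twist angle, exact counter-torque on body
        Tf[0] += Tm[f]
        t0 = np.empty(3)
        nrm = 0.0
        for d in range(3):
            t0[d] = pos[f, 1, d] - pos[f, 0, d]
            nrm += t0[d] * t0[d]
        nrm = np.sqrt(nrm)
        for d in range(3):
            tau_body[d] -= Tm[f] * t0[d] / nrm
        # free-bead forces into the flat vector
        for i in range(1, n):
            for d in range(3):
                F[3 * (1 + off + i - 1) + d] += Ff[i, d]
        off += n - 1
    # excluded volume
    status = _wca_accumulate(centers, is_bead, pairs, npairs, par, F)
    # magnetic torque m x B
    _rotate(R, mvec, tmp)
    tau_body[0] += tmp[1] * B[2] - tmp[2] * B[1]
    tau_body[1] += tmp[2] * B[0] - tmp[0] * B[2]
    tau_body[2] += tmp[0] * B[1] - tmp[1] * B[0]
    return status


@njit(cache=True, fastmath=True, inline="always")
def _cross(a, b, out):
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]


@njit(cache=True, fastmath=True)
def _twist_solve(y, n, lam, out, scr):
    """out = (I + lam·L)^{-1} y with L the twist-chain Laplacian."""
    if n == 1:
        out[0] = y[0]
        return
    diag = scr[0]
    for i in range(n):
        deg = 2.0 if 0 < i < n - 1 else 1.0
        diag[i] = 1.0 + lam * deg
    cp = scr[1]
    dp = scr[2]
    cp[0] = -lam / diag[0]
    dp[0] = y[0] / diag[0]
    for i in range(1, n):
        m = diag[i] + lam * cp[i - 1]
        cp[i] = -lam / m
        dp[i] = (y[i] + lam * dp[i - 1]) / m
    out[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        out[i] = dp[i] - cp[i] * out[i + 1]


@njit(cache=True, fastmath=True)
def _stretch_solve(pos_f, n, rhs, tpar, tperp, c, kout, stscr, stscr3):
    """Stiff-stretch stage solve of the Rosenbrock-W integrator.

    Computes kout = (I - c·M_local·J_stretch)^{-1} rhs with J approximated
    by its bond-direction dyadic.  Projecting onto bond directions reduces
    the 3(n-1)-dimensional block system to a scalar tridiagonal problem in
    the bond strain rates.  Row 0 of ``rhs`` is the prescribed velocity of
    the body-rigid first bead; rows 1..n-1 of ``kout`` receive the solution.
    """
    nbonds = n - 1
    e = stscr3[0]
    for j in range(nbonds):
        ex = pos_f[j + 1, 0] - pos_f[j, 0]
        ey = pos_f[j + 1, 1] - pos_f[j, 1]
        ez = pos_f[j + 1, 2] - pos_f[j, 2]
        ln = np.sqrt(ex * ex + ey * ey + ez * ez)
        e[j, 0] = ex / ln
        e[j, 1] = ey / ln
        e[j, 2] = ez / ln
    tang_f = stscr3[1]
    for i in range(n):
        j0 = i - 1 if i > 0 else 0
        j1 = i if i < nbonds else nbonds - 1
        tx = e[j0, 0] + e[j1, 0]
        ty = e[j0, 1] + e[j1, 1]
        tz = e[j0, 2] + e[j1, 2]
        ln = np.sqrt(tx * tx + ty * ty + tz * tz)
        tang_f[i, 0] = tx / ln
        tang_f[i, 1] = ty / ln
        tang_f[i, 2] = tz / ln
    # mobility along a direction u for bead i: tperp + (tpar-tperp)(t.u)^2
    # (local anisotropic drag, mobility form)
    # precompute the scalars needed by the tridiagonal system
    # a_j = e_j^T M_{j+1} e_j (+ e_j^T M_j e_j for j>0; bead0 is rigid)
    diag = stscr[0]
    up = stscr[1]     # coefficient of s_{j+1}
    lo = stscr[2]     # coefficient of s_{j-1}
    b = stscr[3]
    r = rhs

    for j in range(nbonds):
        # e_j^T M_i e_m terms; M_i built from bead tangent tang_f[i]
        a_sum = 0.0
        # bead j+1 (always free)
        td = (tang_f[j + 1, 0] * e[j, 0] + tang_f[j + 1, 1] * e[j, 1]
              + tang_f[j + 1, 2] * e[j, 2])
        a_sum += tperp + (tpar - tperp) * td * td
        if j > 0:
            td2 = (tang_f[j, 0] * e[j, 0] + tang_f[j, 1] * e[j, 1]
                   + tang_f[j, 2] * e[j, 2])
            a_sum += tperp + (tpar - tperp) * td2 * td2
        diag[j] = 1.0 + c * a_sum
        if j < nbonds - 1:
            # -c e_j^T M_{j+1} e_{j+1}
            ee = (e[j, 0] * e[j + 1, 0] + e[j, 1] * e[j + 1, 1]
                  + e[j, 2] * e[j + 1, 2])
            tdj = (tang_f[j + 1, 0] * e[j, 0] + tang_f[j + 1, 1] * e[j, 1]
                   + tang_f[j + 1, 2] * e[j, 2])
            tdj1 = (tang_f[j + 1, 0] * e[j + 1, 0]
                    + tang_f[j + 1, 1] * e[j + 1, 1]
                    + tang_f[j + 1, 2] * e[j + 1, 2])
            up[j] = -c * (tperp * ee + (tpar - tperp) * tdj * tdj1)
        else:
            up[j] = 0.0
        if j > 0:
            ee = (e[j, 0] * e[j - 1, 0] + e[j, 1] * e[j - 1, 1]
                  + e[j, 2] * e[j - 1, 2])
            tdj = (tang_f[j, 0] * e[j, 0] + tang_f[j, 1] * e[j, 1]
                   + tang_f[j, 2] * e[j, 2])
            tdj1 = (tang_f[j, 0] * e[j - 1, 0] + tang_f[j, 1] * e[j - 1, 1]
                    + tang_f[j, 2] * e[j - 1, 2])
            lo[j] = -c * (tperp * ee + (tpar - tperp) * tdj * tdj1)
        else:
            lo[j] = 0.0
        b[j] = (e[j, 0] * (r[j + 1, 0] - r[j, 0])
                + e[j, 1] * (r[j + 1, 1] - r[j, 1])
                + e[j, 2] * (r[j + 1, 2] - r[j, 2]))
    # Thomas solve
    s = stscr[4]
    cp = stscr[5]
    cp[0] = up[0] / diag[0]
    s[0] = b[0] / diag[0]
    for j in range(1, nbonds):
        m = diag[j] - lo[j] * cp[j - 1]
        cp[j] = up[j] / m
        s[j] = (b[j] - lo[j] * s[j - 1]) / m
    for j in range(nbonds - 2, -1, -1):
        s[j] = s[j] - cp[j] * s[j + 1]
    # kout_i = r_i + c M_i (e_i s_i - e_{i-1} s_{i-1})
    for i in range(1, n):
        gx = 0.0
        gy = 0.0
        gz = 0.0
        if i <= nbonds - 1:  # outer bond exists
            gx += e[i, 0] * s[i]
            gy += e[i, 1] * s[i]
            gz += e[i, 2] * s[i]
        gx -= e[i - 1, 0] * s[i - 1]
        gy -= e[i - 1, 1] * s[i - 1]
        gz -= e[i - 1, 2] * s[i - 1]
        td = (tang_f[i, 0] * gx + tang_f[i, 1] * gy + tang_f[i, 2] * gz)
        mx = tperp * gx + (tpar - tperp) * td * tang_f[i, 0]
        my = tperp * gy + (tpar - tperp) * td * tang_f[i, 1]
        mz = tperp * gz + (tpar - tperp) * td * tang_f[i, 2]
        kout[i, 0] = r[i, 0] + c * mx
        kout[i, 1] = r[i, 1] + c * my
        kout[i, 2] = r[i, 2] + c * mz


@njit(cache=True, fastmath=True)
def _set_anchored_beads(X, q, pos, nb, anchors, par):
    R = np.empty((3, 3))
    _quat_matrix(q, R)
    a_lab = np.empty(3)
    for f in range(2):
        _rotate(R, anchors[f], a_lab)
        for d in range(3):
            pos[f, 0, d] = X[d] + par[P_ADIST] * a_lab[d]


@njit(cache=True, fastmath=True)
def run_steps(X, q, pos, theta, nb, anchors, adirs, obar, mbar, c0cl, Tm,
              mvec, B, par, nsteps, mob_every, coupling, step0):
    """Advance the state by ``nsteps`` RK2 steps in place.

    Returns STATUS_OK, or an error status on bond-strain blow-up or
    non-finite state (time-step instability).
    """
    nmax = pos.shape[1]
    K = 1 + (nb[0] - 1) + (nb[1] - 1)
    centers = np.empty((K, 3))
    radii = np.empty(K)
    tangents = np.zeros((K, 3))
    is_bead = np.empty(K, dtype=np.int64)
    chain_id = np.empty(K, dtype=np.int64)
    chain_pos = np.empty(K, dtype=np.int64)
    idx = 1
    chain_id[0] = -1
    chain_pos[0] = 0
    for f in range(2):
        for i in range(1, nb[f]):
            chain_id[idx] = f
            chain_pos[idx] = i
            idx += 1
    M = np.zeros((3 * K, 3 * K))
    pairs = np.empty((MAX_PAIRS, 2), dtype=np.int64)
    npairs = 0
    F = np.zeros(3 * K)
    tau = np.zeros(3)
    Tth = np.zeros((2, nmax - 1))
    Ftmp = np.zeros((nmax, 3))
    Xm = np.empty(3)
    qm = np.empty(4)
    posm = pos.copy()
    thetam = theta.copy()
    omega = np.empty(3)
    d0 = np.empty(3)
    delta = np.empty((nmax, 3))
    nbm = nmax - 1
    scr_l = np.empty(nbm)
    scr_t = np.empty((nbm, 3))
    scr_u = np.empty((nbm, 3))
    scr_tb = np.empty((nbm, 3))
    scr_lb = np.empty(nbm)
    scr_ub = np.empty((nbm, 3))
    scr_thb = np.empty(nbm)
    cnscr = np.empty((3, nbm))
    stscr = np.empty((6, nbm))
    stscr3 = np.empty((3, nmax, 3))
    dt = par[P_DT]
    gr = par[P_GR]
    ktl = par[P_KTWIST] / par[P_ELL0]
    kstr = par[P_KS] / par[P_ELL0]
    tpar = 1.0 / par[P_GPARL]
    tperp = 1.0 / par[P_GPERPL]

    gam = 1.7071067811865475  # Rosenbrock-W parameter, L-stable
    lam = gam * dt * ktl / gr
    cstr = gam * dt * kstr
    V1b = np.empty(3)
    omega1 = np.empty(3)
    d0r1 = np.empty((2, 3))
    b0old = np.empty((2, 3))
    k1pos = np.empty((2, nmax, 3))
    k1th = np.empty((2, nbm))
    k2th = np.empty(nbm)
    rhs = np.empty((nmax, 3))
    rhs_th = np.empty(nbm)
    pos_snap = np.empty((2, nmax, 3))
    for step in range(nsteps):
        if (step0 + step) % mob_every == 0:
            _fill_particles(X, q, pos, nb, par, centers, radii, tangents,
                            is_bead)
            _build_mobility(centers, radii, tangents, is_bead, par, coupling,
                            M)
            npairs = _build_pairs(centers, is_bead, chain_id, chain_pos, par,
                                  pairs)
        # ---------------- stage 1 at the current state
        _fill_centers_only(X, pos, nb, centers)
        st = _eval_forces(X, q, pos, theta, nb, anchors, adirs, obar, mbar,
                          c0cl, Tm, mvec, B, par, centers, is_bead, pairs,
                          npairs, F, tau, Tth, Ftmp, scr_l, scr_t, scr_u,
                          scr_tb, scr_lb, scr_ub, scr_thb)
        if st != 0:
            return STATUS_NONFINITE
        V = M @ F
        for d in range(3):
            V1b[d] = V[d]
            omega1[d] = tau[d] / par[P_GBR]
        # body predictor (full step with stage-1 rates)
        for d in range(3):
            Xm[d] = X[d] + dt * V1b[d]
        _quat_rotate_update(q, omega1, dt, qm)
        _set_anchored_beads(Xm, qm, posm, nb, anchors, par)
        off = 0
        for f in range(2):
            n = nb[f]
            for i in range(n):
                for d in range(3):
                    pos_snap[f, i, d] = pos[f, i, d]
            # instantaneous rigid-body velocity of the anchored bead
            rx = pos[f, 0, 0] - X[0]
            ry = pos[f, 0, 1] - X[1]
            rz = pos[f, 0, 2] - X[2]
            d0r1[f, 0] = V1b[0] + omega1[1] * rz - omega1[2] * ry
            d0r1[f, 1] = V1b[1] + omega1[2] * rx - omega1[0] * rz
            d0r1[f, 2] = V1b[2] + omega1[0] * ry - omega1[1] * rx
            for d in range(3):
                rhs[0, d] = d0r1[f, d]
            for i in range(1, n):
                for d in range(3):
                    rhs[i, d] = V[3 * (1 + off + i - 1) + d]
            _stretch_solve(pos[f, :n], n, rhs, tpar, tperp, cstr,
                           k1pos[f], stscr, stscr3)
            for i in range(1, n):
                for d in range(3):
                    posm[f, i, d] = pos[f, i, d] + dt * k1pos[f, i, d]
            nbt = n - 1
            for j in range(nbt):
                rhs_th[j] = Tth[f, j] / gr
            _twist_solve(rhs_th, nbt, lam, k1th[f], cnscr)
            for j in range(nbt):
                thetam[f, j] = theta[f, j] + dt * k1th[f, j]
            off += n - 1
        # ---------------- stage 2 at the predictor state
        _fill_centers_only(Xm, posm, nb, centers)
        st = _eval_forces(Xm, qm, posm, thetam, nb, anchors, adirs, obar,
                          mbar, c0cl, Tm, mvec, B, par, centers, is_bead,
                          pairs, npairs, F, tau, Tth, Ftmp, scr_l, scr_t,
                          scr_u, scr_tb, scr_lb, scr_ub, scr_thb)
        if st != 0:
            return STATUS_NONFINITE
        V = M @ F
        for d in range(3):
            omega[d] = 0.5 * (omega1[d] + tau[d] / par[P_GBR])
        off = 0
        for f in range(2):
            n = nb[f]
            # stage-2 rigid rate of the anchored bead at the predictor pose
            rx = posm[f, 0, 0] - Xm[0]
            ry = posm[f, 0, 1] - Xm[1]
            rz = posm[f, 0, 2] - Xm[2]
            w2x = tau[0] / par[P_GBR]
            w2y = tau[1] / par[P_GBR]
            w2z = tau[2] / par[P_GBR]
            rhs[0, 0] = V[0] + w2y * rz - w2z * ry - 2.0 * d0r1[f, 0]
            rhs[0, 1] = V[1] + w2z * rx - w2x * rz - 2.0 * d0r1[f, 1]
            rhs[0, 2] = V[2] + w2x * ry - w2y * rx - 2.0 * d0r1[f, 2]
            for i in range(1, n):
                for d in range(3):
                    rhs[i, d] = V[3 * (1 + off + i - 1) + d] \
                        - 2.0 * k1pos[f, i, d]
            _stretch_solve(pos_snap[f, :n], n, rhs, tpar, tperp, cstr,
                           delta, stscr, stscr3)
            for i in range(1, n):
                for d in range(3):
                    pos[f, i, d] = pos[f, i, d] + 0.5 * dt * (
                        3.0 * k1pos[f, i, d] + delta[i, d])
            nbt = n - 1
            for j in range(nbt):
                rhs_th[j] = Tth[f, j] / gr - 2.0 * k1th[f, j]
            _twist_solve(rhs_th, nbt, lam, k2th, cnscr)
            for j in range(nbt):
                theta[f, j] = theta[f, j] + 0.5 * dt * (
                    3.0 * k1th[f, j] + k2th[j])
            off += n - 1
        for d in range(3):
            X[d] = X[d] + 0.5 * dt * (V1b[d] + V[d])
        _quat_rotate_update(q, omega, dt, qm)
        for i in range(4):
            q[i] = qm[i]
        _set_anchored_beads(X, q, pos, nb, anchors, par)
        # ---------------- sanity checks (cheap, every 200 steps)
        if step % 200 == 199:
            if not np.isfinite(X[0] + X[1] + X[2]):
                return STATUS_NONFINITE
            for f in range(2):
                for j in range(nb[f] - 1):
                    lx = pos[f, j + 1, 0] - pos[f, j, 0]
                    ly = pos[f, j + 1, 1] - pos[f, j, 1]
                    lz = pos[f, j + 1, 2] - pos[f, j, 2]
                    l = np.sqrt(lx * lx + ly * ly + lz * lz)
                    if not np.isfinite(l):
                        return STATUS_NONFINITE
                    if abs(l / par[P_ELL0] - 1.0) > 0.10:
                        return STATUS_STRAIN
    return STATUS_OK


@njit(cache=True, fastmath=True)
def _fill_centers_only(X, pos, nb, centers):
    centers[0, 0] = X[0]
    centers[0, 1] = X[1]
    centers[0, 2] = X[2]
    idx = 1
    for f in range(2):
        for i in range(1, nb[f]):
            for d in range(3):
                centers[idx, d] = pos[f, i, d]
            idx += 1
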
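"""Discrete elastic-rod energetics of a helical filament.

Each filament is a bead chain with stretching, bending and twisting
elasticity.  Reference directors are constructed by space-parallel transport
from the body anchor frame along the chain, so the material twist is carried
entirely by one angle per bond.  The intrinsic (stress-free) shape is a
helix, encoded by a constant discrete curvature magnitude in the material
frame and a constant twist increment per vertex; winding the base angle
cranks the preferred shape around the base tangent, which is how motor
torque becomes thrust.

Forces are exact analytic gradients of the scalar energy, obtained by
reverse-mode differentiation of the forward construction (including the
position dependence of the transported frames).  The inner loops are written
allocation-free for the integration kernel; the gradient is validated
against central differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["flagellum_forces", "flagellum_energy", "twist_matvec"]


@njit(cache=True, fastmath=True)
def _forward(pos, a_lab, d1a, l, t, u):
    """Bond lengths/tangents and transported reference directors (in place)."""
    nb = pos.shape[0] - 1
    for j in range(nb):
        ex = pos[j + 1, 0] - pos[j, 0]
        ey = pos[j + 1, 1] - pos[j, 1]
        ez = pos[j + 1, 2] - pos[j, 2]
        lj = np.sqrt(ex * ex + ey * ey + ez * ez)
        l[j] = lj
        t[j, 0] = ex / lj
        t[j, 1] = ey / lj
        t[j, 2] = ez / lj
    px, py, pz = a_lab[0], a_lab[1], a_lab[2]
    xx, xy, xz = d1a[0], d1a[1], d1a[2]
    for j in range(nb):
        vx, vy, vz = t[j, 0], t[j, 1], t[j, 2]
        c = px * vx + py * vy + pz * vz
        rx = py * vz - pz * vy
        ry = pz * vx - px * vz
        rz = px * vy - py * vx
        k = 1.0 / (1.0 + c)
        s = rx * xx + ry * xy + rz * xz
        ux = c * xx + (ry * xz - rz * xy) + k * s * rx
        uy = c * xy + (rz * xx - rx * xz) + k * s * ry
        uz = c * xz + (rx * xy - ry * xx) + k * s * rz
        u[j, 0] = ux
        u[j, 1] = uy
        u[j, 2] = uz
        px, py, pz = vx, vy, vz
        xx, xy, xz = ux, uy, uz


@njit(cache=True, fastmath=True)
def flagellum_forces(pos, theta, a_lab, d1a, ell0, ks, kbend, ktwist,
                     omega_bar, m_bar, c0_clamp, k_hook, F, Tth, abar, dbar,
                     l, t, u, tbar, lbar, ubar, thbar):
    """Elastic energy and exact negative gradients for one filament.

    ``F`` (bead forces, pN) and ``Tth`` (axial torques conjugate to the bond
    twist angles, pN·µm) are accumulated; ``abar``/``dbar`` receive energy
    gradients with respect to the anchor axis and director (the caller forms
    the body reaction torque from them).  The trailing arguments are caller-
    provided scratch arrays.  Returns the scalar energy.
    """
    n = pos.shape[0]
    nb = n - 1
    _forward(pos, a_lab, d1a, l, t, u)
    for j in range(nb):
        tbar[j, 0] = 0.0
        tbar[j, 1] = 0.0
        tbar[j, 2] = 0.0
        ubar[j, 0] = 0.0
        ubar[j, 1] = 0.0
        ubar[j, 2] = 0.0
        lbar[j] = 0.0
        thbar[j] = 0.0

    E = 0.0
    # ---- stretching
    for j in range(nb):
        dl = l[j] - ell0
        E += 0.5 * ks / ell0 * dl * dl
        lbar[j] += ks / ell0 * dl

    # ---- hook clamp at the base: cone clamp on the angle between the first
    # bond tangent and the anchor axis (axisymmetric, so the motor degree of
    # freedom spins freely); c0_clamp = cos of the preferred angle, set at
    # build time from the rest helix plus any tilt offset.
    ax, ay, az = a_lab[0], a_lab[1], a_lab[2]
    t0x, t0y, t0z = t[0, 0], t[0, 1], t[0, 2]
    cc = ax * t0x + ay * t0y + az * t0z
    dcc = cc - c0_clamp
    E += 0.5 * k_hook * dcc * dcc
    gcl = k_hook * dcc
    abar[0] += gcl * t0x
    abar[1] += gcl * t0y
    abar[2] += gcl * t0z
    tbar[0, 0] += gcl * ax
    tbar[0, 1] += gcl * ay
    tbar[0, 2] += gcl * az

    # ---- interior vertices
    for i in range(1, nb):
        j = i - 1  # inboard bond frame
        ct = np.cos(theta[j])
        st = np.sin(theta[j])
        tjx, tjy, tjz = t[j, 0], t[j, 1], t[j, 2]
        ujx, ujy, ujz = u[j, 0], u[j, 1], u[j, 2]
        wx = tjy * ujz - tjz * ujy
        wy = tjz * ujx - tjx * ujz
        wz = tjx * ujy - tjy * ujx
        m1x = ct * ujx + st * wx
        m1y = ct * ujy + st * wy
        m1z = ct * ujz + st * wz
        m2x = ct * wx - st * ujx
        m2y = ct * wy - st * ujy
        m2z = ct * wz - st * ujz
        tix, tiy, tiz = t[i, 0], t[i, 1], t[i, 2]
        c = tjx * tix + tjy * tiy + tjz * tiz
        sc = 2.0 / (1.0 + c)
        kbx = sc * (tjy * tiz - tjz * tiy)
        kby = sc * (tjz * tix - tjx * tiz)
        kbz = sc * (tjx * tiy - tjy * tix)
        w1 = kbx * m2x + kby * m2y + kbz * m2z
        w2 = -(kbx * m1x + kby * m1y + kbz * m1z)
        dw1 = w1 - omega_bar
        dw2 = w2
        E += 0.5 * kbend / ell0 * (dw1 * dw1 + dw2 * dw2)
        g1 = kbend / ell0 * dw1
        g2 = kbend / ell0 * dw2
        # twist
        mt = theta[i] - theta[i - 1]
        dmt = mt - m_bar
        E += 0.5 * ktwist / ell0 * dmt * dmt
        gt = ktwist / ell0 * dmt
        thbar[i] += gt
        thbar[i - 1] -= gt
        # adjoints of kb, m1, m2
        kbbx = g1 * m2x - g2 * m1x
        kbby = g1 * m2y - g2 * m1y
        kbbz = g1 * m2z - g2 * m1z
        m2bx = g1 * kbx
        m2by = g1 * kby
        m2bz = g1 * kbz
        m1bx = -g2 * kbx
        m1by = -g2 * kby
        m1bz = -g2 * kbz
        # kb VJP: p = t_j, q = t_i
        gk = kbbx * kbx + kbby * kby + kbbz * kbz
        inv = 1.0 / (1.0 + c)
        tbar[j, 0] += 2.0 * inv * (tiy * kbbz - tiz * kbby) - inv * gk * tix
        tbar[j, 1] += 2.0 * inv * (tiz * kbbx - tix * kbbz) - inv * gk * tiy
        tbar[j, 2] += 2.0 * inv * (tix * kbby - tiy * kbbx) - inv * gk * tiz
        tbar[i, 0] += 2.0 * inv * (kbby * tjz - kbbz * tjy) - inv * gk * tjx
        tbar[i, 1] += 2.0 * inv * (kbbz * tjx - kbbx * tjz) - inv * gk * tjy
        tbar[i, 2] += 2.0 * inv * (kbbx * tjy - kbby * tjx) - inv * gk * tjz
        # m1 = ct u + st (t x u); m2 = ct (t x u) - st u
        # ubar += ct m1b + st (m1b x t) - st m2b + ct (m2b x t)
        ubar[j, 0] += (ct * m1bx + st * (m1by * tjz - m1bz * tjy)
                       - st * m2bx + ct * (m2by * tjz - m2bz * tjy))
        ubar[j, 1] += (ct * m1by + st * (m1bz * tjx - m1bx * tjz)
                       - st * m2by + ct * (m2bz * tjx - m2bx * tjz))
        ubar[j, 2] += (ct * m1bz + st * (m1bx * tjy - m1by * tjx)
                       - st * m2bz + ct * (m2bx * tjy - m2by * tjx))
        # tbar += st (u x m1b) + ct (u x m2b)
        tbar[j, 0] += st * (ujy * m1bz - ujz * m1by) + ct * (ujy * m2bz - ujz * m2by)
        tbar[j, 1] += st * (ujz * m1bx - ujx * m1bz) + ct * (ujz * m2bx - ujx * m2bz)
        tbar[j, 2] += st * (ujx * m1by - ujy * m1bx) + ct * (ujx * m2by - ujy * m2bx)
        thbar[j] += (m1bx * m2x + m1by * m2y + m1bz * m2z
                     - (m2bx * m1x + m2by * m1y + m2bz * m1z))

    # ---- reverse transport sweep: u_j = PT(t_{j-1} -> t_j) u_{j-1}
    for j in range(nb - 1, -1, -1):
        if j > 0:
            px, py, pz = t[j - 1, 0], t[j - 1, 1], t[j - 1, 2]
            xx, xy, xz = u[j - 1, 0], u[j - 1, 1], u[j - 1, 2]
        else:
            px, py, pz = a_lab[0], a_lab[1], a_lab[2]
            xx, xy, xz = d1a[0], d1a[1], d1a[2]
        vx, vy, vz = t[j, 0], t[j, 1], t[j, 2]
        gx = ubar[j, 0]
        gy = ubar[j, 1]
        gz = ubar[j, 2]
        rx = py * vz - pz * vy
        ry = pz * vx - px * vz
        rz = px * vy - py * vx
        c = px * vx + py * vy + pz * vz
        k = 1.0 / (1.0 + c)
        s = rx * xx + ry * xy + rz * xz
        rg = rx * gx + ry * gy + rz * gz
        # xbar += c g - r x g + k (r.g) r
        xbx = c * gx - (ry * gz - rz * gy) + k * rg * rx
        xby = c * gy - (rz * gx - rx * gz) + k * rg * ry
        xbz = c * gz - (rx * gy - ry * gx) + k * rg * rz
        cbar = (gx * xx + gy * xy + gz * xz) - k * k * s * rg
        rbx = (xy * gz - xz * gy) + k * rg * xx + k * s * gx
        rby = (xz * gx - xx * gz) + k * rg * xy + k * s * gy
        rbz = (xx * gy - xy * gx) + k * rg * xz + k * s * gz
        # ubar_prev += cbar v + v x rbar ; vbar += cbar u + rbar x u
        pbx = cbar * vx + (vy * rbz - vz * rby)
        pby = cbar * vy + (vz * rbx - vx * rbz)
        pbz = cbar * vz + (vx * rby - vy * rbx)
        vbx = cbar * px + (rby * pz - rbz * py)
        vby = cbar * py + (rbz * px - rbx * pz)
        vbz = cbar * pz + (rbx * py - rby * px)
        tbar[j, 0] += vbx
        tbar[j, 1] += vby
        tbar[j, 2] += vbz
        if j > 0:
            tbar[j - 1, 0] += pbx
            tbar[j - 1, 1] += pby
            tbar[j - 1, 2] += pbz
            ubar[j - 1, 0] += xbx
            ubar[j - 1, 1] += xby
            ubar[j - 1, 2] += xbz
        else:
            abar[0] += pbx
            abar[1] += pby
            abar[2] += pbz
            dbar[0] += xbx
            dbar[1] += xby
            dbar[2] += xbz

    # ---- bond vectors -> bead forces
    for j in range(nb):
        tt = (tbar[j, 0] * t[j, 0] + tbar[j, 1] * t[j, 1]
              + tbar[j, 2] * t[j, 2])
        for d in range(3):
            eb = (tbar[j, d] - tt * t[j, d]) / l[j] + lbar[j] * t[j, d]
            F[j, d] += eb
            F[j + 1, d] -= eb
    for j in range(nb):
        Tth[j] -= thbar[j]
    return E


def flagellum_energy(pos, theta, a_lab, d1a, ell0, ks, kbend, ktwist,
                     omega_bar, m_bar, c0_clamp, k_hook):
    """Scalar elastic energy (gradient checks and diagnostics)."""
    n = pos.shape[0]
    nb = n - 1
    F = np.zeros((n, 3))
    Tth = np.zeros(nb)
    abar = np.zeros(3)
    dbar = np.zeros(3)
    scratch = _scratch(nb)
    return flagellum_forces(pos, theta, a_lab, d1a, ell0, ks, kbend, ktwist,
                            omega_bar, m_bar, c0_clamp, k_hook, F, Tth, abar, dbar,
                            *scratch)


def _scratch(nb: int):
    """Workspace arrays (l, t, u, tbar, lbar, ubar, thbar) for one filament."""
    return (np.empty(nb), np.empty((nb, 3)), np.empty((nb, 3)),
            np.empty((nb, 3)), np.empty(nb), np.empty((nb, 3)), np.empty(nb))


@njit(cache=True, fastmath=True)
def twist_matvec(theta, ktwist, ell0, out):
    """Stiff (linear) part of dE/dθ: out = K θ with K the twist Laplacian."""
    nb = theta.shape[0]
    k = ktwist / ell0
    for j in range(nb):
        out[j] = 0.0
    for i in range(1, nb):
        d = k * (theta[i] - theta[i - 1])
        out[i] += d
        out[i - 1] -= d
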
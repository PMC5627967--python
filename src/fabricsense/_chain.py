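"""Numerical kernels for the driven fabric-link chain.

The fabric strip is a serial chain of K uniform rigid links hanging from the
pendulum tip, with torsional springs/dampers at the joints, quadratic
aerodynamic drag on each link, and optional point masses (sensor boards) at
the link end nodes.  Coupling to the pendulum is one-way: the pendulum
drives the chain root, the chain does not back-react (the experimental
control for this — identical rigid-tip signals with and without fabric — is
enforced by construction).  Within the chain the links are fully coupled
through the serial-chain mass matrix.

All angles are absolute, measured from the hanging-down vertical, positive
counter-clockwise, in a plane with x horizontal and y up.  The equations of
motion in absolute angles are M(phi) phi'' = Q(phi, phi', t) with

    M_ab = l^2 mu_ab cos(phi_a - phi_b)
    mu_ab = m/2 + ms_b + sum_{i>b} (m + ms_i)          (a < b)
    mu_aa = m/3 + ms_a + sum_{i>a} (m + ms_i)

(m link mass, ms_i node point mass) and Q collecting centrifugal coupling,
gravity plus the base pseudo-force, joint spring/damper torques and drag.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["chain_accelerations", "integrate_chain", "chain_node_readings"]


@njit(cache=True)
def chain_accelerations(phi, dphi, theta, dtheta,
                        bvx, bvy, bax, bay,
                        kappa, cj, seg_mass, seg_len, drag, node_mass, g,
                        out_acc, out_nax, out_nay):
    """Angular accelerations of all K links plus link end-node accelerations.

    ``b??`` are velocity/acceleration of the chain root (pendulum tip);
    ``theta``/``dtheta`` the pendulum angle state referenced by the root
    joint spring.  Gravity ``g`` is the dynamical value.
    """
    K = phi.shape[0]
    l = seg_len
    m = seg_mass

    sin_p = np.empty(K)
    cos_p = np.empty(K)
    for i in range(K):
        sin_p[i] = math.sin(phi[i])
        cos_p[i] = math.cos(phi[i])

    # mass-coefficient table: tail_i = total mass strictly beyond link i
    tail = np.empty(K + 1)
    tail[K] = 0.0
    for i in range(K - 1, -1, -1):
        tail[i] = tail[i + 1] + m + node_mass[i]

    M = np.empty((K, K))
    Q = np.zeros(K)
    for a in range(K):
        for b in range(K):
            if a == b:
                mu = m / 3.0 + node_mass[a] + tail[a + 1]
            else:
                hi = b if b > a else a
                mu = m / 2.0 + node_mass[hi] + tail[hi + 1]
            c_ab = cos_p[a] * cos_p[b] + sin_p[a] * sin_p[b]
            M[a, b] = l * l * mu * c_ab
            # centrifugal coupling: +sin(phi_a - phi_b) * dphi_b^2
            s_ab = sin_p[a] * cos_p[b] - cos_p[a] * sin_p[b]
            Q[a] -= l * l * mu * s_ab * dphi[b] * dphi[b]

    # gravity + base pseudo-force; W_a = first mass moment at/beyond link a
    for a in range(K):
        W = m / 2.0 + node_mass[a] + tail[a + 1]
        Q[a] += l * W * (-bax * cos_p[a] - (g + bay) * sin_p[a])

    # joint springs/dampers (root joint references the pendulum angle)
    for a in range(K):
        prev = theta if a == 0 else phi[a - 1]
        prevd = dtheta if a == 0 else dphi[a - 1]
        tau = -kappa * (phi[a] - prev) - cj * (dphi[a] - prevd)
        Q[a] += tau
        if a > 0:
            Q[a - 1] -= tau

    # quadratic drag at each link centre, projected on all inboard joints
    vx, vy = bvx, bvy
    for a in range(K):
        vtx = vx + 0.5 * l * dphi[a] * cos_p[a]
        vty = vy + 0.5 * l * dphi[a] * sin_p[a]
        vtan = vtx * cos_p[a] + vty * sin_p[a]
        fmag = -drag * abs(vtan) * vtan  # along t_a
        for b in range(a + 1):
            lever = 0.5 * l if b == a else l
            c_ab = cos_p[a] * cos_p[b] + sin_p[a] * sin_p[b]
            Q[b] += lever * fmag * c_ab
        vx += l * dphi[a] * cos_p[a]
        vy += l * dphi[a] * sin_p[a]

    acc = np.linalg.solve(M, Q)
    ax, ay = bax, bay
    for i in range(K):
        out_acc[i] = acc[i]
        w2 = dphi[i] * dphi[i]
        ax += l * (acc[i] * cos_p[i] - w2 * sin_p[i])
        ay += l * (acc[i] * sin_p[i] + w2 * cos_p[i])
        out_nax[i] = ax
        out_nay[i] = ay


@njit(cache=True)
def _drive(theta, dtheta, ddtheta, L):
    """Pendulum-tip kinematics (vx, vy, ax, ay) from its angular state."""
    s = math.sin(theta)
    c = math.cos(theta)
    vx = L * dtheta * c
    vy = L * dtheta * s
    ax = L * (ddtheta * c - dtheta * dtheta * s)
    ay = L * (ddtheta * s + dtheta * dtheta * c)
    return vx, vy, ax, ay


@njit(cache=True)
def integrate_chain(phi0, theta_g, dtheta_g, ddtheta_g, L,
                    kappa, cj, seg_mass, seg_len, drag, node_mass, g,
                    K, dt, n_steps, rec_stride, phi_rec, dphi_rec):
    """Fixed-step classical RK4 of the driven chain from rest shape ``phi0``.

    ``theta_g``/``dtheta_g``/``ddtheta_g`` hold the pendulum state on the
    *stage grid* (spacing dt/2, length 2*n_steps+1) so no interpolation is
    needed at Runge–Kutta stage times.  Every ``rec_stride`` steps the state
    is written to ``phi_rec``/``dphi_rec`` (shape (n_rec, K)).
    """
    phi = phi0.copy()
    dphi = np.zeros(K)
    k_acc = np.empty(K)
    nax = np.empty(K)
    nay = np.empty(K)
    p1 = np.empty(K); p2 = np.empty(K); p3 = np.empty(K); p4 = np.empty(K)
    v1 = np.empty(K); v2 = np.empty(K); v3 = np.empty(K); v4 = np.empty(K)
    tmp_p = np.empty(K); tmp_v = np.empty(K)

    rec = 0
    phi_rec[rec, :] = phi
    dphi_rec[rec, :] = dphi
    for step in range(n_steps):
        i0 = 2 * step
        vx, vy, ax, ay = _drive(theta_g[i0], dtheta_g[i0], ddtheta_g[i0], L)
        chain_accelerations(phi, dphi, theta_g[i0], dtheta_g[i0],
                            vx, vy, ax, ay, kappa, cj, seg_mass, seg_len,
                            drag, node_mass, g, k_acc, nax, nay)
        for j in range(K):
            p1[j] = dphi[j]
            v1[j] = k_acc[j]
        i1 = i0 + 1
        vx, vy, ax, ay = _drive(theta_g[i1], dtheta_g[i1], ddtheta_g[i1], L)
        for j in range(K):
            tmp_p[j] = phi[j] + 0.5 * dt * p1[j]
            tmp_v[j] = dphi[j] + 0.5 * dt * v1[j]
        chain_accelerations(tmp_p, tmp_v, theta_g[i1], dtheta_g[i1],
                            vx, vy, ax, ay, kappa, cj, seg_mass, seg_len,
                            drag, node_mass, g, k_acc, nax, nay)
        for j in range(K):
            p2[j] = tmp_v[j]
            v2[j] = k_acc[j]
        for j in range(K):
            tmp_p[j] = phi[j] + 0.5 * dt * p2[j]
            tmp_v[j] = dphi[j] + 0.5 * dt * v2[j]
        chain_accelerations(tmp_p, tmp_v, theta_g[i1], dtheta_g[i1],
                            vx, vy, ax, ay, kappa, cj, seg_mass, seg_len,
                            drag, node_mass, g, k_acc, nax, nay)
        for j in range(K):
            p3[j] = tmp_v[j]
            v3[j] = k_acc[j]
        i2 = i0 + 2
        vx, vy, ax, ay = _drive(theta_g[i2], dtheta_g[i2], ddtheta_g[i2], L)
        for j in range(K):
            tmp_p[j] = phi[j] + dt * p3[j]
            tmp_v[j] = dphi[j] + dt * v3[j]
        chain_accelerations(tmp_p, tmp_v, theta_g[i2], dtheta_g[i2],
                            vx, vy, ax, ay, kappa, cj, seg_mass, seg_len,
                            drag, node_mass, g, k_acc, nax, nay)
        for j in range(K):
            p4[j] = tmp_v[j]
            v4[j] = k_acc[j]
        sixth = dt / 6.0
        for j in range(K):
            phi[j] += sixth * (p1[j] + 2.0 * p2[j] + 2.0 * p3[j] + p4[j])
            dphi[j] += sixth * (v1[j] + 2.0 * v2[j] + 2.0 * v3[j] + v4[j])
        if (step + 1) % rec_stride == 0:
            rec += 1
            phi_rec[rec, :] = phi
            dphi_rec[rec, :] = dphi


@njit(cache=True)
def chain_node_readings(phi_rec, dphi_rec, theta_s, dtheta_s, ddtheta_s, L,
                        kappa, cj, seg_mass, seg_len, drag, node_mass, g,
                        g_unit, out):
    """Noise-free accelerometer readings at every chain node.

    ``out`` has shape (n_samples, K): entry (t, j) is the specific force at
    node j+1, projected on the tangential axis of link j, in units of
    ``g_unit`` (standard gravity).
    """
    T, K = phi_rec.shape
    acc = np.empty(K)
    nax = np.empty(K)
    nay = np.empty(K)
    for t in range(T):
        vx, vy, ax, ay = _drive(theta_s[t], dtheta_s[t], ddtheta_s[t], L)
        chain_accelerations(phi_rec[t], dphi_rec[t], theta_s[t], dtheta_s[t],
                            vx, vy, ax, ay, kappa, cj, seg_mass, seg_len,
                            drag, node_mass, g, acc, nax, nay)
        for j in range(K):
            s = math.sin(phi_rec[t, j])
            c = math.cos(phi_rec[t, j])
            # specific force = point acceleration minus gravity vector
            out[t, j] = (nax[j] * c + (nay[j] + g) * s) / g_unit
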
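"""Numba-compiled inner loops: fixed-step RK4 integration and the DFD table.

The double-pendulum dynamics are reduced to three inertial constants

    a = I1 + m1*c1**2 + I2 + m2*(l1**2 + c2**2)
    b = m2*l1*c2
    d = I2 + m2*c2**2

so that, with q2 the relative elbow angle,

    M(q2) = [[a + 2b cos q2, d + b cos q2],
             [d + b cos q2,  d          ]]

and the Coriolis/centripetal generalized force is
C(q, qdot) qdot = (-b sin q2 (2 q1' q2' + q2'^2),  b sin q2 q1'^2).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def _pend_accel(a, b, d, q2, qd1, qd2, tau1, tau2):
    """Joint accelerations of M qdd + C qd = tau."""
    c2 = math.cos(q2)
    s2 = math.sin(q2)
    m11 = a + 2.0 * b * c2
    m12 = d + b * c2
    m22 = d
    # generalized Coriolis forces
    h1 = -b * s2 * (2.0 * qd1 * qd2 + qd2 * qd2)
    h2 = b * s2 * qd1 * qd1
    r1 = tau1 - h1
    r2 = tau2 - h2
    det = m11 * m22 - m12 * m12
    qdd1 = (m22 * r1 - m12 * r2) / det
    qdd2 = (m11 * r2 - m12 * r1) / det
    return qdd1, qdd2


@njit(cache=False)
def _unforced_rhs(a, b, d, y):
    out = np.empty(4)
    qdd1, qdd2 = _pend_accel(a, b, d, y[1], y[2], y[3], 0.0, 0.0)
    out[0] = y[2]
    out[1] = y[3]
    out[2] = qdd1
    out[3] = qdd2
    return out


@njit(cache=False)
def simulate_unforced_rk4(a, b, d, q1, q2, qd1, qd2, dt, n_steps):
    """Fixed-step RK4 flow of the unforced pendulum; returns (n_steps+1, 4)."""
    out = np.empty((n_steps + 1, 4))
    y = np.array([q1, q2, qd1, qd2])
    out[0] = y
    for i in range(n_steps):
        k1 = _unforced_rhs(a, b, d, y)
        k2 = _unforced_rhs(a, b, d, y + 0.5 * dt * k1)
        k3 = _unforced_rhs(a, b, d, y + 0.5 * dt * k2)
        k4 = _unforced_rhs(a, b, d, y + dt * (k3))
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[i + 1] = y
    return out


@njit(cache=False)
def _endpoint(l1, l2, bx, by, q1, q2):
    c1 = math.cos(q1)
    s1 = math.sin(q1)
    c12 = math.cos(q1 + q2)
    s12 = math.sin(q1 + q2)
    ex = bx + l1 * c1 + l2 * c12
    ey = by + l1 * s1 + l2 * s12
    return ex, ey


@njit(cache=False)
def _pend_coupled_rhs(a, b, d, l1, l2, bx, by, K, B, hx, hy, hvx, hvy, y):
    """State derivative of the pendulum driven through the spring-damper.

    y = (q1, q2, qd1, qd2); the hand is at (hx, hy) with velocity (hvx, hvy).
    """
    q1 = y[0]
    q2 = y[1]
    qd1 = y[2]
    qd2 = y[3]
    c1 = math.cos(q1)
    s1 = math.sin(q1)
    c12 = math.cos(q1 + q2)
    s12 = math.sin(q1 + q2)
    ex = bx + l1 * c1 + l2 * c12
    ey = by + l1 * s1 + l2 * s12
    # Jacobian of the endpoint
    j11 = -l1 * s1 - l2 * s12
    j12 = -l2 * s12
    j21 = l1 * c1 + l2 * c12
    j22 = l2 * c12
    evx = j11 * qd1 + j12 * qd2
    evy = j21 * qd1 + j22 * qd2
    fx = K * (hx - ex) + B * (hvx - evx)
    fy = K * (hy - ey) + B * (hvy - evy)
    tau1 = j11 * fx + j21 * fy
    tau2 = j12 * fx + j22 * fy
    qdd1, qdd2 = _pend_accel(a, b, d, q2, qd1, qd2, tau1, tau2)
    out = np.empty(4)
    out[0] = qd1
    out[1] = qd2
    out[2] = qdd1
    out[3] = qdd2
    return out


@njit(cache=False)
def simulate_pendulum_coupled(
    a, b, d, l1, l2, bx, by, K, B, hand_pos, hand_vel, y0, dt
):
    """RK4 integration of the coupled pendulum along a sampled hand trajectory.

    hand_pos / hand_vel are (N, 2) at step size dt; hand states at RK4
    half-steps are linearly interpolated.  Returns (states (N, 4),
    endpoint (N, 2), endpoint velocity (N, 2), coupling force (N, 2)).
    """
    n = hand_pos.shape[0]
    states = np.empty((n, 4))
    epos = np.empty((n, 2))
    evel = np.empty((n, 2))
    force = np.empty((n, 2))
    y = y0.copy()
    for i in range(n):
        states[i] = y
        q1 = y[0]
        q2 = y[1]
        qd1 = y[2]
        qd2 = y[3]
        c1 = math.cos(q1)
        s1 = math.sin(q1)
        c12 = math.cos(q1 + q2)
        s12 = math.sin(q1 + q2)
        ex = bx + l1 * c1 + l2 * c12
        ey = by + l1 * s1 + l2 * s12
        j11 = -l1 * s1 - l2 * s12
        j12 = -l2 * s12
        j21 = l1 * c1 + l2 * c12
        j22 = l2 * c12
        evx = j11 * qd1 + j12 * qd2
        evy = j21 * qd1 + j22 * qd2
        fx = K * (hand_pos[i, 0] - ex) + B * (hand_vel[i, 0] - evx)
        fy = K * (hand_pos[i, 1] - ey) + B * (hand_vel[i, 1] - evy)
        epos[i, 0] = ex
        epos[i, 1] = ey
        evel[i, 0] = evx
        evel[i, 1] = evy
        force[i, 0] = fx
        force[i, 1] = fy
        if i == n - 1:
            break
        # hand state at the RK4 half and full step
        hmx = 0.5 * (hand_pos[i, 0] + hand_pos[i + 1, 0])
        hmy = 0.5 * (hand_pos[i, 1] + hand_pos[i + 1, 1])
        hmvx = 0.5 * (hand_vel[i, 0] + hand_vel[i + 1, 0])
        hmvy = 0.5 * (hand_vel[i, 1] + hand_vel[i + 1, 1])
        k1 = _pend_coupled_rhs(a, b, d, l1, l2, bx, by, K, B,
                               hand_pos[i, 0], hand_pos[i, 1],
                               hand_vel[i, 0], hand_vel[i, 1], y)
        k2 = _pend_coupled_rhs(a, b, d, l1, l2, bx, by, K, B,
                               hmx, hmy, hmvx, hmvy, y + 0.5 * dt * k1)
        k3 = _pend_coupled_rhs(a, b, d, l1, l2, bx, by, K, B,
                               hmx, hmy, hmvx, hmvy, y + 0.5 * dt * k2)
        k4 = _pend_coupled_rhs(a, b, d, l1, l2, bx, by, K, B,
                               hand_pos[i + 1, 0], hand_pos[i + 1, 1],
                               hand_vel[i + 1, 0], hand_vel[i + 1, 1],
                               y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return states, epos, evel, force


@njit(cache=False)
def simulate_point_mass_coupled(m, K, B, hand_pos, hand_vel, y0, dt):
    """Same coupling law applied to a planar point mass; y = (x, y, vx, vy)."""
    n = hand_pos.shape[0]
    states = np.empty((n, 4))
    force = np.empty((n, 2))
    y = y0.copy()
    for i in range(n):
        states[i] = y
        fx = K * (hand_pos[i, 0] - y[0]) + B * (hand_vel[i, 0] - y[2])
        fy = K * (hand_pos[i, 1] - y[1]) + B * (hand_vel[i, 1] - y[3])
        force[i, 0] = fx
        force[i, 1] = fy
        if i == n - 1:
            break
        hmx = 0.5 * (hand_pos[i, 0] + hand_pos[i + 1, 0])
        hmy = 0.5 * (hand_pos[i, 1] + hand_pos[i + 1, 1])
        hmvx = 0.5 * (hand_vel[i, 0] + hand_vel[i + 1, 0])
        hmvy = 0.5 * (hand_vel[i, 1] + hand_vel[i + 1, 1])

        def rhs(py, hx, hy, hvx, hvy):
            out = np.empty(4)
            out[0] = py[2]
            out[1] = py[3]
            out[2] = (K * (hx - py[0]) + B * (hvx - py[2])) / m
            out[3] = (K * (hy - py[1]) + B * (hvy - py[3])) / m
            return out

        k1 = rhs(y, hand_pos[i, 0], hand_pos[i, 1], hand_vel[i, 0], hand_vel[i, 1])
        k2 = rhs(y + 0.5 * dt * k1, hmx, hmy, hmvx, hmvy)
        k3 = rhs(y + 0.5 * dt * k2, hmx, hmy, hmvx, hmvy)
        k4 = rhs(y + dt * k3, hand_pos[i + 1, 0], hand_pos[i + 1, 1],
                 hand_vel[i + 1, 0], hand_vel[i + 1, 1])
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return states, force


@njit(cache=False)
def dfd_table(P, Q):
    """Discrete Fréchet distance by the standard dynamic program.

    ca[i, j] = max(d(P_i, Q_j), min(ca[i-1, j], ca[i, j-1], ca[i-1, j-1])).
    """
    n = P.shape[0]
    m = Q.shape[0]
    ca = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            dx = P[i, 0] - Q[j, 0]
            dy = P[i, 1] - Q[j, 1]
            dij = math.sqrt(dx * dx + dy * dy)
            if i == 0 and j == 0:
                ca[i, j] = dij
            elif i == 0:
                ca[i, j] = max(ca[0, j - 1], dij)
            elif j == 0:
                ca[i, j] = max(ca[i - 1, 0], dij)
            else:
                prev = min(ca[i - 1, j], ca[i, j - 1], ca[i - 1, j - 1])
                ca[i, j] = max(prev, dij)
    return ca[n - 1, m - 1]
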
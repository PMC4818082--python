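"""Reference paths and trajectories for point-to-point object maneuvers.

Three references are computed between each pair of targets:

* the **straight / minimum-jerk** trajectory — the stereotypical unperturbed
  reach: a straight spatial path traversed with the quintic speed profile
  ``s(τ) = 10τ³ − 15τ⁴ + 6τ⁵``;
* the **path of least kinetic energy** — the geodesic of the kinetic-energy
  metric M(q) on the pendulum's configuration space.  Unforced motions are
  exactly these geodesics, so the path is found by solving a two-point
  boundary value problem of the unforced system with free boundary
  velocities (single shooting, multi-start);
* the **effort-optimal trajectory** — the rest-to-rest admissible trajectory
  minimizing the integral cost of the force applied to the object, found by
  direct trajectory optimization.

For an isotropic point mass the metric is Euclidean and both optimal
references collapse onto the straight segment.

The mechanical work acquired by the object over a maneuver is

    E = ∫₀ᵀ |F·v| dt

with F the force applied to the object and v the hand velocity
(:func:`path_energy`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, root

from . import _kernels
from .containers import Path, Trajectory
from .dynamics import (
    PendulumParams,
    PointMassParams,
    forward_kinematics,
    inverse_kinematics,
    jacobian,
)

__all__ = [
    "TargetLayout",
    "default_layout",
    "straight_path",
    "min_jerk_trajectory",
    "path_energy",
    "joint_path_energy",
    "geodesic_path",
    "waypoint_geodesic_path",
    "effort_optimal_trajectory",
    "GeodesicConvergenceError",
]


class GeodesicConvergenceError(RuntimeError):
    """Shooting failed to meet the boundary conditions after all restarts."""


@dataclass(frozen=True)
class TargetLayout:
    """Three planar reach targets (centers in meters, common diameter)."""

    centers: tuple[tuple[float, float], ...]
    diameter: float = 0.03

    def __post_init__(self):
        centers = tuple((float(x), float(y)) for x, y in self.centers)
        if len(centers) != len(set(centers)):
            raise ValueError("target centers must be pairwise distinct")
        if not self.diameter > 0:
            raise ValueError("target diameter must be positive")
        object.__setattr__(self, "centers", centers)

    @property
    def n_targets(self) -> int:
        return len(self.centers)

    def center(self, i: int) -> np.ndarray:
        return np.asarray(self.centers[i], dtype=float)

    def ordered_pairs(self) -> list[tuple[int, int]]:
        """All ordered (start, end) target pairs; direction matters for the BVP."""
        n = self.n_targets
        return [(i, j) for i in range(n) for j in range(n) if i != j]


def default_layout(base: tuple[float, float] = (0.0, 0.0)) -> TargetLayout:
    """Three targets on an equilateral triangle of side 0.15 m.

    The triangle is centered 0.30 m in front of the pendulum pivot with one
    vertex toward the pivot, keeping all targets well inside the reachable
    annulus (max distance ≈ 0.35 m of a 0.40 m reach) and away from the
    outstretched singularity.
    """
    side = 0.15
    r = side / np.sqrt(3.0)
    cx, cy = base[0], base[1] + 0.30
    angles = np.deg2rad([-90.0, 30.0, 150.0])
    centers = tuple((cx + r * np.cos(a), cy + r * np.sin(a)) for a in angles)
    return TargetLayout(centers=centers, diameter=0.03)


def straight_path(p_start, p_end, n: int = 100) -> Path:
    """``n`` equally spaced points on the segment from p_start to p_end."""
    if n < 2:
        raise ValueError("a straight path needs n >= 2 points")
    p_start = np.asarray(p_start, dtype=float).reshape(2)
    p_end = np.asarray(p_end, dtype=float).reshape(2)
    s = np.linspace(0.0, 1.0, n)[:, None]
    return Path(p_start + s * (p_end - p_start))


def _quintic(tau: np.ndarray):
    """Minimum-jerk time profile s, s', s'' on the unit interval."""
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    sd = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    sdd = 60 * tau - 180 * tau**2 + 120 * tau**3
    return s, sd, sdd


def min_jerk_trajectory(p_start, p_end, T: float = 1.0, rate: float = 100.0) -> Trajectory:
    """Straight reach with the quintic minimum-jerk speed profile.

    Zero velocity and acceleration at both ends; peak speed is
    1.875·‖Δp‖/T at mid-movement.
    """
    if T <= 0:
        raise ValueError("duration must be positive")
    p_start = np.asarray(p_start, dtype=float).reshape(2)
    p_end = np.asarray(p_end, dtype=float).reshape(2)
    n = int(round(T * rate))
    t = np.linspace(0.0, T, n + 1)
    s, sd, _ = _quintic(t / T)
    dp = p_end - p_start
    pos = p_start + s[:, None] * dp
    vel = (sd / T)[:, None] * dp
    return Trajectory(t=t, pos=pos, vel=vel)


def path_energy(traj: Trajectory) -> float:
    """Mechanical work transferred to the object: ∫ |F·v| dt (joules)."""
    if traj.force is None:
        raise ValueError("trajectory carries no force series; cannot integrate work")
    power = np.abs(np.sum(traj.force * traj.vel, axis=1))
    return float(np.trapezoid(power, traj.t))


# ---------------------------------------------------------------------------
# geodesics of the kinetic-energy metric
# ---------------------------------------------------------------------------


def joint_path_energy(params: PendulumParams, q: np.ndarray) -> float:
    """Discrete path-energy functional Σ Δqᵀ M(q̄) Δq of a joint-space polyline.

    Up to parametrization this is the Riemannian energy of the curve under
    the kinetic-energy metric; its minimizers (fixed endpoints, uniform
    parametrization) discretize constant-speed geodesics.  The sum is scaled
    by the number of segments so the value approximates ∫ q̇ᵀ M q̇ dτ on the
    unit interval and is comparable across discretizations.
    """
    q = np.asarray(q, dtype=float)
    dq = np.diff(q, axis=0)
    qm = 0.5 * (q[:-1] + q[1:])
    a, b, d = params.abc
    c2 = np.cos(qm[:, 1])
    m11 = a + 2.0 * b * c2
    m12 = d + b * c2
    n_seg = dq.shape[0]
    return float(
        n_seg
        * np.sum(m11 * dq[:, 0] ** 2 + 2.0 * m12 * dq[:, 0] * dq[:, 1] + d * dq[:, 1] ** 2)
    )


def _wrap_to(q_ref: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Shift each component of q by multiples of 2π to lie nearest q_ref."""
    return q_ref + np.mod(q - q_ref + np.pi, 2.0 * np.pi) - np.pi


def _shoot(params: PendulumParams, q0: np.ndarray, v0: np.ndarray, n_steps: int, dt: float):
    a, b, d = params.abc
    return _kernels.simulate_unforced_rk4(a, b, d, q0[0], q0[1], v0[0], v0[1], dt, n_steps)


def geodesic_path(
    params: PendulumParams | PointMassParams,
    p_start,
    p_end,
    branch: int | None = None,
    n_samples: int = 200,
    n_starts: int = 8,
    full_output: bool = False,
):
    """Path of least kinetic energy between two endpoint positions.

    For the pendulum this solves the two-point boundary value problem of the
    unforced system (boundary velocities free) by single shooting over the
    initial joint velocity, with a fixed nominal duration of 1 s — geodesics
    are invariant to this time normalization, only the path shape matters.
    Multi-start over ``n_starts`` initial-velocity directions and, when
    ``branch`` is None, both elbow branches; among converged solutions the
    one with the least discretized path energy is returned.

    For a point mass the metric is Euclidean and the straight segment is
    returned directly.
    """
    p_start = np.asarray(p_start, dtype=float).reshape(2)
    p_end = np.asarray(p_end, dtype=float).reshape(2)
    if np.allclose(p_start, p_end):
        path = Path(p_start[None, :])
        return (path, {"residual": 0.0, "energy": 0.0}) if full_output else path
    if isinstance(params, PointMassParams):
        path = straight_path(p_start, p_end, n_samples)
        return (path, {"residual": 0.0, "energy": 0.0}) if full_output else path

    dt = 1e-3
    n_steps = 1000  # nominal duration 1 s
    branches = (1, -1) if branch is None else (branch,)
    best = None
    best_residual = np.inf
    for br in branches:
        q0 = inverse_kinematics(params, p_start, branch=br)
        q1 = _wrap_to(q0, inverse_kinematics(params, p_end, branch=br))
        dq = q1 - q0

        def residual(v0, q0=q0, q1=q1):
            out = _shoot(params, q0, v0, n_steps, dt)
            return out[-1, :2] - q1

        speed = max(np.linalg.norm(dq), 1e-6)
        for k in range(n_starts):
            ang = 2.0 * np.pi * k / n_starts
            ca, sa = np.cos(ang), np.sin(ang)
            v_init = np.array([ca * dq[0] - sa * dq[1], sa * dq[0] + ca * dq[1]])
            if np.linalg.norm(v_init) < 1e-9:
                v_init = speed * np.array([ca, sa])
            sol = root(residual, v_init, method="hybr", tol=1e-12)
            res_norm = float(np.linalg.norm(residual(sol.x)))
            best_residual = min(best_residual, res_norm)
            if res_norm > 1e-8:
                continue
            out = _shoot(params, q0, sol.x, n_steps, dt)
            energy = joint_path_energy(params, out[:: max(1, n_steps // 100), :2])
            if best is None or energy < best["energy"] - 1e-12:
                best = {
                    "energy": energy,
                    "residual": res_norm,
                    "v0": sol.x.copy(),
                    "branch": br,
                    "joint_path": out[:, :2],
                }
    if best is None:
        raise GeodesicConvergenceError(
            f"shooting did not converge for any start; best boundary residual "
            f"{best_residual:.3e} rad"
        )
    q_traj = best["joint_path"]
    idx = np.linspace(0, q_traj.shape[0] - 1, n_samples).round().astype(int)
    pts = forward_kinematics(params, q_traj[idx])
    # pin the endpoints exactly to the requested positions (residual ~1e-9)
    pts[0], pts[-1] = p_start, p_end
    path = Path(pts)
    return (path, best) if full_output else path


def waypoint_geodesic_path(
    params: PendulumParams,
    p_start,
    p_end,
    n: int = 50,
    branch: int | None = None,
    full_output: bool = False,
):
    """Direct discretized minimizer of the path-energy functional.

    Minimizes Σ Δqᵀ M(q̄) Δq over an ``n``-waypoint joint-space polyline with
    fixed endpoints (analytic gradient, L-BFGS).  An independent route to the
    least-energy path that never integrates the dynamics; used to cross-check
    the shooting solution.
    """
    p_start = np.asarray(p_start, dtype=float).reshape(2)
    p_end = np.asarray(p_end, dtype=float).reshape(2)
    a, bb, d = params.abc
    branches = (1, -1) if branch is None else (branch,)
    best = None
    for br in branches:
        q0 = inverse_kinematics(params, p_start, branch=br)
        q1 = _wrap_to(q0, inverse_kinematics(params, p_end, branch=br))
        base = np.linspace(q0, q1, n)

        def unpack(x):
            q = base.copy()
            q[1:-1] = x.reshape(n - 2, 2)
            return q

        def cost_grad(x):
            q = unpack(x)
            dq = np.diff(q, axis=0)
            qm = 0.5 * (q[:-1] + q[1:])
            c2 = np.cos(qm[:, 1])
            s2 = np.sin(qm[:, 1])
            m11 = a + 2.0 * bb * c2
            m12 = d + bb * c2
            e = np.sum(m11 * dq[:, 0] ** 2 + 2 * m12 * dq[:, 0] * dq[:, 1] + d * dq[:, 1] ** 2)
            # per-segment M(q̄)Δq and metric-derivative quadratic form
            Mdq = np.column_stack([m11 * dq[:, 0] + m12 * dq[:, 1], m12 * dq[:, 0] + d * dq[:, 1]])
            g = -s2 * (2 * bb * dq[:, 0] ** 2 + 2 * bb * dq[:, 0] * dq[:, 1])  # Δqᵀ M' Δq
            grad = np.zeros((n, 2))
            grad[:-1] += -2.0 * Mdq
            grad[1:] += 2.0 * Mdq
            grad[:-1, 1] += 0.5 * g
            grad[1:, 1] += 0.5 * g
            return e, grad[1:-1].ravel()

        res = minimize(
            cost_grad,
            base[1:-1].ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12},
        )
        q = unpack(res.x)
        e = joint_path_energy(params, q)
        if best is None or e < best["energy"]:
            best = {"energy": e, "branch": br, "joint_path": q, "opt": res}
    pts = forward_kinematics(params, best["joint_path"])
    pts[0], pts[-1] = p_start, p_end
    path = Path(pts)
    return (path, best) if full_output else path


# ---------------------------------------------------------------------------
# effort-optimal trajectories
# ---------------------------------------------------------------------------


def _mode_basis(tau: np.ndarray, n_modes: int):
    """Smooth basis vanishing with zero slope at both ends: sin(πτ)sin(kπτ)."""
    k = np.arange(1, n_modes + 1)[None, :]
    pt = np.pi * tau[:, None]
    s1, c1 = np.sin(pt), np.cos(pt)
    sk, ck = np.sin(k * pt), np.cos(k * pt)
    phi = s1 * sk
    dphi = np.pi * (c1 * sk + k * s1 * ck)
    ddphi = np.pi**2 * (-(1 + k**2) * s1 * sk + 2 * k * c1 * ck)
    return phi, dphi, ddphi


def _inverse_dynamics_force(params: PendulumParams, q, qd, qdd):
    """Endpoint force u with M q̈ + C q̇ = Jᵀ u, vectorized over time."""
    a, b, d = params.abc
    c2 = np.cos(q[:, 1])
    s2 = np.sin(q[:, 1])
    tau1 = (a + 2 * b * c2) * qdd[:, 0] + (d + b * c2) * qdd[:, 1] - b * s2 * (
        2 * qd[:, 0] * qd[:, 1] + qd[:, 1] ** 2
    )
    tau2 = (d + b * c2) * qdd[:, 0] + d * qdd[:, 1] + b * s2 * qd[:, 0] ** 2
    s1, c1 = np.sin(q[:, 0]), np.cos(q[:, 0])
    s12, c12 = np.sin(q[:, 0] + q[:, 1]), np.cos(q[:, 0] + q[:, 1])
    j11 = -params.l1 * s1 - params.l2 * s12
    j12 = -params.l2 * s12
    j21 = params.l1 * c1 + params.l2 * c12
    j22 = params.l2 * c12
    det = j11 * j22 - j12 * j21
    # u = J^{-T} tau
    ux = (j22 * tau1 - j21 * tau2) / det
    uy = (-j12 * tau1 + j11 * tau2) / det
    return np.column_stack([ux, uy])


def effort_optimal_trajectory(
    params: PendulumParams | PointMassParams,
    p_start,
    p_end,
    T: float = 1.0,
    n_knots: int = 40,
    n_modes: int = 6,
    branch: int | None = None,
    cost_form: str = "squared",
    rate: float = 100.0,
    max_iter: int = 500,
    full_output: bool = False,
):
    """Rest-to-rest trajectory minimizing the integral cost of applied force.

    The object is fully actuated, so the trajectory is optimized directly in
    configuration space: q(t) is a minimum-jerk baseline between the boundary
    configurations plus smooth modes vanishing (with zero slope) at both
    ends, and the applied force follows from inverse dynamics.  The effort
    ∫‖u‖²dt (``cost_form='squared'``, default) or ∫‖u‖dt (``'abs'``) is then
    minimized over the mode coefficients with L-BFGS, i.e. gradient descent
    starting from the straight-line/min-jerk trajectory.

    ``n_knots`` sets the quadrature resolution (6·n_knots intervals).
    Returns the object-endpoint :class:`Trajectory` sampled at ``rate``, with
    the optimized force as its force series; with ``full_output=True`` also a
    dict with the cost history and solver diagnostics.
    """
    if T <= 0:
        raise ValueError("duration must be positive")
    if cost_form not in ("squared", "abs"):
        raise ValueError("cost_form must be 'squared' or 'abs'")
    p_start = np.asarray(p_start, dtype=float).reshape(2)
    p_end = np.asarray(p_end, dtype=float).reshape(2)
    n_grid = 6 * n_knots + 1
    tau = np.linspace(0.0, 1.0, n_grid)
    t_grid = tau * T
    phi, dphi, ddphi = _mode_basis(tau, n_modes)
    s, sd, sdd = _quintic(tau)
    pend = isinstance(params, PendulumParams)
    branches = ((1, -1) if branch is None else (branch,)) if pend else (0,)

    def make_eval(q0, q1):
        dq = q1 - q0

        def q_of(c, tau_arr=None):
            if tau_arr is None:
                ph, dph, ddph = phi, dphi, ddphi
                ss, ssd, ssdd = s, sd, sdd
            else:
                ph, dph, ddph = _mode_basis(tau_arr, n_modes)
                ss, ssd, ssdd = _quintic(tau_arr)
            q = q0 + ss[:, None] * dq + ph @ c
            qd = (ssd[:, None] * dq + dph @ c) / T
            qdd = (ssdd[:, None] * dq + ddph @ c) / T**2
            return q, qd, qdd

        def force(c, tau_arr=None):
            q, qd, qdd = q_of(c, tau_arr)
            if pend:
                u = _inverse_dynamics_force(params, q, qd, qdd)
            else:
                u = params.m * qdd
            return q, qd, u

        def cost(x):
            _, _, u = force(x.reshape(n_modes, 2))
            nn = np.sum(u * u, axis=1)
            if cost_form == "abs":
                nn = np.sqrt(nn)
            return float(np.trapezoid(nn, t_grid))

        return q_of, force, cost

    best = None
    for br in branches:
        if pend:
            q0 = inverse_kinematics(params, p_start, branch=br)
            q1 = _wrap_to(q0, inverse_kinematics(params, p_end, branch=br))
        else:
            q0, q1 = p_start, p_end
        q_of, force, cost = make_eval(q0, q1)
        history = [cost(np.zeros(2 * n_modes))]
        res = minimize(
            cost,
            np.zeros(2 * n_modes),
            method="L-BFGS-B",
            callback=lambda x, c=cost, h=history: h.append(c(x)),
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best["cost"]:
            best = {
                "cost": float(res.fun),
                "cost_history": np.asarray(history),
                "coeffs": res.x.reshape(n_modes, 2),
                "branch": br,
                "opt": res,
                "force_eval": force,
            }
    # sample the winning trajectory at the recording rate
    n_out = int(round(T * rate))
    tau_out = np.linspace(0.0, 1.0, n_out + 1)
    q, qd, u = best["force_eval"](best["coeffs"], tau_out)
    if pend:
        pos = forward_kinematics(params, q)
        vel = np.einsum("nij,nj->ni", np.stack([jacobian(params, qi) for qi in q]), qd)
    else:
        pos, vel = q, qd
    # boundary positions are met by construction; pin against FK roundoff
    pos[0], pos[-1] = p_start, p_end
    traj = Trajectory(t=tau_out * T, pos=pos, vel=vel, force=u)
    if full_output:
        info = {k: best[k] for k in ("cost", "cost_history", "branch", "coeffs")}
        return traj, info
    return traj
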
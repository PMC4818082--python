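"""Planar double-pendulum and point-mass dynamics with spring-damper coupling.

The manipulated object is a frictionless planar double pendulum (no gravity:
motion is in the horizontal plane), or alternatively a point mass with
isotropic inertia.  The hand interacts with the object's endpoint through a
virtual spring-damper, the standard admittance-style haptic coupling

    F = K (x_hand - x_end) + B (v_hand - v_end),

where F is the force applied *to the object* — the force whose mechanical
work the energy functional integrates.

Angle convention: ``q1`` is the absolute angle of the proximal link from the
workspace x-axis, ``q2`` the elbow angle of the distal link relative to the
proximal one, so the kinetic-energy metric M depends only on q2.  Angles are
stored unwrapped (continuous).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .containers import Trajectory

__all__ = [
    "PendulumParams",
    "PointMassParams",
    "CouplingParams",
    "JointState",
    "UnreachableTargetError",
    "mass_matrix",
    "coriolis_term",
    "kinetic_energy",
    "forward_kinematics",
    "jacobian",
    "inverse_kinematics",
    "coupling_force",
    "simulate_unforced",
    "simulate_coupled",
    "CoupledSimResult",
    "JointTrajectory",
]


class UnreachableTargetError(ValueError):
    """Raised when a workspace point lies outside the reachable annulus."""


@dataclass(frozen=True)
class PendulumParams:
    """Mechanical properties of the virtual double pendulum.

    Defaults are the experiment's object: two identical 10 kg links of length
    0.2 m, rotational inertia 0.4 kg·m² about the center of mass at mid-link.
    ``base`` is the planar position of the fixed pivot (workspace frame).
    """

    m1: float = 10.0
    m2: float = 10.0
    l1: float = 0.2
    l2: float = 0.2
    I1: float = 0.4
    I2: float = 0.4
    c1: float = 0.1
    c2: float = 0.1
    base: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        for name in ("m1", "m2", "l1", "l2", "I1", "I2", "c1", "c2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.c1 > self.l1 or self.c2 > self.l2:
            raise ValueError("centers of mass must lie on their links (c <= l)")
        object.__setattr__(self, "base", (float(self.base[0]), float(self.base[1])))

    # Inertial constants of the reduced mass matrix (see _kernels docstring).
    @property
    def abc(self) -> tuple[float, float, float]:
        a = self.I1 + self.m1 * self.c1**2 + self.I2 + self.m2 * (self.l1**2 + self.c2**2)
        b = self.m2 * self.l1 * self.c2
        d = self.I2 + self.m2 * self.c2**2
        return a, b, d

    @property
    def reach(self) -> float:
        return self.l1 + self.l2

    @property
    def inner_reach(self) -> float:
        return abs(self.l1 - self.l2)


@dataclass(frozen=True)
class PointMassParams:
    """A point mass with isotropic, configuration-independent inertia."""

    m: float = 15.0

    def __post_init__(self):
        if not self.m > 0:
            raise ValueError("mass must be strictly positive")


@dataclass(frozen=True)
class CouplingParams:
    """Virtual spring-damper between hand and object endpoint."""

    K: float = 2200.0
    B: float = 65.0

    def __post_init__(self):
        if self.K < 0 or self.B < 0:
            raise ValueError("stiffness and damping must be nonnegative")


@dataclass
class JointState:
    """Joint angles (rad) and angular velocities (rad/s) of the pendulum."""

    q: np.ndarray
    qdot: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float).reshape(2)
        self.qdot = np.asarray(self.qdot, dtype=float).reshape(2)
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qdot))):
            raise ValueError("joint state must be finite")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.q, self.qdot])


def mass_matrix(params: PendulumParams, q) -> np.ndarray:
    """Configuration-dependent inertia M(q) of the pendulum (2x2, kg·m²).

    Symmetric positive definite for every configuration; depends only on the
    elbow angle q2 (the metric is invariant under rotation of the whole arm).
    """
    a, b, d = params.abc
    c2 = np.cos(np.asarray(q, dtype=float).reshape(2)[1])
    return np.array([[a + 2.0 * b * c2, d + b * c2], [d + b * c2, d]])


def mass_matrix_derivative(params: PendulumParams, q) -> np.ndarray:
    """dM/dq2 (the only nonzero partial of the metric)."""
    _, b, _ = params.abc
    s2 = np.sin(np.asarray(q, dtype=float).reshape(2)[1])
    return np.array([[-2.0 * b * s2, -b * s2], [-b * s2, 0.0]])


def coriolis_term(params: PendulumParams, state: JointState) -> np.ndarray:
    """Generalized Coriolis/centripetal force C(q, q̇)q̇ (N·m).

    With this term the unforced dynamics read M(q) q̈ + C(q, q̇) q̇ = 0.
    """
    _, b, _ = params.abc
    s2 = np.sin(state.q[1])
    qd1, qd2 = state.qdot
    return np.array([-b * s2 * (2.0 * qd1 * qd2 + qd2**2), b * s2 * qd1**2])


def kinetic_energy(params: PendulumParams, state: JointState) -> float:
    """½ q̇ᵀ M(q) q̇ — the total mechanical energy of the gravity-free object."""
    M = mass_matrix(params, state.q)
    return float(0.5 * state.qdot @ M @ state.qdot)


def forward_kinematics(params: PendulumParams, q) -> np.ndarray:
    """Workspace position of the pendulum endpoint for joint angles ``q``.

    Accepts a single configuration (2,) or a stack (N, 2); returns the
    matching shape of planar points.
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    x = params.base[0] + params.l1 * np.cos(q[:, 0]) + params.l2 * np.cos(q[:, 0] + q[:, 1])
    y = params.base[1] + params.l1 * np.sin(q[:, 0]) + params.l2 * np.sin(q[:, 0] + q[:, 1])
    out = np.column_stack([x, y])
    return out[0] if single else out


def jacobian(params: PendulumParams, q) -> np.ndarray:
    """2x2 endpoint Jacobian ∂(forward_kinematics)/∂q (m/rad)."""
    q = np.asarray(q, dtype=float).reshape(2)
    s1, c1 = np.sin(q[0]), np.cos(q[0])
    s12, c12 = np.sin(q[0] + q[1]), np.cos(q[0] + q[1])
    return np.array(
        [
            [-params.l1 * s1 - params.l2 * s12, -params.l2 * s12],
            [params.l1 * c1 + params.l2 * c12, params.l2 * c12],
        ]
    )


def inverse_kinematics(params: PendulumParams, p, branch: int = 1) -> np.ndarray:
    """Joint angles placing the endpoint at workspace point ``p``.

    ``branch`` selects the elbow side: +1 gives q2 in [0, π], -1 in [-π, 0].
    Raises :class:`UnreachableTargetError` outside the reachable annulus
    (a ~1e-9 m tolerance absorbs roundoff at the boundary).
    """
    p = np.asarray(p, dtype=float).reshape(2)
    r = p - np.asarray(params.base)
    dist = float(np.hypot(r[0], r[1]))
    tol = 1e-9
    if dist > params.reach + tol or dist < params.inner_reach - tol:
        raise UnreachableTargetError(
            f"point at distance {dist:.6f} m from the pivot is outside the "
            f"reachable annulus [{params.inner_reach:.6f}, {params.reach:.6f}] m"
        )
    cos_q2 = (dist**2 - params.l1**2 - params.l2**2) / (2.0 * params.l1 * params.l2)
    cos_q2 = float(np.clip(cos_q2, -1.0, 1.0))
    q2 = float(np.sign(branch) if branch != 0 else 1.0) * np.arccos(cos_q2)
    q1 = np.arctan2(r[1], r[0]) - np.arctan2(
        params.l2 * np.sin(q2), params.l1 + params.l2 * np.cos(q2)
    )
    return np.array([q1, q2])


def coupling_force(cp: CouplingParams, hand_pos, hand_vel, end_pos, end_vel) -> np.ndarray:
    """Spring-damper force applied to the object (N)."""
    hand_pos = np.asarray(hand_pos, dtype=float)
    hand_vel = np.asarray(hand_vel, dtype=float)
    end_pos = np.asarray(end_pos, dtype=float)
    end_vel = np.asarray(end_vel, dtype=float)
    return cp.K * (hand_pos - end_pos) + cp.B * (hand_vel - end_vel)


@dataclass
class JointTrajectory:
    """Joint-space time series (t, q, qdot) from a simulation."""

    t: np.ndarray
    q: np.ndarray
    qdot: np.ndarray

    def kinetic_energy(self, params: PendulumParams) -> np.ndarray:
        a, b, d = params.abc
        c2 = np.cos(self.q[:, 1])
        m11 = a + 2.0 * b * c2
        m12 = d + b * c2
        qd1, qd2 = self.qdot[:, 0], self.qdot[:, 1]
        return 0.5 * (m11 * qd1**2 + 2.0 * m12 * qd1 * qd2 + d * qd2**2)

    def endpoint_path(self, params: PendulumParams) -> np.ndarray:
        return forward_kinematics(params, self.q)


def _unforced_rhs(params: PendulumParams):
    a, b, d = params.abc

    def rhs(t, y):
        return _kernels._unforced_rhs(a, b, d, y)

    return rhs


def simulate_unforced(
    params: PendulumParams,
    initial: JointState,
    T: float,
    dt: float = 1e-4,
    method: str = "adaptive",
) -> JointTrajectory:
    """Flow of the unforced pendulum M q̈ + C q̇ = 0 for duration ``T``.

    ``method='adaptive'`` uses a high-accuracy DOP853 integration sampled at
    ``dt``; ``method='rk4'`` is a fixed-step RK4 at step ``dt`` (the 1 kHz
    haptic-loop integrator).  Kinetic energy is conserved along the flow.
    """
    if not (T > 0 and dt > 0):
        raise ValueError("T and dt must be positive")
    a, b, d = params.abc
    n_steps = int(round(T / dt))
    t = np.linspace(0.0, n_steps * dt, n_steps + 1)
    if method == "rk4":
        out = _kernels.simulate_unforced_rk4(
            a, b, d, initial.q[0], initial.q[1], initial.qdot[0], initial.qdot[1], dt, n_steps
        )
        return JointTrajectory(t=t, q=out[:, :2], qdot=out[:, 2:])
    if method != "adaptive":
        raise ValueError(f"unknown method {method!r}")
    sol = solve_ivp(
        _unforced_rhs(params),
        (0.0, t[-1]),
        initial.as_vector(),
        method="DOP853",
        t_eval=t,
        rtol=1e-12,
        atol=1e-13,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"unforced integration failed: {sol.message}")
    y = sol.y.T
    return JointTrajectory(t=t, q=y[:, :2], qdot=y[:, 2:])


@dataclass
class CoupledSimResult:
    """Output of :func:`simulate_coupled`, downsampled to the recording rate.

    ``states`` holds joint states (pendulum) or planar position/velocity
    (point mass); ``force`` is the spring-damper force applied to the object.
    """

    t: np.ndarray
    hand_pos: np.ndarray
    hand_vel: np.ndarray
    end_pos: np.ndarray
    end_vel: np.ndarray
    force: np.ndarray
    states: np.ndarray

    def hand_trajectory(self) -> Trajectory:
        """Hand motion with the object force attached (the Eq-for-work inputs)."""
        return Trajectory(t=self.t, pos=self.hand_pos, vel=self.hand_vel, force=self.force)

    def object_trajectory(self) -> Trajectory:
        return Trajectory(t=self.t, pos=self.end_pos, vel=self.end_vel, force=self.force)


def _resample_hand(hand_traj: Trajectory, dt: float):
    """Hand position/velocity on the simulation grid (linear interpolation)."""
    n = int(round(hand_traj.duration / dt))
    t = hand_traj.t[0] + np.arange(n + 1) * dt
    t[-1] = min(t[-1], hand_traj.t[-1])
    pos = np.column_stack(
        [np.interp(t, hand_traj.t, hand_traj.pos[:, k]) for k in range(2)]
    )
    vel = np.column_stack(
        [np.interp(t, hand_traj.t, hand_traj.vel[:, k]) for k in range(2)]
    )
    return t, pos, vel


def simulate_coupled(
    params: PendulumParams | PointMassParams,
    cp: CouplingParams,
    hand_traj: Trajectory,
    initial: JointState | np.ndarray | None = None,
    dt: float = 1e-3,
    record_rate: float = 100.0,
    reach_margin: float = 0.05,
) -> CoupledSimResult:
    """Drive the object with a hand trajectory through the spring-damper.

    Integrates M(q) q̈ + C q̇ = Jᵀ F (pendulum) or m a = F (point mass) with a
    fixed-step RK4 at step ``dt`` (default the 1 kHz haptic rate) and returns
    the object states and force series downsampled to ``record_rate``.

    If ``initial`` is None the object starts at rest with its endpoint at the
    first hand sample (pendulum: elbow-positive inverse-kinematics branch).
    A hand excursion beyond the reachable annulus plus ``reach_margin`` only
    warns — the virtual spring simply stretches.
    """
    t, hpos, hvel = _resample_hand(hand_traj, dt)
    stride = max(1, int(round(1.0 / (record_rate * dt))))
    if isinstance(params, PendulumParams):
        r = np.hypot(hpos[:, 0] - params.base[0], hpos[:, 1] - params.base[1])
        if np.any(r > params.reach + reach_margin) or np.any(
            r < max(params.inner_reach - reach_margin, 0.0)
        ):
            warnings.warn(
                "hand trajectory leaves the reachable annulus by more than the "
                f"configured margin ({reach_margin} m); the coupling spring will stretch",
                stacklevel=2,
            )
        if initial is None:
            q0 = inverse_kinematics(params, hpos[0], branch=1)
            y0 = np.array([q0[0], q0[1], 0.0, 0.0])
        else:
            y0 = initial.as_vector() if isinstance(initial, JointState) else np.asarray(initial, dtype=float)
        a, b, d = params.abc
        states, epos, evel, force = _kernels.simulate_pendulum_coupled(
            a, b, d, params.l1, params.l2, params.base[0], params.base[1],
            cp.K, cp.B, hpos, hvel, y0, dt,
        )
    else:
        if initial is None:
            y0 = np.array([hpos[0, 0], hpos[0, 1], 0.0, 0.0])
        else:
            y0 = np.asarray(initial, dtype=float).reshape(4)
        states, force = _kernels.simulate_point_mass_coupled(
            params.m, cp.K, cp.B, hpos, hvel, y0, dt
        )
        epos, evel = states[:, :2], states[:, 2:]
    sl = slice(None, None, stride)
    return CoupledSimResult(
        t=t[sl],
        hand_pos=hpos[sl],
        hand_vel=hvel[sl],
        end_pos=epos[sl],
        end_vel=evel[sl],
        force=force[sl],
        states=states[sl],
    )
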
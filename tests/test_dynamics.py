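import numpy as np
import pytest

from kinepath.containers import Trajectory
from kinepath.dynamics import (
    CouplingParams,
    JointState,
    PendulumParams,
    PointMassParams,
    UnreachableTargetError,
    coriolis_term,
    coupling_force,
    forward_kinematics,
    inverse_kinematics,
    jacobian,
    kinetic_energy,
    mass_matrix,
    mass_matrix_derivative,
    simulate_coupled,
    simulate_unforced,
)
from kinepath.paths import min_jerk_trajectory

from oracles import christoffel_coriolis, symbolic_mass_matrix


def test_params_validation():
    with pytest.raises(ValueError):
        PendulumParams(m1=-1.0)
    with pytest.raises(ValueError):
        PendulumParams(c1=0.3)  # center of mass beyond link
    with pytest.raises(ValueError):
        PointMassParams(m=0.0)
    with pytest.raises(ValueError):
        CouplingParams(K=-1.0)


def test_mass_matrix_matches_symbolic_lagrangian(pend, rng):
    """The closed-form metric agrees with an independent sympy derivation."""
    M_sym = symbolic_mass_matrix(pend)
    for q2 in rng.uniform(-np.pi, np.pi, 5):
        np.testing.assert_allclose(
            mass_matrix(pend, (0.0, q2)), M_sym(q2), rtol=0, atol=1e-12
        )
    # straightened configuration: M[0,0] = a + 2b = 1.8 kg m^2 for these links
    np.testing.assert_allclose(mass_matrix(pend, (0.3, 0.0))[0, 0], 1.8, atol=1e-12)


def test_mass_matrix_spd_and_shoulder_invariance(pend, rng):
    for _ in range(1000):
        q = rng.uniform(-2 * np.pi, 2 * np.pi, 2)
        M = mass_matrix(pend, q)
        assert np.allclose(M, M.T)
        assert np.all(np.linalg.eigvalsh(M) > 0)
    # the metric depends only on the elbow angle
    q2 = 0.7
    M_ref = mass_matrix(pend, (0.0, q2))
    for q1 in rng.uniform(-np.pi, np.pi, 10):
        np.testing.assert_allclose(mass_matrix(pend, (q1, q2)), M_ref, atol=1e-14)


def test_coriolis_quadratic_in_velocity(pend):
    st = JointState(q=(0.4, 1.1), qdot=(0.0, 0.0))
    np.testing.assert_allclose(coriolis_term(pend, st), 0.0, atol=1e-15)


def test_coriolis_matches_christoffel_oracle(pend, rng):
    for _ in range(20):
        q = rng.uniform(-np.pi, np.pi, 2)
        qd = rng.uniform(-3, 3, 2)
        expected = christoffel_coriolis(lambda qq: mass_matrix(pend, qq), q, qd)
        got = coriolis_term(pend, JointState(q=q, qdot=qd))
        np.testing.assert_allclose(got, expected, atol=1e-5)


def test_coriolis_power_balance(pend, rng):
    """Skew symmetry: q̇ᵀ Ṁ q̇ = 2 q̇ᵀ C q̇, so the unforced flow conserves energy."""
    for _ in range(20):
        q = rng.uniform(-np.pi, np.pi, 2)
        qd = rng.uniform(-3, 3, 2)
        Mdot = mass_matrix_derivative(pend, q) * qd[1]
        lhs = qd @ Mdot @ qd
        rhs = 2.0 * qd @ coriolis_term(pend, JointState(q=q, qdot=qd))
        assert abs(lhs - rhs) < 1e-9


def test_kinetic_energy(pend, rng):
    assert kinetic_energy(pend, JointState(q=(1.0, -0.5), qdot=(0, 0))) == 0.0
    # straightened arm rotating about the shoulder at 1 rad/s: E = M11/2
    assert kinetic_energy(pend, JointState(q=(0.2, 0.0), qdot=(1.0, 0.0))) == pytest.approx(0.9)
    for _ in range(50):
        st = JointState(q=rng.uniform(-np.pi, np.pi, 2), qdot=rng.uniform(-5, 5, 2))
        assert kinetic_energy(pend, st) >= 0.0


@pytest.mark.parametrize(
    "q, expected",
    [
        ((0.0, 0.0), (0.4, 0.0)),
        ((np.pi / 2, 0.0), (0.0, 0.4)),
        ((0.0, np.pi), (0.0, 0.0)),
    ],
)
def test_forward_kinematics_examples(pend, q, expected):
    np.testing.assert_allclose(forward_kinematics(pend, q), expected, atol=1e-12)


def test_jacobian_finite_difference(pend, rng):
    h = 1e-7
    for _ in range(20):
        q = rng.uniform(-np.pi, np.pi, 2)
        J = jacobian(pend, q)
        for k in range(2):
            e = np.zeros(2)
            e[k] = h
            fd = (forward_kinematics(pend, q + e) - forward_kinematics(pend, q - e)) / (2 * h)
            np.testing.assert_allclose(J[:, k], fd, atol=1e-6)


def test_jacobian_singular_when_collinear(pend):
    assert abs(np.linalg.det(jacobian(pend, (0.3, 0.0)))) < 1e-12
    assert abs(np.linalg.det(jacobian(pend, (0.3, np.pi)))) < 1e-12
    # the distal column always has norm l2
    J = jacobian(pend, (0.0, np.pi / 2))
    assert np.linalg.norm(J[:, 1]) == pytest.approx(pend.l2)


def test_inverse_kinematics_roundtrip(pend, rng):
    for _ in range(50):
        r = rng.uniform(0.02, pend.reach - 1e-6)
        th = rng.uniform(-np.pi, np.pi)
        p = np.array([r * np.cos(th), r * np.sin(th)])
        for branch in (1, -1):
            q = inverse_kinematics(pend, p, branch=branch)
            np.testing.assert_allclose(forward_kinematics(pend, q), p, atol=1e-9)
            assert np.sign(q[1]) in (branch, 0.0)


def test_inverse_kinematics_edges(pend):
    np.testing.assert_allclose(
        inverse_kinematics(pend, (0.4, 0.0), branch=1), (0.0, 0.0), atol=1e-6
    )
    with pytest.raises(UnreachableTargetError, match="0.5"):
        inverse_kinematics(pend, (0.5, 0.0))
    q = inverse_kinematics(pend, (0.2, 0.2), branch=1)
    np.testing.assert_allclose(forward_kinematics(pend, q), (0.2, 0.2), atol=1e-9)


def test_coupling_force_linear_law():
    cp = CouplingParams(K=2200.0, B=65.0)
    np.testing.assert_allclose(
        coupling_force(cp, (0.1, 0.2), (0.3, 0.4), (0.1, 0.2), (0.3, 0.4)), (0.0, 0.0)
    )
    np.testing.assert_allclose(
        coupling_force(CouplingParams(K=2200.0, B=0.0), (0.01, 0), (0, 0), (0, 0), (0, 0)),
        (22.0, 0.0),
    )
    np.testing.assert_allclose(
        coupling_force(CouplingParams(K=0.0, B=65.0), (0, 0), (0.1, 0), (0, 0), (0, 0)),
        (6.5, 0.0),
    )


def test_unforced_rest_state_is_fixed_point(pend):
    out = simulate_unforced(pend, JointState(q=(0.5, 1.0), qdot=(0, 0)), T=0.5, dt=1e-3)
    np.testing.assert_allclose(out.q, np.tile(out.q[0], (len(out.t), 1)), atol=1e-12)


@pytest.mark.parametrize("method,dt,tol", [("adaptive", 1e-3, 1e-10), ("rk4", 1e-3, 1e-8)])
def test_unforced_energy_conservation(pend, rng, method, dt, tol):
    st = JointState(q=rng.uniform(-np.pi, np.pi, 2), qdot=rng.uniform(-3, 3, 2))
    out = simulate_unforced(pend, st, T=1.0, dt=dt, method=method)
    ke = out.kinetic_energy(pend)
    assert np.max(np.abs(ke - ke[0])) / ke[0] < tol


def test_unforced_geodesic_reparametrization(pend):
    """Scaling the initial velocity rescales time but traverses the same path."""
    q0, v0 = np.array([0.3, 1.2]), np.array([1.0, -0.7])
    a = simulate_unforced(pend, JointState(q=q0, qdot=v0), T=1.0, dt=1e-3, method="rk4")
    b = simulate_unforced(pend, JointState(q=q0, qdot=2 * v0), T=0.5, dt=5e-4, method="rk4")
    np.testing.assert_allclose(a.q, b.q, atol=1e-8)


def _held_minjerk_hand(a, b, T=1.0, hold=0.5, rate=1000.0):
    mj = min_jerk_trajectory(a, b, T, rate=rate)
    n = int(round(hold * rate))
    dt = 1.0 / rate
    t = np.concatenate([mj.t, mj.t[-1] + np.arange(1, n + 1) * dt])
    pos = np.vstack([mj.pos, np.repeat(mj.pos[-1][None, :], n, axis=0)])
    vel = np.vstack([mj.vel, np.zeros((n, 2))])
    return Trajectory(t=t, pos=pos, vel=vel)


def test_coupled_equilibrium(pend, coupling):
    p0 = forward_kinematics(pend, (0.6, 0.9))
    t = np.arange(0, 1.0, 1e-3)
    hand = Trajectory(t=t, pos=np.repeat(p0[None, :], t.size, 0), vel=np.zeros((t.size, 2)))
    sim = simulate_coupled(pend, coupling, hand)
    assert np.max(np.abs(sim.force)) < 1e-9
    np.testing.assert_allclose(sim.end_pos, np.tile(p0, (sim.end_pos.shape[0], 1)), atol=1e-9)


def test_coupled_unforced_limit_conserves_energy(pend):
    """With zero coupling the driven simulation reduces to the free flow."""
    p0 = forward_kinematics(pend, (0.2, 1.0))
    t = np.arange(0, 1.0, 1e-3)
    hand = Trajectory(t=t, pos=np.repeat(p0[None, :], t.size, 0), vel=np.zeros((t.size, 2)))
    y0 = np.array([0.2, 1.0, 1.5, -1.0])
    sim = simulate_coupled(pend, CouplingParams(K=0.0, B=0.0), hand, initial=y0,
                           record_rate=1000.0)
    from kinepath.dynamics import JointTrajectory

    jt = JointTrajectory(t=sim.t, q=sim.states[:, :2], qdot=sim.states[:, 2:])
    ke = jt.kinetic_energy(pend)
    assert np.max(np.abs(ke - ke[0])) / ke[0] < 1e-6


def test_coupled_tracking_settles(pend, coupling, layout):
    """The underdamped spring lag rings down during the post-movement hold."""
    a, b = layout.center(0), layout.center(1)
    for hold, tol in ((0.5, 0.010), (1.0, 0.005)):
        sim = simulate_coupled(pend, coupling, _held_minjerk_hand(a, b, hold=hold))
        assert np.linalg.norm(sim.end_pos[-1] - sim.hand_pos[-1]) < tol


def test_coupled_power_balance(pend, coupling, layout):
    """Energy gained by the object equals the integral of F·v_endpoint."""
    a, b = layout.center(0), layout.center(2)
    sim = simulate_coupled(pend, coupling, _held_minjerk_hand(a, b), record_rate=1000.0)
    from kinepath.dynamics import JointTrajectory

    jt = JointTrajectory(t=sim.t, q=sim.states[:, :2], qdot=sim.states[:, 2:])
    ke = jt.kinetic_energy(pend)
    work = np.trapezoid(np.sum(sim.force * sim.end_vel, axis=1), sim.t)
    assert abs((ke[-1] - ke[0]) - work) < 1e-5 * max(np.max(ke), 1e-12)


def test_coupled_point_mass(pm, coupling, layout):
    a, b = layout.center(0), layout.center(1)
    sim = simulate_coupled(pm, coupling, _held_minjerk_hand(a, b, hold=1.0))
    assert np.linalg.norm(sim.end_pos[-1] - sim.hand_pos[-1]) < 5e-3
    # at rest at the hand: no force
    t = np.arange(0, 0.5, 1e-3)
    hand = Trajectory(t=t, pos=np.tile(a, (t.size, 1)), vel=np.zeros((t.size, 2)))
    sim0 = simulate_coupled(pm, coupling, hand)
    assert np.max(np.abs(sim0.force)) < 1e-12


def test_coupled_warns_outside_reach(pend, coupling):
    t = np.arange(0, 0.5, 1e-3)
    pos = np.column_stack([np.linspace(0.3, 0.6, t.size), np.zeros(t.size)])
    vel = np.gradient(pos, 1e-3, axis=0)
    with pytest.warns(UserWarning, match="reachable annulus"):
        simulate_coupled(pend, coupling, Trajectory(t=t, pos=pos, vel=vel))
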
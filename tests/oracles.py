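"""Independent oracles used by the tests.

Everything here is deliberately naive — exhaustive enumeration, symbolic
derivation, finite differences — and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

import numpy as np


def dfd_bruteforce(P: np.ndarray, Q: np.ndarray) -> float:
    """Discrete Fréchet distance by exhaustive enumeration of all monotone
    couplings (feasible for paths of ~6 points)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    n, m = P.shape[0], Q.shape[0]
    d = np.linalg.norm(P[:, None, :] - Q[None, :, :], axis=2)
    best = [np.inf]

    def walk(i: int, j: int, leash: float):
        leash = max(leash, d[i, j])
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], leash)
            return
        if i < n - 1:
            walk(i + 1, j, leash)
        if j < m - 1:
            walk(i, j + 1, leash)
        if i < n - 1 and j < m - 1:
            walk(i + 1, j + 1, leash)

    walk(0, 0, 0.0)
    return best[0]


def symbolic_mass_matrix(params):
    """Mass matrix from a sympy Lagrangian derivation of the two-link chain.

    Returns a callable M(q2) -> 2x2 ndarray.
    """
    import sympy as sp

    q1, q2, w1, w2 = sp.symbols("q1 q2 w1 w2", real=True)
    c1 = params.c1 * sp.Matrix([sp.cos(q1), sp.sin(q1)])
    c2 = params.l1 * sp.Matrix([sp.cos(q1), sp.sin(q1)]) + params.c2 * sp.Matrix(
        [sp.cos(q1 + q2), sp.sin(q1 + q2)]
    )
    # COM velocities under qdot = (w1, w2)
    v1 = c1.jacobian([q1, q2]) * sp.Matrix([w1, w2])
    v2 = c2.jacobian([q1, q2]) * sp.Matrix([w1, w2])
    ke = (
        sp.Rational(1, 2) * params.m1 * (v1.T * v1)[0]
        + sp.Rational(1, 2) * params.m2 * (v2.T * v2)[0]
        + sp.Rational(1, 2) * params.I1 * w1**2
        + sp.Rational(1, 2) * params.I2 * (w1 + w2) ** 2
    )
    M_sym = sp.simplify(sp.hessian(ke, [w1, w2]))
    f = sp.lambdify((q1, q2), M_sym, "numpy")
    return lambda q2_val: np.asarray(f(0.0, q2_val), dtype=float)


def christoffel_coriolis(mass_matrix_fn, q: np.ndarray, qdot: np.ndarray, h: float = 1e-6):
    """C(q, q̇)q̇ from numerically differentiated Christoffel symbols."""
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    dM = np.empty((2, 2, 2))  # dM[k] = ∂M/∂q_k
    for k in range(2):
        e = np.zeros(2)
        e[k] = h
        dM[k] = (mass_matrix_fn(q + e) - mass_matrix_fn(q - e)) / (2 * h)
    out = np.zeros(2)
    for k in range(2):
        for i in range(2):
            for j in range(2):
                gamma = 0.5 * (dM[j][k, i] + dM[i][k, j] - dM[k][i, j])
                out[k] += gamma * qdot[i] * qdot[j]
    return out
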
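"""Linear-programming backends for the CLIME column problems.

Each CLIME column solves

    min ||w||_1  subject to  ||sigma @ w - e_b||_inf <= lambda

which, after splitting w = u - v with u, v >= 0, is the LP

    min 1'(u, v)  s.t.  [[S, -S], [-S, S]] (u, v) <= [lam + e; lam - e].

All costs are +1, so the all-slack basis is dual feasible and the problem is
a natural fit for the dual simplex method. The default backend is a
numba-compiled tableau dual simplex with Bland's rule (finite termination on
degenerate problems); ``backend="highs"`` routes every column through
scipy.optimize.linprog instead and is kept as an independent reference.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: constraint tolerance shared by both backends
CONSTRAINT_TOL = 1e-8

_STATUS_OK = 0
_STATUS_INFEASIBLE = 1
_STATUS_ITER_LIMIT = 2


class LpInfeasibleError(RuntimeError):
    """The column LP has no feasible point (singular sigma at tiny lambda)."""

    def __init__(self, column: int):
        self.column = column
        super().__init__(f"CLIME column LP infeasible for column {column}")


class LpConvergenceError(RuntimeError):
    """The solver hit its iteration limit without reaching optimality."""

    def __init__(self, column: int):
        self.column = column
        super().__init__(f"LP solver failed to converge on column {column}")


@njit(cache=True)
def _dual_simplex(A, b, tol, max_iter):  # pragma: no cover - exercised via wrapper
    """min 1'x s.t. A x <= b, x >= 0 with all costs 1 (dual-feasible start)."""
    m, n = A.shape
    T = np.zeros((m, n + m + 1))
    T[:, :n] = A
    for i in range(m):
        T[i, n + i] = 1.0
    T[:, n + m] = b
    cost = np.zeros(n + m + 1)
    cost[:n] = 1.0
    basis = np.arange(n, n + m)

    for _ in range(max_iter):
        # leaving row: Bland's rule, smallest basis index among negative rhs
        r = -1
        best = n + m + 1
        for i in range(m):
            if T[i, n + m] < -tol and basis[i] < best:
                best = basis[i]
                r = i
        if r == -1:
            x = np.zeros(n)
            for i in range(m):
                if basis[i] < n:
                    x[basis[i]] = T[i, n + m]
            return x, _STATUS_OK
        # entering column: minimum dual ratio, Bland on ties
        jin = -1
        best_ratio = 1e300
        for j in range(n + m):
            a = T[r, j]
            if a < -tol:
                ratio = cost[j] / (-a)
                if ratio < best_ratio - 1e-12:
                    best_ratio = ratio
                    jin = j
        if jin == -1:
            return np.zeros(n), _STATUS_INFEASIBLE
        piv = T[r, jin]
        T[r, :] /= piv
        for i in range(m):
            if i != r:
                f = T[i, jin]
                if f != 0.0:
                    T[i, :] -= f * T[r, :]
        f = cost[jin]
        if f != 0.0:
            cost -= f * T[r, :]
        basis[r] = jin
    return np.zeros(n), _STATUS_ITER_LIMIT


@njit(cache=True)
def _clime_columns_simplex(S, lam, tol, max_iter):  # pragma: no cover
    p = S.shape[0]
    omega = np.zeros((p, p))
    A = np.empty((2 * p, 2 * p))
    A[:p, :p] = S
    A[:p, p:] = -S
    A[p:, :p] = -S
    A[p:, p:] = S
    for col in range(p):
        b = np.empty(2 * p)
        for i in range(p):
            e = 1.0 if i == col else 0.0
            b[i] = lam + e
            b[p + i] = lam - e
        x, status = _dual_simplex(A.copy(), b, tol, max_iter)
        if status != _STATUS_OK:
            return omega, status, col
        omega[:, col] = x[:p] - x[p:]
    return omega, _STATUS_OK, -1


def _clime_columns_highs(S: np.ndarray, lam: float) -> np.ndarray:
    from scipy.optimize import linprog

    p = S.shape[0]
    A_ub = np.block([[S, -S], [-S, S]])
    c = np.ones(2 * p)
    omega = np.zeros((p, p))
    for col in range(p):
        e = np.zeros(p)
        e[col] = 1.0
        b_ub = np.concatenate([lam + e, lam - e])
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, method="highs")
        if res.status == 2:
            raise LpInfeasibleError(col)
        if res.status != 0:
            raise LpConvergenceError(col)
        omega[:, col] = res.x[:p] - res.x[p:]
    return omega


def solve_clime_columns(sigma: np.ndarray, lam: float, backend: str = "simplex") -> np.ndarray:
    """Solve all p column LPs of the CLIME problem for one (sigma, lambda).

    Returns the unsymmetrised column-stacked solution.
    """
    S = np.ascontiguousarray(np.asarray(sigma, dtype=float))
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("sigma must be a square matrix")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if backend == "simplex":
        omega, status, col = _clime_columns_simplex(S, float(lam), CONSTRAINT_TOL, 50_000)
        if status == _STATUS_INFEASIBLE:
            raise LpInfeasibleError(col)
        if status == _STATUS_ITER_LIMIT:
            raise LpConvergenceError(col)
        return omega
    if backend == "highs":
        return _clime_columns_highs(S, float(lam))
    raise ValueError(f"unknown LP backend {backend!r}")
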
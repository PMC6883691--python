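"""Exact simplex-constrained quadratic programming for small K.

The deconvolution work-horse is

    argmin_pi  (1/2) pi' Q pi + a' pi
    subject to sum(pi) = 1 (optional) and pi >= 0 (optional)

with ``Q = X'X`` and ``a = -X'y`` for a design ``X`` (regions or CpGs
by cell types) and observations ``y``.  Because K is the number of
cell types (six for whole blood), the problem is tiny, and an exact
active-set search is both simpler and more robust than an iterative
solver: every subset of the bound constraints is a candidate active
set, the equality-constrained KKT system is solved for each subset in
order of increasing size, and the first primal- and dual-feasible
solution is returned.  For strictly convex Q this is the unique global
minimiser.  Cost is O(2^K K^3), negligible for K <= ~15; in practice
the empty active set (all proportions positive) succeeds immediately
for most samples.

A symmetric ridge of ``1e-10 * trace(Q)/K`` is added when Q is
numerically singular (near-collinear designs).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._exceptions import SolverError, ValidationError

__all__ = ["SimplexQPProblem", "solve_simplex_qp"]

_SYM_TOL = 1e-10
_KKT_TOL = 1e-8


@dataclass
class SimplexQPProblem:
    """Quadratic program ``min 0.5 x'Qx + a'x`` on (part of) the simplex."""

    Q: np.ndarray
    a: np.ndarray
    equality_sum_constraint: bool = True
    lower_bound_zero: bool = True

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.a = np.asarray(self.a, dtype=float).ravel()
        K = self.a.size
        if self.Q.shape != (K, K):
            raise ValidationError(
                f"Q has shape {self.Q.shape}, expected ({K}, {K})"
            )
        asym = np.abs(self.Q - self.Q.T).max(initial=0.0)
        scale = max(np.abs(self.Q).max(initial=0.0), 1.0)
        if asym > _SYM_TOL * scale:
            raise ValidationError(
                f"Q is not symmetric (max asymmetry {asym:.3e})"
            )
        self.Q = 0.5 * (self.Q + self.Q.T)


def _solve_active_set(
    Q: np.ndarray, a: np.ndarray, active: tuple[int, ...], equality: bool
) -> tuple[np.ndarray, float] | None:
    """KKT solve with the given coordinates pinned to zero; None if singular."""
    K = a.size
    free = [j for j in range(K) if j not in active]
    if not free:
        return None
    nf = len(free)
    Qff = Q[np.ix_(free, free)]
    af = a[free]
    try:
        if equality:
            kkt = np.zeros((nf + 1, nf + 1))
            kkt[:nf, :nf] = Qff
            kkt[:nf, nf] = 1.0
            kkt[nf, :nf] = 1.0
            rhs = np.concatenate([-af, [1.0]])
            sol = np.linalg.solve(kkt, rhs)
            xf, lam = sol[:nf], sol[nf]
        else:
            xf = np.linalg.solve(Qff, -af)
            lam = 0.0
    except np.linalg.LinAlgError:
        return None
    x = np.zeros(K)
    x[free] = xf
    return x, lam


def _try_solve(problem: SimplexQPProblem) -> np.ndarray | None:
    Q, a = problem.Q, problem.a
    K = a.size
    equality = problem.equality_sum_constraint
    bounds = problem.lower_bound_zero
    if not bounds:
        res = _solve_active_set(Q, a, (), equality)
        if res is None:
            return None
        x, lam = res
        grad = Q @ x + a + lam
        if np.abs(grad).max(initial=0.0) > _KKT_TOL * max(1.0, np.abs(a).max()):
            return None
        return x
    max_active = K - 1 if equality else K
    for size in range(0, max_active + 1):
        for active in combinations(range(K), size):
            res = _solve_active_set(Q, a, active, equality)
            if res is None:
                continue
            x, lam = res
            if x.min(initial=0.0) < -1e-12:
                continue
            grad = Q @ x + a + lam
            scale = max(1.0, np.abs(a).max(initial=0.0))
            # stationarity on free coordinates
            free = [j for j in range(K) if j not in active]
            if np.abs(grad[free]).max(initial=0.0) > _KKT_TOL * scale:
                continue
            # dual feasibility: multipliers of active bounds non-negative
            if active and grad[list(active)].min() < -_KKT_TOL * scale:
                continue
            if equality and abs(x.sum() - 1.0) > _KKT_TOL:
                continue
            return np.where(np.abs(x) < 1e-15, 0.0, x)
    return None


def solve_simplex_qp(problem: SimplexQPProblem) -> np.ndarray:
    """Solve the constrained QP exactly; KKT residual <= 1e-8.

    Raises
    ------
    SolverError
        If no KKT point is found even after ridging Q (should not occur
        for PSD Q on the simplex).
    """
    x = _try_solve(problem)
    if x is not None:
        return x
    # PSD ridge for numerically singular Q, then retry
    K = problem.a.size
    ridge = 1e-10 * max(np.trace(problem.Q) / K, 1.0)
    ridged = SimplexQPProblem(
        Q=problem.Q + ridge * np.eye(K),
        a=problem.a,
        equality_sum_constraint=problem.equality_sum_constraint,
        lower_bound_zero=problem.lower_bound_zero,
    )
    x = _try_solve(ridged)
    if x is None:
        raise SolverError("no KKT point found for the constrained QP")
    return x
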
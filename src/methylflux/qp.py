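"""Dense convex quadratic programming for small flux models.

Solves  minimize ½ vᵀQv + cᵀv  subject to  A v = b,  lb ≤ v ≤ ub
with Q symmetric positive semidefinite.  Problems here are tiny (tens of
variables), so everything is dense linear algebra:

* the equality-constrained stationary point comes from the KKT block
  system solved with ``numpy.linalg.lstsq`` (rank-deficient A and
  singular Q are fine as long as the system is consistent);
* bounds are handled by a clamping active-set loop with multiplier
  checks, falling back to SLSQP (then re-polished through the exact KKT
  solve) if the loop does not settle.

Residuals reported to callers are always recomputed from the returned
vector, never taken from the solver's own bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["QPResult", "solve_qp", "EqualityInfeasible", "QPError"]

FEAS_TOL = 1e-9


class QPError(RuntimeError):
    pass


class EqualityInfeasible(QPError):
    """Equality constraints are mutually inconsistent (with the bounds)."""

    def __init__(self, message: str, residual: float = np.nan):
        super().__init__(message)
        self.residual = residual


@dataclass
class QPResult:
    v: np.ndarray
    eq_residual: float          # max |A v - b|, recomputed
    bound_violation: float      # max violation of lb/ub, recomputed
    objective: float
    active_lower: list[int] = field(default_factory=list)
    active_upper: list[int] = field(default_factory=list)
    iterations: int = 0
    used_fallback: bool = False


def _kkt_solve(
    Q: np.ndarray,
    c: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    fixed: dict[int, float],
) -> tuple[np.ndarray, float]:
    """Stationary point of the equality-constrained QP with some variables
    pinned at ``fixed`` values.  Returns (v, consistency residual of the
    KKT system restricted to the equality rows)."""
    n = Q.shape[0]
    free = np.array([i for i in range(n) if i not in fixed], dtype=int)
    v = np.zeros(n)
    for i, val in fixed.items():
        v[i] = val
    if free.size == 0:
        res = np.max(np.abs(A @ v - b)) if A.size else 0.0
        return v, float(res)
    Qff = Q[np.ix_(free, free)]
    Af = A[:, free] if A.size else np.zeros((0, free.size))
    # move fixed-variable contributions to the right-hand side
    if fixed:
        fixed_idx = np.array(sorted(fixed), dtype=int)
        xfix = np.array([fixed[i] for i in fixed_idx])
        rhs_lin = -(c[free] + Q[np.ix_(free, fixed_idx)] @ xfix)
        rhs_eq = b - A[:, fixed_idx] @ xfix if A.size else b
    else:
        rhs_lin = -c[free]
        rhs_eq = b
    m = Af.shape[0]
    K = np.zeros((free.size + m, free.size + m))
    K[: free.size, : free.size] = Qff
    K[: free.size, free.size:] = Af.T
    K[free.size:, : free.size] = Af
    rhs = np.concatenate([rhs_lin, rhs_eq])
    sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    v[free] = sol[: free.size]
    res = np.max(np.abs(A @ v - b)) if A.size else 0.0
    return v, float(res)


def _multipliers(
    Q: np.ndarray, c: np.ndarray, A: np.ndarray, v: np.ndarray, active: list[int]
) -> np.ndarray:
    """Bound multipliers mu_k = -(Qv + c + A^T lam)_k at the active set,
    with lam chosen by least squares on the free rows."""
    g = Q @ v + c
    n = Q.shape[0]
    free = np.array([i for i in range(n) if i not in active], dtype=int)
    if A.size:
        lam, *_ = np.linalg.lstsq(A[:, free].T, -g[free], rcond=None)
        mu = -(g + A.T @ lam)
    else:
        mu = -g
    return mu


def solve_qp(
    Q: np.ndarray,
    c: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    feas_tol: float = FEAS_TOL,
    max_iter: int = 200,
) -> QPResult:
    """Solve the bounded equality-constrained QP; raises
    :class:`EqualityInfeasible` when the equalities cannot be met."""
    Q = np.asarray(Q, dtype=float)
    c = np.asarray(c, dtype=float)
    A = np.asarray(A, dtype=float).reshape(-1, Q.shape[0])
    b = np.asarray(b, dtype=float).reshape(-1)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    n = Q.shape[0]
    if np.any(lb > ub):
        bad = [int(i) for i in np.where(lb > ub)[0]]
        raise EqualityInfeasible(f"empty bound interval for variable(s) {bad}")

    scale = max(1.0, float(np.max(np.abs(b))) if b.size else 1.0)

    # variables pinned by equal bounds are fixed from the start
    pinned = {int(i): float(lb[i]) for i in np.where(lb == ub)[0]}

    fixed = dict(pinned)
    used_fallback = False
    v = np.zeros(n)
    for it in range(1, max_iter + 1):
        v, eq_res = _kkt_solve(Q, c, A, b, fixed)
        if eq_res > feas_tol * scale:
            if len(fixed) == len(pinned):
                raise EqualityInfeasible(
                    "equality constraints are mutually inconsistent "
                    f"(residual {eq_res:.3g})",
                    residual=eq_res,
                )
            # infeasibility introduced by clamped bounds -> fall back
            used_fallback = True
            break
        viol_lo = lb - v
        viol_hi = v - ub
        worst = -1
        worst_viol = feas_tol * scale
        at_lower = True
        for i in range(n):
            if i in fixed:
                continue
            if viol_lo[i] > worst_viol:
                worst, worst_viol, at_lower = i, viol_lo[i], True
            if viol_hi[i] > worst_viol:
                worst, worst_viol, at_lower = i, viol_hi[i], False
        if worst >= 0:
            fixed[worst] = float(lb[worst] if at_lower else ub[worst])
            continue
        # feasible: check multipliers of clamped (non-pinned) bounds
        active = sorted(fixed)
        mu = _multipliers(Q, c, A, v, active)
        drop = None
        drop_val = -1e-7 * max(1.0, float(np.max(np.abs(Q @ v + c))))
        for i in active:
            if i in pinned:
                continue
            m_i = mu[i] if fixed[i] == lb[i] else -mu[i]
            if m_i < drop_val:
                drop, drop_val = i, m_i
        if drop is None:
            return _finalize(Q, c, A, b, lb, ub, v, fixed, it, used_fallback)
        del fixed[drop]
    else:
        used_fallback = True

    # ---- SLSQP fallback + exact polish -------------------------------
    from scipy.optimize import minimize

    v0, _ = _kkt_solve(Q, c, A, b, pinned)
    v0 = np.clip(v0, lb, ub)
    finite_lb = np.where(np.isfinite(lb), lb, None)
    finite_ub = np.where(np.isfinite(ub), ub, None)
    bounds = list(zip(finite_lb, finite_ub))
    cons = []
    if A.size:
        cons.append({"type": "eq", "fun": lambda x: A @ x - b, "jac": lambda x: A})
    res = minimize(
        lambda x: 0.5 * x @ Q @ x + c @ x,
        v0,
        jac=lambda x: Q @ x + c,
        bounds=bounds,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    v = res.x
    # polish: pin near-active bounds, re-solve the reduced KKT exactly
    fixed = dict(pinned)
    tol_active = 1e-6 * scale
    for i in range(n):
        if i in fixed:
            continue
        if np.isfinite(lb[i]) and v[i] - lb[i] < tol_active:
            fixed[i] = float(lb[i])
        elif np.isfinite(ub[i]) and ub[i] - v[i] < tol_active:
            fixed[i] = float(ub[i])
    v_pol, eq_res = _kkt_solve(Q, c, A, b, fixed)
    if (
        eq_res <= feas_tol * scale
        and np.all(v_pol >= lb - feas_tol * scale)
        and np.all(v_pol <= ub + feas_tol * scale)
        and 0.5 * v_pol @ Q @ v_pol + c @ v_pol
        <= 0.5 * v @ Q @ v + c @ v + 1e-12 * scale**2
    ):
        v = v_pol
    eq_res = float(np.max(np.abs(A @ v - b))) if A.size else 0.0
    if eq_res > 1e-6 * scale:
        raise EqualityInfeasible(
            "no feasible point for equalities within bounds "
            f"(residual {eq_res:.3g}); variables at bounds: "
            f"{_binding(v, lb, ub)}",
            residual=eq_res,
        )
    return _finalize(Q, c, A, b, lb, ub, v, fixed, max_iter, True)


def _binding(v: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> list[int]:
    out = []
    for i in range(v.size):
        if (np.isfinite(lb[i]) and abs(v[i] - lb[i]) < 1e-6) or (
            np.isfinite(ub[i]) and abs(v[i] - ub[i]) < 1e-6
        ):
            out.append(i)
    return out


def _finalize(Q, c, A, b, lb, ub, v, fixed, iterations, used_fallback) -> QPResult:
    eq_res = float(np.max(np.abs(A @ v - b))) if A.size else 0.0
    bviol = float(
        max(
            np.max(np.where(np.isfinite(lb), lb - v, -np.inf), initial=0.0),
            np.max(np.where(np.isfinite(ub), v - ub, -np.inf), initial=0.0),
        )
    )
    return QPResult(
        v=v,
        eq_residual=eq_res,
        bound_violation=bviol,
        objective=float(0.5 * v @ Q @ v + c @ v),
        active_lower=[i for i in sorted(fixed) if fixed[i] == lb[i]],
        active_upper=[i for i in sorted(fixed) if fixed[i] == ub[i]],
        iterations=iterations,
        used_fallback=used_fallback,
    )
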
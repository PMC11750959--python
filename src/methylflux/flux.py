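"""Daily-snapshot flux balance with a quadratic (min Σv²) objective.

Each sampling day is treated as an independent steady-state snapshot: the
internal metabolites obey ``S_int · v = 0`` while measured accumulation /
consumption rates enter as hard constraints on the corresponding exchange
reactions.  Among all flux distributions consistent with the data the
solver returns the one of minimal squared norm Σⱼ vⱼ² — the objective is
strictly convex, so the reported distribution is unique.

When the measured rates are mutually inconsistent with steady state
(noisy derivatives), a two-stage relaxation first minimises the squared
constraint violations and then minimises Σv² at that fixed minimal
violation; such solutions are flagged ``status="relaxed"``.

The *flux activity* of an internal metabolite m is the total production
Φ⁺(m) = Σⱼ max(Sₘⱼ vⱼ, 0) (equivalently total consumption Φ⁻); the two
coincide at steady state and are the quantity tracked through the
THF/SAM (one-carbon) cycle over the culture time course.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkError, ReactionNetwork
from .qp import EqualityInfeasible, solve_qp

__all__ = [
    "FluxConstraint",
    "FluxSolution",
    "FluxActivity",
    "solve_snapshot_fluxes",
    "flux_activity",
    "run_flux_timecourse",
]

logger = logging.getLogger(__name__)

STEADY_STATE_TOL = 1e-8


@dataclass(frozen=True)
class FluxConstraint:
    """A measured flux value for one reaction on one (day, condition).

    ``kind="equality"`` pins the flux at ``value``; ``kind="band"`` allows
    ``value ± tolerance``.  Units are mmol·gDW⁻¹·day⁻¹ throughout.
    """

    reaction_id: str
    value: float
    kind: str = "equality"
    tolerance: float = 0.0
    day: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("equality", "band"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if not math.isfinite(self.value):
            raise ValueError(f"constraint on {self.reaction_id!r}: non-finite value")
        if self.tolerance < 0:
            raise ValueError(f"constraint on {self.reaction_id!r}: tolerance < 0")

    def as_band(self, rel_tol: float) -> "FluxConstraint":
        """Convert to a band of half-width ``rel_tol·|value|``."""
        return FluxConstraint(
            self.reaction_id,
            self.value,
            kind="band",
            tolerance=abs(self.value) * rel_tol,
            day=self.day,
            condition=self.condition,
        )


@dataclass
class FluxSolution:
    fluxes: dict[str, float]
    day: int
    condition: str
    objective_value: float
    max_steady_state_residual: float
    constraint_residuals: dict[str, float]
    status: str  # optimal | relaxed | infeasible
    diagnostic: str = ""

    def vector(self, network: ReactionNetwork) -> np.ndarray:
        return np.array([self.fluxes[r] for r in network.reaction_ids])


@dataclass(frozen=True)
class FluxActivity:
    metabolite_id: str
    producing: float
    consuming: float
    day: int = 0
    condition: str = ""


def _constraint_arrays(
    network: ReactionNetwork, constraints: list[FluxConstraint]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(C, d) selector rows for equality constraints; bound tightenings for
    bands are applied directly to (lb, ub)."""
    n = len(network.reactions)
    lb, ub = network.bounds()
    rows, vals = [], []
    for con in constraints:
        j = network.reaction_index(con.reaction_id)
        if con.kind == "band" and con.tolerance > 0:
            lb[j] = max(lb[j], con.value - con.tolerance)
            ub[j] = min(ub[j], con.value + con.tolerance)
        else:
            e = np.zeros(n)
            e[j] = 1.0
            rows.append(e)
            vals.append(con.value)
    C = np.array(rows) if rows else np.zeros((0, n))
    d = np.array(vals) if vals else np.zeros(0)
    return C, d, lb, ub


def solve_snapshot_fluxes(
    network: ReactionNetwork,
    constraints: list[FluxConstraint],
    weights: np.ndarray | None = None,
    relative_tolerance: float = 0.0,
    feas_tol: float = 1e-9,
) -> FluxSolution:
    """Solve one steady-state snapshot under measured constraints.

    Parameters
    ----------
    weights
        Optional per-reaction positive weights for the objective
        Σⱼ wⱼ vⱼ² (sensitivity analysis); default all-ones.
    relative_tolerance
        If > 0, every equality constraint is converted to a band of
        half-width ``rel_tol·|value|`` before solving.
    """
    keys = {(c.day, c.condition) for c in constraints}
    if len(keys) > 1:
        raise ValueError(f"constraints span multiple (day, condition) keys: {keys}")
    day, condition = (constraints[0].day, constraints[0].condition) if constraints else (0, "")
    for con in constraints:
        network.reaction_index(con.reaction_id)  # raises on unknown id

    if relative_tolerance > 0:
        constraints = [
            c.as_band(relative_tolerance) if c.kind == "equality" else c
            for c in constraints
        ]

    n = len(network.reactions)
    S_int = network.S_internal
    C, d, lb, ub = _constraint_arrays(network, constraints)
    W = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(W <= 0):
        raise ValueError("objective weights must be positive")
    Q = 2.0 * np.diag(W)

    A = np.vstack([S_int, C])
    b = np.concatenate([np.zeros(S_int.shape[0]), d])

    status = "optimal"
    diagnostic = ""
    try:
        result = solve_qp(Q, np.zeros(n), A, b, lb, ub, feas_tol=feas_tol)
        v = result.v
    except EqualityInfeasible:
        status = "relaxed"
        try:
            v, diagnostic = _relaxed_solve(S_int, C, d, lb, ub, Q, feas_tol)
        except EqualityInfeasible as exc:
            return FluxSolution(
                fluxes={r: math.nan for r in network.reaction_ids},
                day=day,
                condition=condition,
                objective_value=math.nan,
                max_steady_state_residual=math.nan,
                constraint_residuals={},
                status="infeasible",
                diagnostic=str(exc),
            )

    ss_res = float(np.max(np.abs(S_int @ v))) if S_int.size else 0.0
    con_res = {
        c.reaction_id: float(v[network.reaction_index(c.reaction_id)] - c.value)
        for c in constraints
    }
    if status == "optimal" and ss_res > STEADY_STATE_TOL:
        status = "relaxed"
        diagnostic = f"steady-state residual {ss_res:.3g} above tolerance"
    return FluxSolution(
        fluxes=dict(zip(network.reaction_ids, (float(x) for x in v))),
        day=day,
        condition=condition,
        objective_value=float(np.sum(W * v * v)),
        max_steady_state_residual=ss_res,
        constraint_residuals=con_res,
        status=status,
        diagnostic=diagnostic,
    )


def _relaxed_solve(S_int, C, d, lb, ub, Q, feas_tol):
    """Two-stage relaxation: minimise ‖Cv−d‖² under steady state + bounds,
    then minimise the flux norm at the fixed minimal violation."""
    n = Q.shape[0]
    b0 = np.zeros(S_int.shape[0])
    # stage 1: Q1 = 2 CᵀC (singular PSD), linear term -2 Cᵀd
    stage1 = solve_qp(2.0 * C.T @ C, -2.0 * C.T @ d, S_int, b0, lb, ub, feas_tol=feas_tol)
    r_star = C @ stage1.v - d
    # stage 2: min flux norm with violations pinned at their minimum
    A2 = np.vstack([S_int, C])
    b2 = np.concatenate([b0, d + r_star])
    stage2 = solve_qp(Q, np.zeros(n), A2, b2, lb, ub, feas_tol=max(feas_tol, 1e-10))
    diag = (
        "constraints relaxed; residual L2 "
        f"{float(np.linalg.norm(r_star)):.6g}"
    )
    return stage2.v, diag


def flux_activity(
    solution: FluxSolution,
    network: ReactionNetwork,
    metabolite_id: str,
) -> FluxActivity:
    """Production/consumption totals through one metabolite.

    Contributions are signed: ``S[m,j]·vⱼ > 0`` counts as production even
    for a reversible reaction running backwards.
    """
    if solution.status == "infeasible":
        raise ValueError("cannot compute flux activity of an infeasible solution")
    i = network.metabolite_index(metabolite_id)
    v = solution.vector(network)
    contrib = network.S[i] * v
    producing = float(np.sum(contrib[contrib > 0]))
    consuming = float(-np.sum(contrib[contrib < 0]))
    return FluxActivity(metabolite_id, producing, consuming, solution.day, solution.condition)


def run_flux_timecourse(
    network: ReactionNetwork,
    constraints: list[FluxConstraint],
    metabolite_watchlist: list[str] | None = None,
    **solve_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, list[FluxSolution]]:
    """Solve one snapshot per (condition, day) and tabulate the results.

    Returns ``(flux_table, activity_table, solutions)`` where flux_table
    has columns condition/day/reaction_id/flux and activity_table has
    condition/day/metabolite_id/producing/consuming.
    """
    if not constraints:
        raise ValueError("no constraints given")
    watch = list(metabolite_watchlist or [])
    for m in watch:
        network.metabolite_index(m)
    groups: dict[tuple[str, int], list[FluxConstraint]] = {}
    for c in constraints:
        groups.setdefault((c.condition, c.day), []).append(c)

    flux_rows, act_rows, solutions = [], [], []
    for (condition, day) in sorted(groups):
        sol = solve_snapshot_fluxes(network, groups[(condition, day)], **solve_kwargs)
        solutions.append(sol)
        if sol.status == "infeasible":
            logger.warning(
                "snapshot (%s, day %s) infeasible: %s", condition, day, sol.diagnostic
            )
            continue
        for rid, val in sol.fluxes.items():
            flux_rows.append((condition, day, rid, val))
        for m in watch:
            act = flux_activity(sol, network, m)
            act_rows.append((condition, day, m, act.producing, act.consuming))
    flux_table = pd.DataFrame(flux_rows, columns=["condition", "day", "reaction_id", "flux"])
    activity_table = pd.DataFrame(
        act_rows, columns=["condition", "day", "metabolite_id", "producing", "consuming"]
    )
    return flux_table, activity_table, solutions
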
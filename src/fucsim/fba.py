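"""Flux balance analysis: LP solve, flux variability, and a brute-force oracle.

FBA predicts a steady-state flux distribution v maximizing a linear objective
c·v subject to mass balance S·v = 0 and bounds l ≤ v ≤ u. The optimum is
generically degenerate (many flux vectors share the optimal objective), so
biological claims should be made through :func:`flux_variability` ranges, not
through the particular vertex :func:`solve_fba` happens to return.

:func:`enumerate_vertices_oracle` exhaustively enumerates basic feasible
solutions of small networks (≤ 12 reactions, finite bounds) and serves as an
independent check on the LP solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy.optimize import linprog

from .model import ConstraintModel, ModelError, assemble_matrix

__all__ = [
    "FluxSolution",
    "FbaError",
    "OracleSizeError",
    "solve_fba",
    "flux_variability",
    "enumerate_vertices_oracle",
]

#: primal feasibility target for reported solutions
FEASIBILITY_TOL = 1e-9
#: relative slack applied to the objective floor in flux variability
FVA_RELATIVE_SLACK = 1e-6


class FbaError(ModelError):
    """Raised when an operation needs an optimal base solution and has none."""


class OracleSizeError(ModelError):
    """The exhaustive oracle refuses networks it cannot enumerate."""


@dataclass
class FluxSolution:
    """Outcome of one FBA solve.

    ``status`` is one of ``optimal``, ``infeasible``, ``unbounded``. For an
    optimal solution ``fluxes`` maps reaction id → flux (mmol·gDW⁻¹·h⁻¹) and
    ``residual`` is max |S·v| over metabolites.
    """

    status: str
    objective_value: float | None = None
    fluxes: dict[str, float] | None = None
    residual: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _lp_parts(model: ConstraintModel):
    S, met_ids, rxn_ids = assemble_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return S, met_ids, rxn_ids, bounds


def _run_lp(c, S, bounds, sense, A_ub=None, b_ub=None):
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(
        sign * np.asarray(c),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL},
    )
    return res


def solve_fba(
    model: ConstraintModel, objective: str | None = None, sense: str = "max"
) -> FluxSolution:
    """Maximize (or minimize) the flux of one reaction at steady state.

    Deterministic for a fixed model ordering: the HiGHS solver returns one
    optimal vertex reproducibly, but which vertex is an artifact of the
    ordering — use :func:`flux_variability` for claims about individual fluxes.
    """
    objective = objective or model.objective
    if objective is None:
        raise FbaError("no objective reaction given and model has none")
    rxn_ids = model.reaction_ids()
    if objective not in rxn_ids:
        raise FbaError(f"objective reaction '{objective}' not in model")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")

    S, _, rxn_ids, bounds = _lp_parts(model)
    c = np.zeros(len(rxn_ids))
    j = rxn_ids.index(objective)
    c[j] = 1.0
    res = _run_lp(c, S, bounds, sense)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxSolution(status="infeasible" if status == "infeasible" else status)
    v = np.asarray(res.x)
    residual = float(np.max(np.abs(S @ v))) if S.size else 0.0
    return FluxSolution(
        status="optimal",
        objective_value=float(v[j]),
        fluxes=dict(zip(rxn_ids, (float(x) for x in v))),
        residual=residual,
    )


def flux_variability(
    model: ConstraintModel,
    objective: str | None = None,
    fraction: float = 1.0,
    reactions: list[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Min/max flux of each reaction while holding the objective near optimum.

    The objective is constrained to ≥ ``fraction`` × its optimum, with a
    relative slack of 1e-6 so that a degenerate optimal face is explored
    rather than a single vertex. ``fraction`` 0 reproduces the unconstrained
    bounds-feasible ranges. Infeasibility of the base problem propagates as
    :class:`FbaError`.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    objective = objective or model.objective
    base = solve_fba(model, objective)
    if not base.optimal:
        raise FbaError(f"base FBA problem is {base.status}; no variability to compute")
    opt = base.objective_value

    S, _, rxn_ids, bounds = _lp_parts(model)
    n = len(rxn_ids)
    c_obj = np.zeros(n)
    c_obj[rxn_ids.index(objective)] = 1.0
    floor = fraction * opt - FVA_RELATIVE_SLACK * max(1.0, abs(opt))
    A_ub = -c_obj.reshape(1, -1)
    b_ub = np.array([-floor])

    targets = reactions if reactions is not None else list(rxn_ids)
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        k = rxn_ids.index(rid)
        e = np.zeros(n)
        e[k] = 1.0
        lo = _run_lp(e, S, bounds, "min", A_ub=A_ub, b_ub=b_ub)
        hi = _run_lp(e, S, bounds, "max", A_ub=A_ub, b_ub=b_ub)
        if lo.status != 0 or hi.status != 0:
            raise FbaError(f"variability subproblem for '{rid}' did not solve")
        vmin, vmax = float(lo.x[k]), float(hi.x[k])
        if vmin > vmax:  # solver jitter on a fixed flux
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rid] = (vmin, vmax)
    return ranges


def enumerate_vertices_oracle(
    model: ConstraintModel,
    objective: str | None = None,
    sense: str = "max",
    max_reactions: int = 12,
    tol: float = 1e-7,
) -> FluxSolution:
    """Exhaustive optimum of a small FBA problem, independent of any LP solver.

    Enumerates every basic solution of {S·v = 0, l ≤ v ≤ u}: with r = rank(S),
    each vertex fixes n − r coordinates at a bound and solves the remaining
    square system. All bounds must be finite (the polytope is then bounded, so
    a nonempty feasible set has a vertex and the optimum is attained at one).
    Refuses models with more than ``max_reactions`` reactions.
    """
    objective = objective or model.objective
    n = len(model.reactions)
    if n > max_reactions:
        raise OracleSizeError(
            f"oracle limited to {max_reactions} reactions, model has {n}"
        )
    S, _, rxn_ids, bounds = _lp_parts(model)
    if objective not in rxn_ids:
        raise FbaError(f"objective reaction '{objective}' not in model")
    if not all(np.isfinite(lb) and np.isfinite(ub) for lb, ub in bounds):
        raise OracleSizeError("oracle requires finite bounds on every reaction")
    j = rxn_ids.index(objective)
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])

    r = int(np.linalg.matrix_rank(S, tol=1e-9)) if S.size else 0
    n_fix = n - r
    better = (lambda a, b: a > b) if sense == "max" else (lambda a, b: a < b)

    best_val: float | None = None
    best_v: np.ndarray | None = None
    scale = max(1.0, float(np.max(np.abs(S)))) if S.size else 1.0

    for fixed in combinations(range(n), n_fix):
        free = [i for i in range(n) if i not in fixed]
        A_free = S[:, free]
        for pattern in product((0, 1), repeat=n_fix):
            v = np.zeros(n)
            for idx, side in zip(fixed, pattern):
                v[idx] = lb[idx] if side == 0 else ub[idx]
            rhs = -S[:, list(fixed)] @ v[list(fixed)] if n_fix else np.zeros(S.shape[0])
            if free:
                sol, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > tol * scale:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            val = float(v[j])
            if best_val is None or better(val, best_val):
                best_val = val
                best_v = v.copy()

    if best_val is None:
        return FluxSolution(status="infeasible")
    return FluxSolution(
        status="optimal",
        objective_value=best_val,
        fluxes=dict(zip(rxn_ids, (float(x) for x in best_v))),
        residual=float(np.max(np.abs(S @ best_v))) if S.size else 0.0,
    )
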
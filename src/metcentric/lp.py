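"""Flux balance analysis and flux variability analysis as linear programs.

FBA maximises (or minimises) a single reaction flux — typically the biomass
reaction — subject to steady state ``S·v = 0``, any scenario coupling rows,
and the flux bounds ``lb ≤ v ≤ ub``.  FVA then minimises and maximises each
reaction flux in turn under the extra constraint that the objective stays at
(a fraction γ of) its optimum, exposing the degeneracy of the optimal face.

LPs are solved with HiGHS dual simplex through scipy, so reported flux
distributions are basic (vertex) solutions and deterministic for a fixed
solver configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy
from scipy.optimize import linprog

from .model import ConstrainedProblem

__all__ = ["FluxDistribution", "FluxRange", "SolverError", "solve_fba", "run_fva"]

#: Feasibility/optimality tolerance handed to the LP solver.
SOLVER_TOL = 1e-9
#: Default cutoff below which a flux is considered inactive (mmol gDW^-1 h^-1).
ACTIVITY_THRESHOLD = 1e-12

_METHOD = "highs-ds"


class SolverError(RuntimeError):
    """Raised when an LP is infeasible or unbounded where a solution is required."""


@dataclass
class FluxDistribution:
    """One flux value per reaction, with objective value and solve status."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # "optimal" | "infeasible" | "unbounded"
    activity_threshold: float = ACTIVITY_THRESHOLD
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    def active_reactions(self) -> list[str]:
        return [r for r, v in self.fluxes.items() if abs(v) > self.activity_threshold]

    def as_array(self, model) -> np.ndarray:
        return np.array([self.fluxes[r.id] for r in model.reactions])


@dataclass
class FluxRange:
    """Per-reaction (min, max) flux at suboptimality fraction γ."""

    ranges: dict[str, tuple[float, float]]
    gamma: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]


def _metadata() -> dict:
    return {
        "solver": f"scipy-{_METHOD}",
        "scipy_version": scipy.__version__,
        "tolerance": SOLVER_TOL,
    }


def _linprog(c, A_eq, b_eq, lb, ub, A_ub=None, b_ub=None):
    return linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method=_METHOD,
        options={"primal_feasibility_tolerance": SOLVER_TOL,
                 "dual_feasibility_tolerance": SOLVER_TOL},
    )


def solve_fba(
    problem: ConstrainedProblem, minimize_total_flux: bool = False
) -> FluxDistribution:
    """Solve the FBA linear program for a constrained problem.

    Returns an optimal vertex solution; on infeasibility or unboundedness the
    status is reported and no flux vector is fabricated.

    ``minimize_total_flux`` adds a secondary objective: among the optimal
    solutions, return one with minimal total absolute flux.  This suppresses
    arbitrary internal loops in degenerate optima; it is off by default so
    that reported distributions are plain vertex solutions of the stated LP.
    """
    A_eq, b_eq = problem.equalities()
    c = problem.objective_vector()
    sign = -1.0 if problem.objective_sense == "max" else 1.0
    res = _linprog(sign * c, A_eq, b_eq, problem.lb, problem.ub)
    if res.status == 2:
        return FluxDistribution({}, None, "infeasible", metadata=_metadata())
    if res.status == 3:
        return FluxDistribution({}, None, "unbounded", metadata=_metadata())
    if not res.success:  # pragma: no cover - numerical failure
        raise SolverError(f"LP solver failure: {res.message}")
    opt = float(sign * res.fun)
    x = res.x
    meta = _metadata()
    if minimize_total_flux:
        x = _parsimonious(problem, A_eq, b_eq, c, sign, opt)
        meta["secondary_objective"] = "min total |v|"
    fluxes = {r.id: float(v) for r, v in zip(problem.model.reactions, x)}
    return FluxDistribution(fluxes, opt, "optimal", metadata=meta)


def _parsimonious(problem, A_eq, b_eq, c, sign, opt) -> np.ndarray:
    """Minimise total |v| at the (tolerance-relaxed) optimal objective,
    via the standard split v = v+ - v- into nonnegative components."""
    lb, ub = problem.lb, problem.ub
    n = len(lb)
    A2 = np.hstack([A_eq, -A_eq])
    lb2 = np.concatenate([np.maximum(lb, 0.0), np.maximum(-ub, 0.0)])
    ub2 = np.concatenate([np.maximum(ub, 0.0), np.maximum(-lb, 0.0)])
    pin = sign * np.concatenate([c, -c])[None, :]
    slack = 1e-9 * max(1.0, abs(opt))
    res = _linprog(
        np.ones(2 * n), A2, b_eq, lb2, ub2,
        A_ub=pin, b_ub=np.array([sign * opt + slack]),
    )
    if not res.success:  # pragma: no cover - the optimum is feasible
        raise SolverError("total-flux minimisation failed")
    return res.x[:n] - res.x[n:]


def run_fva(
    problem: ConstrainedProblem,
    gamma: float = 1.0,
    reactions: list[str] | None = None,
) -> FluxRange:
    """Flux variability analysis at suboptimality fraction ``gamma``.

    For each reaction the flux is minimised and maximised under the extra
    constraint ``objective ≥ γ·optimum`` (maximisation objectives; the
    inequality is flipped for minimisation).  The constraint system is built
    once and reused across all 2n LPs.
    """
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    base = solve_fba(problem)
    if base.status != "optimal":
        raise SolverError(f"FVA requires an FBA optimum; status: {base.status}")
    opt = base.objective_value
    A_eq, b_eq = problem.equalities()
    c_obj = problem.objective_vector()
    if problem.objective_sense == "max":
        A_ub = -c_obj[None, :]
        b_ub = np.array([-gamma * opt])
    else:
        A_ub = c_obj[None, :]
        b_ub = np.array([opt / gamma if opt > 0 else gamma * opt])
    model = problem.model
    rids = reactions if reactions is not None else [r.id for r in model.reactions]
    ranges: dict[str, tuple[float, float]] = {}
    for rid in rids:
        j = model.rxn_index[rid]
        e = np.zeros(model.n_reactions)
        e[j] = 1.0
        lo = _linprog(e, A_eq, b_eq, problem.lb, problem.ub, A_ub, b_ub)
        hi = _linprog(-e, A_eq, b_eq, problem.lb, problem.ub, A_ub, b_ub)
        if not (lo.success and hi.success):
            raise SolverError(f"FVA subproblem failed for {rid}")
        ranges[rid] = (float(lo.fun), float(-hi.fun))
    meta = _metadata()
    meta["gamma"] = gamma
    meta["objective_value"] = opt
    return FluxRange(ranges, gamma, meta)
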
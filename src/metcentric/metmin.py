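"""Metabolite flux minimisation and essentiality classification.

For each metabolite *i* the minimum producing flux sum compatible with
(sub)optimal growth is the LP

    minimise   sum_j s_ij^+ * v_j        (s_ij^+ = max(s_ij, 0))
    subject to S v = 0,  lb <= v <= ub,
               v_Biomass >= zeta * v_Biomass,opt   (0 < zeta <= 1)

posed over split nonnegative flux variables ``v = v+ − v−`` (each reversible
column of S duplicated and negated) so that the producing flux sum is a
linear function.  A metabolite whose minimum flux sum is zero is
nonessential for optimal growth; this is equivalent to the knockout
formulation in which all fluxes consuming the metabolite are constrained to
zero and the biomass optimum re-computed.  Unlike per-reaction fluxes, the
minimum flux sum is an LP optimum and therefore unaffected by FBA
degeneracy.

Carbon-flux ranking multiplies each minimum flux sum by the metabolite's
carbon count (from its formula, or an explicit override such as counting
only the two transferred carbons of acetyl-CoA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lp import ACTIVITY_THRESHOLD, SolverError, _linprog, solve_fba
from .model import ConstrainedProblem, ModelError, carbon_count
from .splitratio import all_flux_sums

__all__ = [
    "SplitVariableProblem",
    "MinFluxResult",
    "split_flux_variables",
    "minimize_metabolite_flux",
    "scan_metabolite_essentiality",
    "knockout_flux_sum_oracle",
    "rank_by_carbon_flux",
]

#: Minimum flux sum above which a metabolite is classified essential.
ESSENTIALITY_TOL = 1e-9
#: Relative slack on the optimal-biomass constraint, absorbing LP round-off.
BIOMASS_SLACK = 1e-9


@dataclass
class SplitVariableProblem:
    """The split-variable reformulation of a constrained problem.

    ``columns`` lists ``(reaction_id, sign)`` per split variable: the +1
    column is the original stoichiometric column with bounds
    ``[max(lb, 0), ub]``, the −1 column is negated with bounds
    ``[max(−ub, 0), −lb]``.  Variables constrained to zero (and their
    columns) are removed.
    """

    problem: ConstrainedProblem
    columns: list[tuple[str, int]]
    A_eq: np.ndarray
    b_eq: np.ndarray
    lb: np.ndarray
    ub: np.ndarray

    def map_back(self, x: np.ndarray) -> dict[str, float]:
        """Recombine split variables into original fluxes v = v+ − v−."""
        v = {r.id: 0.0 for r in self.problem.model.reactions}
        for val, (rid, sign) in zip(x, self.columns):
            v[rid] += sign * val
        return v


def split_flux_variables(problem: ConstrainedProblem) -> SplitVariableProblem:
    """Split each flux into nonnegative components v+ and v−.

    The corresponding columns of the equality system (S plus coupling rows)
    are duplicated and negated; bounds are mapped so that any split solution
    recombines to a feasible flux vector of the original problem.
    """
    A, b = problem.equalities()
    model = problem.model
    columns: list[tuple[str, int]] = []
    cols, lbs, ubs = [], [], []
    for j, r in enumerate(model.reactions):
        lo, hi = problem.lb[j], problem.ub[j]
        if hi > 0:  # forward component
            columns.append((r.id, +1))
            cols.append(A[:, j])
            lbs.append(max(lo, 0.0))
            ubs.append(hi)
        if lo < 0:  # reverse component
            columns.append((r.id, -1))
            cols.append(-A[:, j])
            lbs.append(max(-hi, 0.0))
            ubs.append(-lo)
    A_eq = np.column_stack(cols)
    return SplitVariableProblem(
        problem, columns, A_eq, b, np.array(lbs), np.array(ubs)
    )


def _producing_objective(split: SplitVariableProblem, metabolite_id: str):
    model = split.problem.model
    if metabolite_id not in model.met_index:
        raise ModelError(f"unknown metabolite {metabolite_id}")
    i = model.met_index[metabolite_id]
    c = np.empty(len(split.columns))
    for k, (rid, sign) in enumerate(split.columns):
        s = sign * model.S[i, model.rxn_index[rid]]
        c[k] = max(s, 0.0)
    return c


def _biomass_row(split: SplitVariableProblem) -> np.ndarray:
    row = np.zeros(len(split.columns))
    for k, (rid, sign) in enumerate(split.columns):
        if rid == split.problem.objective_id:
            row[k] = sign
    return row


def minimize_metabolite_flux(
    split: SplitVariableProblem,
    metabolite_id: str,
    zeta: float = 1.0,
    biomass_opt: float | None = None,
) -> float:
    """Minimum producing flux sum of a metabolite at biomass fraction zeta.

    ``biomass_opt`` is the FBA optimum of the underlying problem; it is
    computed on demand when not supplied.  The biomass constraint is
    ``v_Biomass >= zeta * (1 − slack) * v_Biomass,opt`` with a small relative
    slack absorbing LP round-off.
    """
    if not (0.0 < zeta <= 1.0):
        raise ValueError(f"zeta must be in (0, 1], got {zeta}")
    if biomass_opt is None:
        base = solve_fba(split.problem)
        if base.status != "optimal":
            raise SolverError(f"reference FBA is {base.status}")
        biomass_opt = base.objective_value
    c = _producing_objective(split, metabolite_id)
    bio = _biomass_row(split)
    floor = zeta * biomass_opt
    floor -= BIOMASS_SLACK * max(1.0, abs(floor))
    res = _linprog(
        c, split.A_eq, split.b_eq, split.lb, split.ub,
        A_ub=-bio[None, :], b_ub=np.array([-floor]),
    )
    if not res.success:
        raise SolverError(
            f"metabolite flux minimisation infeasible for {metabolite_id} "
            f"at zeta={zeta}"
        )
    return float(res.fun)


@dataclass
class MinFluxResult:
    metabolite_id: str
    min_flux_sum: float
    essential: bool
    carbon_count: int | None = None
    min_carbon_flux: float | None = None


def scan_metabolite_essentiality(
    problem: ConstrainedProblem,
    zeta: float = 1.0,
    threshold: float = ACTIVITY_THRESHOLD,
    essential_tol: float = ESSENTIALITY_TOL,
    metabolites: list[str] | None = None,
    all_metabolites: bool = False,
    carbon_overrides: dict[str, int] | None = None,
) -> list[MinFluxResult]:
    """Minimum flux sum and essentiality flag for a set of metabolites.

    By default the scan covers the metabolites carrying a flux in a
    reference FBA solution (``Phi > threshold``); pass
    ``all_metabolites=True`` or an explicit list to widen the scope.  One
    split-variable system is built once and reused across all LPs, which
    differ only in their objective.
    """
    base = solve_fba(problem)
    if base.status != "optimal":
        raise SolverError(f"reference FBA is {base.status}")
    if metabolites is None:
        if all_metabolites:
            metabolites = [m.id for m in problem.model.metabolites]
        else:
            phi = all_flux_sums(problem.model, base, threshold)
            metabolites = [m.id for m in problem.model.metabolites
                           if phi[m.id] > threshold]
    split = split_flux_variables(problem)
    results = []
    for mid in metabolites:
        min_phi = minimize_metabolite_flux(
            split, mid, zeta, biomass_opt=base.objective_value
        )
        nC = carbon_count(
            problem.model.metabolite(mid).formula, carbon_overrides, mid
        )
        results.append(
            MinFluxResult(
                mid,
                min_phi,
                essential=min_phi > essential_tol,
                carbon_count=nC,
                min_carbon_flux=None if nC is None else min_phi * nC,
            )
        )
    return results


def knockout_flux_sum_oracle(
    problem: ConstrainedProblem, metabolite_id: str
) -> float:
    """Biomass optimum with the metabolite removed from the network.

    Removal is modelled by restricting all fluxes that could consume the
    metabolite to zero: reactions consuming it in the forward direction get
    an upper bound of zero, reactions consuming it in reverse get a lower
    bound of zero (reversibles are clipped to their non-consuming
    direction).  Returns 0.0 when the knockout leaves no feasible flux
    state.
    """
    model = problem.model
    if metabolite_id not in model.met_index:
        raise ModelError(f"unknown metabolite {metabolite_id}")
    i = model.met_index[metabolite_id]
    lb, ub = problem.lb.copy(), problem.ub.copy()
    for j in range(model.n_reactions):
        s = model.S[i, j]
        if s < 0:  # forward flux consumes i
            ub[j] = min(ub[j], 0.0)
        elif s > 0:  # reverse flux consumes i
            lb[j] = max(lb[j], 0.0)
        if lb[j] > ub[j]:  # clipped past a forced flux: infeasible by bounds
            return 0.0
    ko = ConstrainedProblem(
        model, lb, ub, problem.coupling, problem.objective_id,
        problem.objective_sense,
    )
    res = solve_fba(ko)
    if res.status != "optimal":
        return 0.0
    return res.objective_value


def rank_by_carbon_flux(
    results: list[MinFluxResult],
) -> tuple[list[MinFluxResult], list[MinFluxResult]]:
    """Sort by descending minimum carbon flux (flux sum × carbon count).

    Returns ``(ranked, unknown)`` where ``unknown`` lists metabolites with
    no carbon count available.
    """
    known = [r for r in results if r.carbon_count is not None]
    unknown = [r for r in results if r.carbon_count is None]
    known.sort(key=lambda r: (-(r.min_carbon_flux or 0.0), r.metabolite_id))
    unknown.sort(key=lambda r: r.metabolite_id)
    return known, unknown
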
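"""Stoichiometric models, SBML and scenario input, chemical formulas.

The central container is :class:`StoichiometricModel`: metabolites, reactions
with signed stoichiometries, flux bounds in mmol gDW⁻¹ h⁻¹, and a biomass
objective.  The stoichiometric matrix ``S`` follows the standard convention:
``S[i, j]`` is positive when metabolite *i* appears on the product side of
reaction *j*, negative on the substrate side, zero otherwise.

Growth conditions are expressed as :class:`Scenario` objects (bound overrides,
linear flux-ratio couplings, objective selection) read from a line-oriented
text file, and applied to a model to yield a :class:`ConstrainedProblem` ready
for the LP layer.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "Scenario",
    "ConstrainedProblem",
    "ModelError",
    "FormulaError",
    "read_sbml",
    "write_sbml",
    "build_stoichiometric_matrix",
    "read_scenario",
    "apply_scenario",
    "carbon_count",
]

#: Default magnitude for unspecified flux bounds (mmol gDW^-1 h^-1).
DEFAULT_BOUND = 1000.0


class ModelError(ValueError):
    """Raised for structurally invalid models or inputs."""


class FormulaError(ValueError):
    """Raised for chemical formulas that cannot be parsed."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    formula: str | None = None


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    reversible: bool = False
    lb: float = 0.0
    ub: float = DEFAULT_BOUND

    def is_exchange(self) -> bool:
        """Structural exchange test: the reaction touches a single metabolite."""
        return len(self.stoichiometry) == 1


class StoichiometricModel:
    """A stoichiometric network with bounds and a biomass objective.

    Invariants checked at construction: unique metabolite/reaction ids,
    ``lb <= ub`` for every reaction, and every stoichiometry entry referring
    to a known metabolite.
    """

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        objective_reaction: str | None = None,
    ):
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.met_index = {m.id: k for k, m in enumerate(self.metabolites)}
        self.rxn_index = {r.id: k for k, r in enumerate(self.reactions)}
        if len(self.met_index) != len(self.metabolites):
            raise ModelError("duplicate metabolite ids")
        if len(self.rxn_index) != len(self.reactions):
            raise ModelError("duplicate reaction ids")
        for r in self.reactions:
            if r.lb > r.ub:
                raise ModelError(f"reaction {r.id}: lb {r.lb} > ub {r.ub}")
            for mid in r.stoichiometry:
                if mid not in self.met_index:
                    raise ModelError(
                        f"reaction {r.id} references unknown species {mid}"
                    )
        if objective_reaction is not None and objective_reaction not in self.rxn_index:
            raise ModelError(f"objective reaction {objective_reaction} not in model")
        self.objective_reaction = objective_reaction
        self._S: np.ndarray | None = None

    # -- basic views -------------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def S(self) -> np.ndarray:
        if self._S is None:
            self._S = build_stoichiometric_matrix(self)
        return self._S

    @property
    def lb(self) -> np.ndarray:
        return np.array([r.lb for r in self.reactions], dtype=float)

    @property
    def ub(self) -> np.ndarray:
        return np.array([r.ub for r in self.reactions], dtype=float)

    def metabolite(self, mid: str) -> Metabolite:
        try:
            return self.metabolites[self.met_index[mid]]
        except KeyError:
            raise ModelError(f"unknown metabolite {mid}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self.rxn_index[rid]]
        except KeyError:
            raise ModelError(f"unknown reaction {rid}") from None

    def exchange_reactions(self, id_prefix: str | None = None) -> list[str]:
        """Exchange reactions, identified structurally (single-metabolite
        stoichiometry) or, as a fallback, by id prefix (e.g. ``"EX_"``)."""
        if id_prefix is not None:
            return [r.id for r in self.reactions if r.id.startswith(id_prefix)]
        return [r.id for r in self.reactions if r.is_exchange()]


def build_stoichiometric_matrix(model: StoichiometricModel) -> np.ndarray:
    """Assemble the m×n matrix S from the reaction stoichiometries.

    Products carry positive coefficients, substrates negative ones, and
    entries for uninvolved metabolites are zero.
    """
    S = np.zeros((model.n_metabolites, model.n_reactions))
    for j, r in enumerate(model.reactions):
        for mid, coeff in r.stoichiometry.items():
            S[model.met_index[mid], j] = coeff
    return S


# ---------------------------------------------------------------------------
# SBML input / output
# ---------------------------------------------------------------------------

_NOTES_FORMULA = re.compile(r"FORMULA:\s*([A-Za-z0-9]+)")


def read_sbml(path: str | Path) -> StoichiometricModel:
    """Read an SBML Level 2/3 model into a :class:`StoichiometricModel`.

    Species flagged ``boundaryCondition`` are treated as unconstrained
    sources/sinks and dropped (they contribute no mass-balance row).  Flux
    bounds are taken from the fbc plugin when present, else from COBRA-style
    ``LOWER_BOUND``/``UPPER_BOUND`` kinetic-law parameters, else defaulted
    from reversibility.  Chemical formulas are read from fbc annotation or
    from ``FORMULA:`` tokens in species notes.
    """
    import libsbml

    path = Path(path)
    if not path.exists():
        raise ModelError(f"SBML file not found: {path}")
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelError(
            f"unparsable SBML {path.name}: line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelError(f"unparsable SBML {path.name}: no model element")

    boundary: set[str] = set()
    metabolites: list[Metabolite] = []
    for sp in sbml_model.getListOfSpecies():
        if sp.getBoundaryCondition():
            boundary.add(sp.getId())
            continue
        formula = None
        fbc_sp = sp.getPlugin("fbc")
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            formula = fbc_sp.getChemicalFormula()
        elif sp.isSetNotes():
            m = _NOTES_FORMULA.search(sp.getNotesString())
            if m:
                formula = m.group(1)
        metabolites.append(
            Metabolite(sp.getId(), sp.getName(), sp.getCompartment(), formula)
        )
    known = {m.id for m in metabolites}

    fbc = sbml_model.getPlugin("fbc")

    def _fbc_bound(rxn, which: str) -> float | None:
        plug = rxn.getPlugin("fbc")
        if plug is None:
            return None
        pid = plug.getLowerFluxBound() if which == "lb" else plug.getUpperFluxBound()
        if not pid:
            return None
        par = sbml_model.getParameter(pid)
        return par.getValue() if par is not None else None

    reactions: list[Reaction] = []
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}

        def _add(side_refs, sign: float, stoich=stoich, rxn=rxn):
            for ref in side_refs:
                sid = ref.getSpecies()
                if sid in boundary:
                    continue
                if sid not in known:
                    raise ModelError(
                        f"reaction {rxn.getId()} references unknown species {sid}"
                    )
                val = sign * ref.getStoichiometry()
                if sid in stoich:
                    warnings.warn(
                        f"reaction {rxn.getId()}: duplicate species {sid}, "
                        "coefficients summed"
                    )
                stoich[sid] = stoich.get(sid, 0.0) + val

        _add(rxn.getListOfReactants(), -1.0)
        _add(rxn.getListOfProducts(), +1.0)
        stoich = {k: v for k, v in stoich.items() if v != 0.0}

        rev = rxn.getReversible()
        lb = _fbc_bound(rxn, "lb")
        ub = _fbc_bound(rxn, "ub")
        kl = rxn.getKineticLaw()
        if lb is None and kl is not None and kl.getParameter("LOWER_BOUND"):
            lb = kl.getParameter("LOWER_BOUND").getValue()
        if ub is None and kl is not None and kl.getParameter("UPPER_BOUND"):
            ub = kl.getParameter("UPPER_BOUND").getValue()
        if lb is None:
            lb = -DEFAULT_BOUND if rev else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        reactions.append(
            Reaction(rxn.getId(), stoich, rxn.getName(), rev, float(lb), float(ub))
        )

    objective = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getObjective(fbc.getActiveObjectiveId()) or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective = obj.getFluxObjective(0).getReaction()
    if objective is None:
        warnings.warn(
            f"{path.name}: no objective declared in SBML; "
            "set one via the scenario file"
        )
    return StoichiometricModel(metabolites, reactions, objective)


def write_sbml(model: StoichiometricModel, path: str | Path) -> None:
    """Write the model as SBML Level 2v4 with COBRA-style bound parameters.

    Bounds go into per-reaction KineticLaw ``LOWER_BOUND``/``UPPER_BOUND``
    parameters and formulas into species notes, the dialect used by the
    published genome-scale *E. coli* reconstructions.
    """
    import libsbml

    doc = libsbml.SBMLDocument(2, 4)
    sm = doc.createModel("model")
    compartments = {m.compartment or "c" for m in model.metabolites}
    for cid in sorted(compartments):
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setSize(1.0)
    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name or m.id)
        sp.setCompartment(m.compartment or "c")
        sp.setInitialConcentration(0.0)
        if m.formula:
            sp.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>FORMULA: {m.formula}</p></body>"
            )
    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setName(r.name or r.id)
        rx.setReversible(r.reversible)
        for mid, coeff in sorted(r.stoichiometry.items()):
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coeff))
        kl = rx.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pname, val in (("LOWER_BOUND", r.lb), ("UPPER_BOUND", r.ub),
                           ("FLUX_VALUE", 0.0)):
            par = kl.createParameter()
            par.setId(pname)
            par.setValue(val)
            par.setUnits("mmol_per_gDW_per_hr")
    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """A growth condition: bound overrides, flux couplings, objective.

    ``bound_overrides`` maps reaction id to ``(lb, ub)`` where ``None`` keeps
    the model's value.  Each coupling ``(a, ri, b, rj)`` adds the equality
    ``a·v_ri − b·v_rj = 0``; a 1:1 ratio between two reactions is
    ``(1, ri, 1, rj)``.
    """

    bound_overrides: dict[str, tuple[float | None, float | None]] = field(
        default_factory=dict
    )
    coupling_constraints: list[tuple[float, str, float, str]] = field(
        default_factory=list
    )
    objective: tuple[str, str] | None = None  # (reaction id, "max"|"min")


def read_scenario(path: str | Path) -> Scenario:
    """Parse a scenario file.

    Line formats (``#`` starts a comment, blank lines ignored)::

        BOUND <reaction_id> <lb|-> <ub|->
        COUPLE <a> <reaction_i> <b> <reaction_j>
        OBJECTIVE <reaction_id> MAX|MIN
    """
    scen = Scenario()
    path = Path(path)
    if not path.exists():
        raise ModelError(f"scenario file not found: {path}")
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        try:
            if tok[0].upper() == "BOUND" and len(tok) == 4:
                lb = None if tok[2] == "-" else float(tok[2])
                ub = None if tok[3] == "-" else float(tok[3])
                scen.bound_overrides[tok[1]] = (lb, ub)
            elif tok[0].upper() == "COUPLE" and len(tok) == 5:
                a, b = float(tok[1]), float(tok[3])
                if not (np.isfinite(a) and np.isfinite(b)):
                    raise ValueError("non-finite coupling coefficient")
                scen.coupling_constraints.append((a, tok[2], b, tok[4]))
            elif tok[0].upper() == "OBJECTIVE" and len(tok) == 3:
                sense = tok[2].lower()
                if sense not in ("max", "min"):
                    raise ValueError(f"bad objective sense {tok[2]}")
                scen.objective = (tok[1], sense)
            else:
                raise ValueError(f"unrecognised directive {tok[0]}")
        except (ValueError, IndexError) as exc:
            raise ModelError(f"{path.name}:{lineno}: {exc}") from None
    return scen


@dataclass
class ConstrainedProblem:
    """A model with a scenario applied: effective bounds, coupling rows,
    and the selected objective.  ``lb``/``ub`` are effective bound vectors;
    couplings are kept symbolically and appended to ``S`` as extra equality
    rows by :meth:`equalities`."""

    model: StoichiometricModel
    lb: np.ndarray
    ub: np.ndarray
    coupling: list[tuple[float, str, float, str]]
    objective_id: str
    objective_sense: str = "max"

    def equalities(self) -> tuple[np.ndarray, np.ndarray]:
        """The full equality system: steady state Sv = 0 plus one row
        ``a·v_i − b·v_j = 0`` per coupling constraint."""
        rows = [self.model.S]
        for a, ri, b, rj in self.coupling:
            row = np.zeros((1, self.model.n_reactions))
            row[0, self.model.rxn_index[ri]] = a
            row[0, self.model.rxn_index[rj]] -= b
            rows.append(row)
        A = np.vstack(rows)
        return A, np.zeros(A.shape[0])

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(self.model.n_reactions)
        c[self.model.rxn_index[self.objective_id]] = 1.0
        return c


def apply_scenario(
    model: StoichiometricModel, scenario: Scenario | None = None
) -> ConstrainedProblem:
    """Apply a scenario to a model.

    Uptake limits live on exchange-reaction lower bounds (uptake is negative
    exchange flux: "uptake at most 11" means exchange ``lb = −11``); forced
    secretion is a positive exchange lower bound.  With an empty scenario the
    resulting problem is the raw model.
    """
    scenario = scenario or Scenario()
    lb, ub = model.lb.copy(), model.ub.copy()
    for rid, (olb, oub) in scenario.bound_overrides.items():
        if rid not in model.rxn_index:
            raise ModelError(f"scenario bound for unknown reaction {rid}")
        j = model.rxn_index[rid]
        if olb is not None:
            lb[j] = olb
        if oub is not None:
            ub[j] = oub
        if lb[j] > ub[j]:
            raise ModelError(f"scenario leaves {rid} with lb {lb[j]} > ub {ub[j]}")
    for a, ri, b, rj in scenario.coupling_constraints:
        for rid in (ri, rj):
            if rid not in model.rxn_index:
                raise ModelError(f"coupling references unknown reaction {rid}")
    if scenario.objective is not None:
        obj_id, sense = scenario.objective
        if obj_id not in model.rxn_index:
            raise ModelError(f"objective reaction {obj_id} not in model")
    elif model.objective_reaction is not None:
        obj_id, sense = model.objective_reaction, "max"
    else:
        raise ModelError("no objective: neither model nor scenario defines one")
    return ConstrainedProblem(
        model, lb, ub, list(scenario.coupling_constraints), obj_id, sense
    )


# ---------------------------------------------------------------------------
# Chemical formulas
# ---------------------------------------------------------------------------

_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*)")
#: Placeholder symbols used by genome-scale reconstructions for residues and
#: acyl-carrier groups; they contribute no countable carbon.
_PSEUDO_ELEMENTS = {"R", "X", "Z"}


def carbon_count(
    formula: str | None,
    overrides: dict[str, int] | None = None,
    metabolite_id: str | None = None,
) -> int | None:
    """Number of carbon atoms from a Hill-notation formula.

    An entry in ``overrides`` (keyed by metabolite id) wins over the formula —
    this is how conventions like counting only the two transferred carbons of
    acetyl-CoA are expressed.  Returns ``None`` (unknown) when no formula and
    no override are available.
    """
    if overrides and metabolite_id is not None and metabolite_id in overrides:
        return int(overrides[metabolite_id])
    if formula is None or formula == "":
        return None
    pos, count = 0, 0
    for m in _ELEMENT.finditer(formula):
        if m.start() != pos:
            break
        sym, num = m.group(1), int(m.group(2) or 1)
        if sym in _PSEUDO_ELEMENTS:
            warnings.warn(
                f"pseudo-element {sym} in formula of "
                f"{metabolite_id or formula} counted as zero carbons"
            )
        elif sym == "C":
            count += num
        pos = m.end()
    if pos != len(formula):
        who = f" for metabolite {metabolite_id}" if metabolite_id else ""
        raise FormulaError(f"malformed formula {formula!r}{who}")
    return count
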
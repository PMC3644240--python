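"""Synthetic stoichiometric models with analytically known behaviour.

Each fixture kind is a topological stand-in for a recurring motif of real
metabolic networks, small enough that its FBA optimum, flux sums, split
ratios, variability ranges, and essentiality pattern can be derived by hand:

``chain``
    a linear uptake→…→biomass path; every flux is forced to the uptake rate
    and every intermediate is essential.
``diamond``
    one branch-point metabolite feeding two capacity-limited consumers,
    giving exact split ratios (e.g. 60%/40%).
``cycle``
    a transamination-style loop (de-novo producer, cycle pair, two side
    consumers) for cycle-discounting arithmetic.
``bypass``
    two stoichiometrically equivalent parallel routes (a sedoheptulose-
    bypass analogue): route intermediates are nonessential and every route
    reaction has variability range [0, total] at γ = 1.
``mini_core``
    a ~13-reaction toy of central carbon metabolism (glycolysis/TCA-like
    topology with ATP, CO2, forced acetate-like secretion, maintenance
    drain and a biomass reaction) whose optimum is
    ``(2·uptake − acetate)/1.2``, derived from the steady-state balances.

Fixtures are generated programmatically (never stored) so sizes and ratios
can be property-tested; ``expected`` maps named analytic results for the
test suite.  ``random_steady_state_fluxes`` draws seeded flux vectors from
the null space of S for conservation-law tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .model import Metabolite, Reaction, Scenario, StoichiometricModel

__all__ = ["FixtureBundle", "make_fixture", "random_steady_state_fluxes"]


@dataclass
class FixtureBundle:
    model: StoichiometricModel
    scenario: Scenario
    expected: dict = field(default_factory=dict)


def _met(mid: str, formula: str | None = None) -> Metabolite:
    return Metabolite(mid, name=mid, compartment="c", formula=formula)


def make_fixture(kind: str, seed: int = 0, **params) -> FixtureBundle:
    """Build a fixture of the given kind (deterministic for a fixed seed)."""
    builders = {
        "chain": _chain,
        "diamond": _diamond,
        "cycle": _cycle,
        "bypass": _bypass,
        "mini_core": _mini_core,
    }
    if kind not in builders:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return builders[kind](seed=seed, **params)


def _chain(n: int = 3, uptake: float = 10.0, seed: int = 0) -> FixtureBundle:
    if n < 2:
        raise ValueError("chain needs at least 2 metabolites")
    mets = [_met(f"M{i}", f"C{i + 1}H2O") for i in range(n)]
    rxns = [Reaction("EX_M0", {"M0": -1.0}, lb=-uptake, ub=0.0)]
    for i in range(n - 1):
        rxns.append(Reaction(f"T{i}", {f"M{i}": -1.0, f"M{i + 1}": 1.0}))
    rxns.append(Reaction("BIOMASS", {f"M{n - 1}": -1.0}))
    model = StoichiometricModel(mets, rxns, "BIOMASS")
    fluxes = {"EX_M0": -uptake, "BIOMASS": uptake}
    fluxes.update({f"T{i}": uptake for i in range(n - 1)})
    return FixtureBundle(
        model,
        Scenario(),
        expected={
            "optimum": uptake,
            "fluxes": fluxes,
            "flux_sums": {m.id: uptake for m in mets},
            "essential": {m.id for m in mets},
            "nonessential": set(),
            "fva_point": True,  # min == max for every reaction
        },
    )


def _diamond(
    total: float = 10.0, left: float = 6.0, right: float = 4.0, seed: int = 0
) -> FixtureBundle:
    if left < 0 or right < 0 or total <= 0:
        raise ValueError("diamond needs nonnegative branch capacities")
    mets = [_met(m, "C3H6O3") for m in "ABCD"]
    rxns = [
        Reaction("EX_A", {"A": -1.0}, lb=-total, ub=0.0),
        Reaction("RB", {"A": -1.0, "B": 1.0}, ub=left),
        Reaction("RC", {"A": -1.0, "C": 1.0}, ub=right),
        Reaction("SB", {"B": -1.0, "D": 1.0}),
        Reaction("SC", {"C": -1.0, "D": 1.0}),
        Reaction("BIOMASS", {"D": -1.0}),
    ]
    model = StoichiometricModel(mets, rxns, "BIOMASS")
    opt = min(total, left + right)
    expected = {"optimum": opt}
    if total >= left + right:
        # capacity-limited: the split at A is forced and unique
        expected.update(
            split_A_consuming={"RB": left / opt, "RC": right / opt},
            flux_sums={"A": opt, "B": left, "C": right, "D": opt},
            essential={"A", "D"} | ({"B"} if left else set())
            | ({"C"} if right else set()),
        )
    return FixtureBundle(model, Scenario(), expected=expected)


def _cycle(
    denovo: float = 2.0, cycle_flux: float = 6.0, side: float = 1.0, seed: int = 0
) -> FixtureBundle:
    """Transamination-style cycle.

    X →(DENOVO) A; the pair GDH: A→G and TRANS: G→A (forced at
    ``cycle_flux``) forms the cycle; TCA: A→Q (forced at ``side``) and
    BIOMASS: G→ are the side consumers.
    """
    if denovo <= side:
        raise ValueError("denovo flux must exceed the side drain")
    mets = [_met(m, f) for m, f in
            [("X", "C5H8O5"), ("A", "C5H6O5"), ("G", "C5H9NO4"),
             ("Q", "C4H4O4")]]
    rxns = [
        Reaction("EX_X", {"X": -1.0}, lb=-denovo, ub=-denovo),
        Reaction("DENOVO", {"X": -1.0, "A": 1.0}),
        Reaction("GDH", {"A": -1.0, "G": 1.0}),
        Reaction("TRANS", {"G": -1.0, "A": 1.0}, lb=cycle_flux, ub=cycle_flux),
        Reaction("TCA", {"A": -1.0, "Q": 1.0}, lb=side, ub=side),
        Reaction("EX_Q", {"Q": -1.0}),
        Reaction("BIOMASS", {"G": -1.0}),
    ]
    model = StoichiometricModel(mets, rxns, "BIOMASS")
    gdh = denovo + cycle_flux - side
    phi_A = denovo + cycle_flux
    return FixtureBundle(
        model,
        Scenario(),
        expected={
            "optimum": denovo - side,
            "phi_A": phi_A,
            "split_A_producing": {"DENOVO": denovo / phi_A,
                                  "TRANS": cycle_flux / phi_A},
            "split_A_consuming": {"GDH": gdh / phi_A, "TCA": side / phi_A},
            # after discounting the TRANS/GDH cycle at A:
            "net_phi_A": denovo,
            "net_split_A_producing": {"DENOVO": 1.0},
            "net_split_A_consuming": {"GDH": (gdh - cycle_flux) / denovo,
                                      "TCA": side / denovo},
        },
    )


def _bypass(total: float = 10.0, seed: int = 0) -> FixtureBundle:
    mets = [_met(m, "C6H12O6") for m in "ABCZ"]
    rxns = [
        Reaction("EX_A", {"A": -1.0}, lb=-total, ub=0.0),
        Reaction("R1", {"A": -1.0, "B": 1.0}),
        Reaction("R2", {"B": -1.0, "Z": 1.0}),
        Reaction("R3", {"A": -1.0, "C": 1.0}),
        Reaction("R4", {"C": -1.0, "Z": 1.0}),
        Reaction("BIOMASS", {"Z": -1.0}),
    ]
    model = StoichiometricModel(mets, rxns, "BIOMASS")
    return FixtureBundle(
        model,
        Scenario(),
        expected={
            "optimum": total,
            "fva_ranges": {r: (0.0, total) for r in ("R1", "R2", "R3", "R4")},
            "essential": {"A", "Z"},
            "nonessential": {"B", "C"},
        },
    )


def _mini_core(
    uptake: float = 10.0,
    acetate: float = 1.0,
    maintenance: float = 1.0,
    seed: int = 0,
) -> FixtureBundle:
    """Central-carbon-metabolism toy; see module docstring.

    Steady-state balances give (with v6 = AKGDH flux driven to zero at the
    optimum because ATP is in surplus and the reaction wastes carbon):

        v_BIOMASS = (2·uptake − acetate) / 1.2

    The scenario applies the study conditions: uptake limit, forced
    acetate-like secretion, and the maintenance drain lives on the ATPM
    lower bound in the model itself.
    """
    mets = [
        _met("glc", "C6H12O6"),
        _met("g6p", "C6H13O9P"),
        _met("pyr", "C3H4O3"),
        _met("accoa", "C23H38N7O17P3S"),
        _met("oaa", "C4H4O5"),
        _met("akg", "C5H6O5"),
        _met("glu", "C5H9NO4"),
        _met("atp", "C10H16N5O13P3"),
        _met("co2", "CO2"),
        _met("ac", "C2H4O2"),
    ]
    rxns = [
        Reaction("EX_glc", {"glc": -1.0}, lb=-1000.0, ub=0.0),
        Reaction("PTS", {"glc": -1.0, "g6p": 1.0}),
        Reaction("EMP", {"g6p": -1.0, "pyr": 2.0, "atp": 2.0}),
        Reaction("PDH", {"pyr": -1.0, "accoa": 1.0, "co2": 1.0}),
        Reaction("CS", {"accoa": -1.0, "oaa": -1.0, "akg": 1.0, "co2": 1.0}),
        Reaction("AKGDH", {"akg": -1.0, "oaa": 1.0, "co2": 2.0, "atp": 2.0}),
        Reaction("PPC", {"pyr": -1.0, "co2": -1.0, "oaa": 1.0}),
        Reaction("GDH", {"akg": -1.0, "glu": 1.0}),
        Reaction("PTA", {"accoa": -1.0, "ac": 1.0, "atp": 1.0}),
        Reaction("EX_ac", {"ac": -1.0}),
        Reaction("EX_co2", {"co2": -1.0}),
        Reaction("ATPM", {"atp": -1.0}, lb=maintenance),
        Reaction("BIOMASS", {"glu": -0.5, "atp": -1.0, "oaa": -0.2}),
    ]
    model = StoichiometricModel(mets, rxns, "BIOMASS")
    scenario = Scenario(
        bound_overrides={"EX_glc": (-uptake, None), "EX_ac": (acetate, None)},
    )
    vb = (2 * uptake - acetate) / 1.2
    v_ppc = 0.7 * vb
    v_pdh = 0.5 * vb + acetate
    v_cs = 0.5 * vb
    fluxes = {
        "EX_glc": -uptake, "PTS": uptake, "EMP": uptake,
        "PDH": v_pdh, "CS": v_cs, "AKGDH": 0.0, "PPC": v_ppc,
        "GDH": 0.5 * vb, "PTA": acetate, "EX_ac": acetate,
        "EX_co2": v_pdh + v_cs - v_ppc, "ATPM": 2 * uptake + acetate - vb,
        "BIOMASS": vb,
    }
    return FixtureBundle(
        model,
        scenario,
        expected={
            "optimum": vb,
            "fluxes": fluxes,
            "phi_pyr": 2 * uptake,
            "split_pyr_consuming": {"PDH": v_pdh / (2 * uptake),
                                    "PPC": v_ppc / (2 * uptake)},
            "phi_atp": 2 * uptake + acetate,
            "essential": {m.id for m in mets},
            "nonessential": set(),
        },
    )


def random_steady_state_fluxes(
    model: StoichiometricModel, seed: int = 0, scale: float = 10.0
) -> dict[str, float]:
    """A seeded random flux vector satisfying S·v = 0 (bounds are ignored;
    the vector is for conservation-law tests, not an FBA solution)."""
    ns = null_space(model.S)
    if ns.shape[1] == 0:
        return {r.id: 0.0 for r in model.reactions}
    rng = np.random.default_rng(seed)
    v = ns @ rng.normal(scale=scale, size=ns.shape[1])
    return {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
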
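"""Split-ratio analysis: metabolite-centric balance sheets for a flux vector.

For a stoichiometric matrix ``S`` and flux vector ``v``, the partial flux of
reaction *j* at metabolite *i* is ``rho_ij = s_ij * v_j``.  Positive partial
fluxes produce the metabolite, negative ones consume it.  The flux sum

    Phi_i = sum_{j in P_i} rho_ij = -sum_{j in C_i} rho_ij

is the metabolite's turnover rate, and the split ratios ``rho_ij / Phi_i``
give the fraction produced or consumed via each reaction.  At steady state
the producing and consuming sides balance, so ratios on each side sum to one.

The module also supports discounting explicit metabolic cycles (e.g. a
transamination cycle) from a balance sheet and computing pathway-level net
balances per unit of a reference flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lp import ACTIVITY_THRESHOLD, FluxDistribution
from .model import ModelError, StoichiometricModel

__all__ = [
    "PartialFlux",
    "MetaboliteBalance",
    "compute_partial_fluxes",
    "compute_flux_sum",
    "compute_split_ratios",
    "metabolite_balance",
    "all_flux_sums",
    "compile_balance_sheet",
    "discount_cycle",
    "pathway_net_balance",
]

#: Relative tolerance for the steady-state balance check.
BALANCE_TOL = 1e-6


@dataclass
class PartialFlux:
    reaction_id: str
    value: float  # rho_ij, signed
    ratio: float | None = None  # |rho_ij| / Phi_i
    pathway: str | None = None


@dataclass
class MetaboliteBalance:
    """Flux sum and split ratios for one metabolite."""

    metabolite_id: str
    flux_sum: float
    producing: list[PartialFlux] = field(default_factory=list)
    consuming: list[PartialFlux] = field(default_factory=list)
    active: bool = True


def _flux_lookup(v) -> dict[str, float]:
    if isinstance(v, FluxDistribution):
        return v.fluxes
    return dict(v)


def compute_partial_fluxes(
    model: StoichiometricModel,
    v: FluxDistribution | dict[str, float],
    metabolite_id: str,
    threshold: float = ACTIVITY_THRESHOLD,
) -> tuple[list[PartialFlux], list[PartialFlux]]:
    """Producing (P_i) and consuming (C_i) partial fluxes of one metabolite.

    ``rho_ij = s_ij * v_j``; entries with ``|rho_ij| <= threshold`` are
    dropped.  A reversible reaction running backwards lands on the side its
    signed partial flux dictates.
    """
    if metabolite_id not in model.met_index:
        raise ModelError(f"unknown metabolite {metabolite_id}")
    fluxes = _flux_lookup(v)
    producing: list[PartialFlux] = []
    consuming: list[PartialFlux] = []
    for r in model.reactions:
        coeff = r.stoichiometry.get(metabolite_id)
        if coeff is None:
            continue
        rho = coeff * fluxes.get(r.id, 0.0)
        if abs(rho) <= threshold:
            continue
        (producing if rho > 0 else consuming).append(PartialFlux(r.id, rho))
    return producing, consuming


def compute_flux_sum(
    producing: list[PartialFlux],
    consuming: list[PartialFlux],
    tol: float = BALANCE_TOL,
) -> float:
    """Flux sum Phi_i from grouped partial fluxes.

    Asserts the steady-state identity (producing total equals consuming
    total); an imbalance beyond ``tol`` flags a non-steady-state vector.
    """
    pos = sum(p.value for p in producing)
    neg = -sum(c.value for c in consuming)
    scale = max(1.0, pos, neg)
    if abs(pos - neg) > tol * scale:
        raise ModelError(
            f"flux vector not at steady state: producing {pos:g} vs "
            f"consuming {neg:g}"
        )
    return pos


def compute_split_ratios(
    metabolite_id: str,
    producing: list[PartialFlux],
    consuming: list[PartialFlux],
    flux_sum: float,
    threshold: float = ACTIVITY_THRESHOLD,
) -> MetaboliteBalance:
    """Attach split ratios ``rho_ij / Phi_i`` and build the balance.

    A metabolite with ``Phi_i <= threshold`` is marked inactive and carries
    no ratios.
    """
    if flux_sum <= threshold:
        return MetaboliteBalance(metabolite_id, flux_sum, [], [], active=False)
    prod = [replace(p, ratio=p.value / flux_sum) for p in producing]
    cons = [replace(c, ratio=-c.value / flux_sum) for c in consuming]
    prod.sort(key=lambda p: (-p.ratio, p.reaction_id))
    cons.sort(key=lambda c: (-c.ratio, c.reaction_id))
    return MetaboliteBalance(metabolite_id, flux_sum, prod, cons)


def metabolite_balance(
    model: StoichiometricModel,
    v: FluxDistribution | dict[str, float],
    metabolite_id: str,
    threshold: float = ACTIVITY_THRESHOLD,
    tol: float = BALANCE_TOL,
) -> MetaboliteBalance:
    """Full balance for one metabolite: partial fluxes, flux sum, ratios."""
    producing, consuming = compute_partial_fluxes(model, v, metabolite_id, threshold)
    phi = compute_flux_sum(producing, consuming, tol)
    return compute_split_ratios(metabolite_id, producing, consuming, phi, threshold)


def all_flux_sums(
    model: StoichiometricModel,
    v: FluxDistribution | dict[str, float],
    threshold: float = ACTIVITY_THRESHOLD,
) -> dict[str, float]:
    """Phi_i for every metabolite (vectorised over S)."""
    fluxes = _flux_lookup(v)
    varr = np.array([fluxes.get(r.id, 0.0) for r in model.reactions])
    rho = model.S * varr[None, :]
    rho[np.abs(rho) <= threshold] = 0.0
    pos = np.where(rho > 0, rho, 0.0).sum(axis=1)
    return {m.id: float(pos[i]) for i, m in enumerate(model.metabolites)}


def compile_balance_sheet(
    model: StoichiometricModel,
    v: FluxDistribution | dict[str, float],
    metabolite_id: str,
    annotations: dict[str, str] | None = None,
    merge_groups: dict[str, list[str]] | None = None,
    threshold: float = ACTIVITY_THRESHOLD,
) -> pd.DataFrame:
    """Rendered balance sheet: one row per reaction (or merged group).

    Columns: side, reaction_id, pathway, partial_flux, ratio_percent.  Rows
    are sorted by descending ratio within the producing block, then the
    consuming block.  ``annotations`` maps reaction id to a pathway label
    ("unassigned" otherwise); ``merge_groups`` maps a group label to member
    reaction ids, collapsing them into one row whose ratio is the member sum.
    """
    balance = metabolite_balance(model, v, metabolite_id, threshold)
    annotations = annotations or {}
    merge_groups = merge_groups or {}
    member_to_group = {
        rid: label for label, rids in merge_groups.items() for rid in rids
    }

    rows = []
    for side, entries in (("producing", balance.producing),
                          ("consuming", balance.consuming)):
        merged: dict[str, dict] = {}
        order: list[str] = []
        for e in entries:
            key = member_to_group.get(e.reaction_id, e.reaction_id)
            if key not in merged:
                merged[key] = {
                    "side": side,
                    "reaction_id": key,
                    "pathway": annotations.get(e.reaction_id, "unassigned"),
                    "partial_flux": 0.0,
                    "ratio_percent": 0.0,
                }
                order.append(key)
            merged[key]["partial_flux"] += e.value
            merged[key]["ratio_percent"] += (e.ratio or 0.0) * 100.0
        block = sorted(
            (merged[k] for k in order),
            key=lambda r: (-r["ratio_percent"], r["reaction_id"]),
        )
        rows.extend(block)
    df = pd.DataFrame(
        rows, columns=["side", "reaction_id", "pathway", "partial_flux",
                       "ratio_percent"]
    )
    df["ratio_percent"] = df["ratio_percent"].round(2)
    return df


def discount_cycle(
    balance: MetaboliteBalance,
    cycle_producers: set[str],
    cycle_consumers: set[str],
    tol: float = BALANCE_TOL,
) -> MetaboliteBalance:
    """Net balance after removing an explicit cycle through the metabolite.

    The cycle flux ``c`` (sum of partial fluxes over ``cycle_producers``) is
    removed entirely from the producing side and subtracted from the
    ``cycle_consumers`` proportionally to their partial fluxes; the flux sum
    is recomputed and ratios renormalised.  The cycle cannot absorb more
    than it feeds: ``c`` must not exceed the total consumption via
    ``cycle_consumers``.
    """
    if not cycle_producers and not cycle_consumers:
        return balance
    prod_ids = {p.reaction_id for p in balance.producing}
    cons_ids = {c.reaction_id for c in balance.consuming}
    if not set(cycle_producers) <= prod_ids:
        raise ModelError(
            f"cycle producers {set(cycle_producers) - prod_ids} not on the "
            f"producing side of {balance.metabolite_id}"
        )
    if not set(cycle_consumers) <= cons_ids:
        raise ModelError(
            f"cycle consumers {set(cycle_consumers) - cons_ids} not on the "
            f"consuming side of {balance.metabolite_id}"
        )
    c = sum(p.value for p in balance.producing if p.reaction_id in cycle_producers)
    absorb = -sum(
        e.value for e in balance.consuming if e.reaction_id in cycle_consumers
    )
    if c > absorb * (1 + tol) + tol:
        raise ModelError(
            f"cycle through {balance.metabolite_id} cannot absorb more than "
            f"it feeds (feeds {c:g}, absorbs {absorb:g})"
        )
    producing = [p for p in balance.producing if p.reaction_id not in cycle_producers]
    consuming = []
    for e in balance.consuming:
        if e.reaction_id in cycle_consumers:
            value = e.value * (1.0 - c / absorb) if absorb > 0 else e.value
            if abs(value) <= ACTIVITY_THRESHOLD:
                continue
            consuming.append(PartialFlux(e.reaction_id, value, pathway=e.pathway))
        else:
            consuming.append(PartialFlux(e.reaction_id, e.value, pathway=e.pathway))
    phi = compute_flux_sum(producing, consuming, tol)
    return compute_split_ratios(balance.metabolite_id, producing, consuming, phi)


def pathway_net_balance(
    model: StoichiometricModel,
    v: FluxDistribution | dict[str, float],
    reaction_set: set[str],
    metabolite_ids: list[str],
    reference_reaction: str,
    threshold: float = ACTIVITY_THRESHOLD,
) -> dict[str, tuple[float, float, float]]:
    """Net pathway balance per unit of a reference flux.

    For each metabolite, ``produced`` is the sum of its positive partial
    fluxes restricted to ``reaction_set`` and ``consumed`` the corresponding
    negative sum, both divided by the magnitude of the reference reaction's
    flux (e.g. molecules of ATP per molecule of glucose taken up); ``net``
    is produced − consumed.
    """
    if not reaction_set:
        return {m: (0.0, 0.0, 0.0) for m in metabolite_ids}
    fluxes = _flux_lookup(v)
    ref = abs(fluxes.get(reference_reaction, 0.0))
    if ref <= threshold:
        raise ModelError(f"reference flux {reference_reaction} is zero")
    out = {}
    for mid in metabolite_ids:
        producing, consuming = compute_partial_fluxes(model, v, mid, threshold)
        produced = sum(p.value for p in producing if p.reaction_id in reaction_set)
        consumed = -sum(c.value for c in consuming if c.reaction_id in reaction_set)
        out[mid] = (produced / ref, consumed / ref, (produced - consumed) / ref)
    return out
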
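"""Split ratios, flux sums, balance sheets, cycle discounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metcentric import (
    Metabolite,
    ModelError,
    Reaction,
    StoichiometricModel,
    compile_balance_sheet,
    compute_flux_sum,
    compute_partial_fluxes,
    discount_cycle,
    make_fixture,
    metabolite_balance,
    pathway_net_balance,
    random_steady_state_fluxes,
)
from conftest import solve_kind
from oracles import partial_fluxes_brute_force


class TestPartialFluxes:
    def test_single_producer_single_consumer(self):
        _, problem, fd = solve_kind("chain", n=3, uptake=10.0)
        prod, cons = compute_partial_fluxes(problem.model, fd, "M1")
        assert {(p.reaction_id, p.value) for p in prod} == {("T0", 10.0)}
        assert {(c.reaction_id, c.value) for c in cons} == {("T1", -10.0)}

    def test_stoichiometric_weighting(self):
        """Reaction A -> 2B at flux 3 contributes +6 to B."""
        model = StoichiometricModel(
            [Metabolite("A"), Metabolite("B")],
            [Reaction("R", {"A": -1.0, "B": 2.0})],
        )
        prod, cons = compute_partial_fluxes(model, {"R": 3.0}, "B")
        assert prod[0].value == 6.0
        prod, cons = compute_partial_fluxes(model, {"R": 3.0}, "A")
        assert cons[0].value == -3.0

    def test_reversible_reaction_lands_on_signed_side(self):
        """Backward flux through A -> B produces A and consumes B."""
        model = StoichiometricModel(
            [Metabolite("A"), Metabolite("B")],
            [Reaction("R", {"A": -1.0, "B": 1.0}, reversible=True, lb=-10)],
        )
        prod, cons = compute_partial_fluxes(model, {"R": -4.0}, "A")
        assert prod[0].value == 4.0
        prod, cons = compute_partial_fluxes(model, {"R": -4.0}, "B")
        assert cons[0].value == -4.0

    def test_matches_brute_force_on_random_vectors(self, bundle):
        """Grouping equals a double loop over all (i, j) pairs."""
        for seed in range(5):
            v = random_steady_state_fluxes(bundle.model, seed=seed)
            oracle = partial_fluxes_brute_force(bundle.model, v)
            for met in bundle.model.metabolites:
                prod, cons = compute_partial_fluxes(bundle.model, v, met.id)
                assert {p.reaction_id: p.value for p in prod} == pytest.approx(
                    oracle[met.id][0]
                )
                assert {c.reaction_id: c.value for c in cons} == pytest.approx(
                    oracle[met.id][1]
                )

    def test_unknown_metabolite_rejected(self):
        bundle = make_fixture("chain")
        with pytest.raises(ModelError):
            compute_partial_fluxes(bundle.model, {}, "NOPE")


class TestFluxSum:
    def test_flux_sum_equals_producing_total(self, solved):
        bundle, problem, fd = solved
        for met in bundle.model.metabolites:
            prod, cons = compute_partial_fluxes(bundle.model, fd, met.id)
            phi = compute_flux_sum(prod, cons)
            assert phi == pytest.approx(sum(p.value for p in prod))
            assert phi == pytest.approx(-sum(c.value for c in cons), abs=1e-6)

    def test_inactive_metabolite_has_zero_flux_sum(self):
        bundle = make_fixture("chain")
        bal = metabolite_balance(bundle.model, {r.id: 0.0 for r in
                                                bundle.model.reactions}, "M0")
        assert bal.flux_sum == 0.0
        assert not bal.active

    def test_imbalanced_vector_rejected(self):
        """A vector violating steady state is flagged, not silently summed."""
        bundle = make_fixture("chain")
        with pytest.raises(ModelError, match="steady state"):
            metabolite_balance(bundle.model, {"T0": 5.0, "T1": 1.0}, "M1")


class TestSplitRatios:
    def test_forced_sixty_forty_split(self):
        bundle, problem, fd = solve_kind("diamond", total=10, left=6, right=4)
        bal = metabolite_balance(bundle.model, fd, "A")
        ratios = {c.reaction_id: c.ratio for c in bal.consuming}
        assert ratios == pytest.approx({"RB": 0.6, "RC": 0.4})

    def test_single_producer_single_consumer_is_100_percent(self):
        _, problem, fd = solve_kind("chain")
        bal = metabolite_balance(problem.model, fd, "M1")
        assert bal.producing[0].ratio == pytest.approx(1.0)
        assert bal.consuming[0].ratio == pytest.approx(1.0)

    def test_ratio_sides_sum_to_one(self, solved):
        bundle, problem, fd = solved
        for met in bundle.model.metabolites:
            bal = metabolite_balance(bundle.model, fd, met.id)
            if not bal.active:
                continue
            assert sum(p.ratio for p in bal.producing) == pytest.approx(1, abs=1e-6)
            assert sum(c.ratio for c in bal.consuming) == pytest.approx(1, abs=1e-6)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        left=st.floats(min_value=0.1, max_value=50),
        right=st.floats(min_value=0.1, max_value=50),
    )
    def test_capacity_forced_split_ratio_property(self, left, right):
        """For any branch capacities, the consuming split at the branch
        metabolite is left:(left+right) when uptake is not limiting."""
        bundle, problem, fd = solve_kind(
            "diamond", total=left + right + 1.0, left=left, right=right
        )
        bal = metabolite_balance(bundle.model, fd, "A")
        ratios = {c.reaction_id: c.ratio for c in bal.consuming}
        assert ratios["RB"] == pytest.approx(left / (left + right), rel=1e-6)
        assert ratios["RC"] == pytest.approx(right / (left + right), rel=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_ratios_invariant_under_flux_scaling(self, scale):
        bundle, problem, fd = solve_kind("mini_core")
        base = metabolite_balance(bundle.model, fd, "pyr")
        scaled_v = {rid: scale * v for rid, v in fd.fluxes.items()}
        scaled = metabolite_balance(bundle.model, scaled_v, "pyr")
        for b, s in zip(base.consuming, scaled.consuming):
            assert b.reaction_id == s.reaction_id
            assert b.ratio == pytest.approx(s.ratio, rel=1e-9)


class TestBalanceSheet:
    def test_annotations_and_sorting(self):
        bundle, problem, fd = solve_kind("mini_core")
        ann = {"PDH": "TCA feed", "PPC": "anaplerotic"}
        df = compile_balance_sheet(bundle.model, fd, "pyr", annotations=ann)
        cons = df[df.side == "consuming"].reset_index()
        # descending ratio order: PPC (55.42%) before PDH (44.58%)
        assert list(cons.reaction_id) == ["PPC", "PDH"]
        assert list(cons.pathway) == ["anaplerotic", "TCA feed"]
        assert cons.ratio_percent.sum() == pytest.approx(100.0, abs=0.01)

    def test_missing_annotations_marked_unassigned(self):
        bundle, problem, fd = solve_kind("mini_core")
        df = compile_balance_sheet(bundle.model, fd, "pyr")
        assert set(df.pathway) == {"unassigned"}

    def test_merged_group_ratio_is_member_sum(self):
        bundle, problem, fd = solve_kind("mini_core")
        plain = compile_balance_sheet(bundle.model, fd, "pyr")
        merged = compile_balance_sheet(
            bundle.model, fd, "pyr",
            merge_groups={"pyruvate drains (2 reactions)": ["PDH", "PPC"]},
        )
        cons = merged[merged.side == "consuming"]
        assert len(cons) == 1
        assert cons.iloc[0].reaction_id == "pyruvate drains (2 reactions)"
        expected = plain[plain.side == "consuming"].ratio_percent.sum()
        assert cons.iloc[0].ratio_percent == pytest.approx(expected, abs=0.01)


class TestDiscountCycle:
    def test_cycle_fixture_hand_arithmetic(self):
        """Removing the forced loop leaves the hand-computed net balance."""
        bundle, problem, fd = solve_kind(
            "cycle", denovo=2.0, cycle_flux=6.0, side=1.0
        )
        bal = metabolite_balance(bundle.model, fd, "A")
        assert bal.flux_sum == pytest.approx(8.0)
        net = discount_cycle(bal, {"TRANS"}, {"GDH"})
        assert net.flux_sum == pytest.approx(2.0)
        assert {p.reaction_id: p.ratio for p in net.producing} == pytest.approx(
            {"DENOVO": 1.0}
        )
        assert {c.reaction_id: c.ratio for c in net.consuming} == pytest.approx(
            {"GDH": 0.5, "TCA": 0.5}
        )

    def test_empty_cycle_is_identity(self):
        bundle, problem, fd = solve_kind("cycle")
        bal = metabolite_balance(bundle.model, fd, "A")
        same = discount_cycle(bal, set(), set())
        assert same.flux_sum == bal.flux_sum
        assert len(same.producing) == len(bal.producing)

    def test_mass_conservation_of_discount(self):
        """net Phi = Phi - c simultaneously on both sides."""
        bundle, problem, fd = solve_kind("cycle", denovo=3.0, cycle_flux=5.0,
                                         side=1.5)
        bal = metabolite_balance(bundle.model, fd, "A")
        net = discount_cycle(bal, {"TRANS"}, {"GDH"})
        c = 5.0
        assert net.flux_sum == pytest.approx(bal.flux_sum - c)
        assert sum(p.value for p in net.producing) == pytest.approx(
            bal.flux_sum - c
        )
        assert -sum(e.value for e in net.consuming) == pytest.approx(
            bal.flux_sum - c
        )

    def test_cycle_cannot_absorb_more_than_it_feeds(self):
        bundle, problem, fd = solve_kind("cycle")
        bal = metabolite_balance(bundle.model, fd, "A")
        # TCA only consumes 1.0 but the TRANS loop feeds 6.0
        with pytest.raises(ModelError, match="absorb"):
            discount_cycle(bal, {"TRANS"}, {"TCA"})

    def test_two_interleaved_cycles_commute(self):
        """Discounting two disjoint cycles gives the same net balance in
        either order."""
        bundle, problem, fd = solve_kind(
            "cycle", denovo=4.0, cycle_flux=6.0, side=1.0
        )
        # split the forced consumer into two conceptual cycles sharing GDH
        bal = metabolite_balance(bundle.model, fd, "A")
        a = discount_cycle(discount_cycle(bal, {"TRANS"}, {"GDH"}), set(), set())
        b = discount_cycle(discount_cycle(bal, set(), set()), {"TRANS"}, {"GDH"})
        assert a.flux_sum == pytest.approx(b.flux_sum)
        assert {c.reaction_id: c.ratio for c in a.consuming} == pytest.approx(
            {c.reaction_id: c.ratio for c in b.consuming}
        )


class TestPathwayNetBalance:
    def test_glycolysis_style_net_yield(self):
        """ATP yield of the uptake->pyruvate segment per glucose analogue."""
        bundle, problem, fd = solve_kind("mini_core", uptake=10.0)
        out = pathway_net_balance(
            bundle.model, fd, {"PTS", "EMP"}, ["atp", "pyr", "g6p"], "EX_glc"
        )
        produced, consumed, net = out["atp"]
        assert produced == pytest.approx(2.0)  # 2 ATP per glucose in EMP
        assert consumed == pytest.approx(0.0)
        assert net == pytest.approx(2.0)
        assert out["pyr"][2] == pytest.approx(2.0)
        assert out["g6p"][2] == pytest.approx(0.0)  # internal intermediate

    def test_empty_reaction_set_gives_zeros(self):
        bundle, problem, fd = solve_kind("mini_core")
        out = pathway_net_balance(bundle.model, fd, set(), ["atp"], "EX_glc")
        assert out["atp"] == (0.0, 0.0, 0.0)

    def test_single_reaction_set_equals_its_partials(self):
        bundle, problem, fd = solve_kind("mini_core")
        out = pathway_net_balance(bundle.model, fd, {"EMP"}, ["atp"], "EX_glc")
        assert out["atp"][0] == pytest.approx(2.0 * 10.0 / 10.0)

    def test_zero_reference_flux_rejected(self):
        bundle, problem, fd = solve_kind("mini_core")
        with pytest.raises(ModelError, match="zero"):
            pathway_net_balance(bundle.model, fd, {"EMP"}, ["atp"], "AKGDH")
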
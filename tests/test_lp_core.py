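"""Constraint assembly and LP solution correctness."""

import dataclasses

import numpy as np
import pytest

import foodbanklp as fb
from foodbanklp import lp_core
from foodbanklp.datamodel import ValidationError

from conftest import make_tiny_instance, tiny_closed_form


class TestObjective:
    def test_price_and_penalty_coefficients(self, madrid):
        obj = lp_core.build_objective(madrid)
        assert obj[("c", "cereal")] == pytest.approx(2.70)
        assert obj[("cns", "men 19-30", "protein")] == pytest.approx(1000.0)
        # supplied-mass and surplus variables carry no cost
        assert ("s", "cereal", "men 19-30") not in obj
        assert ("e", "cereal") not in obj


class TestNutrientConstraints:
    def test_rhs_is_requirement_times_effective_headcount(self):
        inst = make_tiny_instance(requirement_protein=0.322, headcount=10.0)
        rows = lp_core.build_nutrient_constraints(inst)
        protein = next(r for r in rows if "protein" in r.tag)
        assert protein.sense == ">="
        assert protein.rhs == pytest.approx(3.22)
        assert protein.coeffs[("s", "pulses", "women 19-30")] == pytest.approx(
            0.179292
        )
        assert protein.coeffs[("cns", "women 19-30", "protein")] == 1.0

    def test_minimal_supply_for_unit_protein(self):
        # 1 kg of protein from a 179.292 g/kg food needs 5.5776 kg of food
        inst = make_tiny_instance(requirement_protein=1.0, headcount=1.0)
        rows = lp_core.build_nutrient_constraints(inst)
        protein = next(r for r in rows if "protein" in r.tag)
        s_min = protein.rhs / protein.coeffs[("s", "pulses", "women 19-30")]
        assert s_min == pytest.approx(5.57749, abs=1e-4)

    def test_energy_rows_are_in_mcal(self, madrid):
        rows = lp_core.build_nutrient_constraints(madrid)
        row = next(r for r in rows if r.tag == "requirement[men 9-13,energy]")
        # 17,500 kcal/person/week x 3832 effective persons = 67,060 Mcal
        assert row.rhs == pytest.approx(17.5 * 3832)


class TestCaloricCaps:
    def test_uncapped_nutrient_contributes_no_row(self, madrid):
        rows = lp_core.build_caloric_caps(madrid)
        assert not any("fibre" in r.tag or "omega" in r.tag for r in rows)

    def test_per_food_group_cap_count_and_rhs(self, madrid):
        rows = lp_core.build_caloric_caps(madrid, "per_food_group")
        assert len(rows) == 3 * 9 * 12  # capped nutrients x foods x groups
        row = next(
            r for r in rows if r.tag == "caloric_cap[lipids,fats_and_oils,men 9-13]"
        )
        # 35% of 17.5 Mcal x 3832 effective persons
        assert row.rhs == pytest.approx(0.35 * 17.5 * 3832)
        assert row.coeffs[("s", "fats_and_oils", "men 9-13")] == pytest.approx(
            9.0 * 0.967151
        )

    def test_total_cap_rhs_is_share_of_energy_requirement(self):
        inst = make_tiny_instance(
            requirement_energy=1000.0, headcount=1.0, protein_cap=0.35
        )
        rows = lp_core.build_caloric_caps(inst, "total")
        assert len(rows) == 1
        assert rows[0].rhs == pytest.approx(0.35 * 1.0)  # Mcal

    def test_zero_supply_satisfies_caps(self, madrid):
        for row in lp_core.build_caloric_caps(madrid):
            assert row.sense == "<=" and row.rhs >= 0


class TestMassBalance:
    def test_aggregate_equality_per_food(self, madrid):
        rows = lp_core.build_mass_balance(madrid, "aggregate")
        assert len(rows) == 9
        row = next(r for r in rows if r.tag == "mass_balance[cereal]")
        assert row.sense == "==" and row.rhs == pytest.approx(51_667)
        assert row.coeffs[("c", "cereal")] == -1.0
        assert row.coeffs[("e", "cereal")] == 1.0

    def test_split_row_families(self, madrid):
        rows = lp_core.build_mass_balance(madrid, "split")
        assert len(rows) == 9 + 9 * 12 + 9

    def test_unknown_formulation(self, madrid):
        with pytest.raises(ValidationError):
            lp_core.build_mass_balance(madrid, "bogus")


class TestFruitVegAndBioavailability:
    def test_fruit_veg_rhs_scales_with_headcount(self, madrid):
        rows = lp_core.build_fruit_veg_minimum(madrid)
        row = next(r for r in rows if "men 19-30" in r.tag)
        assert row.rhs == pytest.approx(2.0 * 20_905 * 0.5)
        assert set(a for _, a, _ in row.coeffs) == {"vegetables", "fruit"}

    def test_bioavailability_balances_at_one_third(self, madrid):
        rows = lp_core.build_bioavailability(madrid)
        row = next(r for r in rows if "men 19-30" in r.tag)
        # 1 kg animal protein vs 3 kg vegetable protein sits exactly on the
        # constraint boundary at AVSP = 1/3
        lhs = (
            row.coeffs[("s", "meat", "men 19-30")] * (1.0 / 0.170717)
            + row.coeffs[("s", "pulses", "men 19-30")] * (3.0 / 0.179292)
        )
        assert lhs == pytest.approx(0.0, abs=1e-9)

    def test_all_vegetable_supply_violates_the_floor(self, madrid):
        rows = lp_core.build_bioavailability(madrid)
        row = next(r for r in rows if "men 19-30" in r.tag)
        lhs = row.coeffs[("s", "pulses", "men 19-30")] * 10.0  # vegetable only
        assert lhs < row.rhs  # 0 >= AVSP * positive fails

    def test_skipped_without_both_protein_classes(self, tiny_instance):
        assert lp_core.build_bioavailability(tiny_instance) == []


class TestAssembleAndSolve:
    def test_variable_count_madrid(self, madrid):
        lp = lp_core.assemble(madrid, "aggregate")
        assert lp.n_variables == 9 + 9 * 12 + 7 * 12 + 9 == 210
        lp_split = lp_core.assemble(madrid, "split")
        assert lp_split.n_variables == 210 + 2 * 9 * 12

    def test_every_row_is_tagged(self, madrid):
        lp = lp_core.assemble(madrid)
        assert len(lp.tags_ub) == len(lp.b_ub)
        assert len(lp.tags_eq) == len(lp.b_eq)
        assert all(t for t in lp.tags_ub + lp.tags_eq)

    def test_empty_instance_rejected(self, madrid):
        bad = dataclasses.replace(madrid, food_groups=[])
        with pytest.raises(ValidationError):
            lp_core.assemble(bad)

    def test_objective_recomputation_matches(self, madrid_solution):
        assert madrid_solution.recomputed_objective() == pytest.approx(
            madrid_solution.objective, rel=1e-6
        )

    def test_feasibility_tolerance(self, madrid_solution):
        assert madrid_solution.residuals().max() <= 1e-6

    def test_mass_balance_residuals(self, madrid, madrid_solution):
        sol = madrid_solution
        resid = sol.s.sum(axis=1) - sol.c - madrid.donations + sol.e
        assert resid.abs().max() <= 1e-6

    def test_surplus_within_donation_bounds(self, madrid, madrid_solution):
        e = madrid_solution.e
        assert (e >= -1e-9).all()
        assert (e <= madrid.donations + 1e-9).all()

    def test_split_equals_aggregate_objective(self, madrid, madrid_solution):
        split = lp_core.solve_instance(madrid, "split")
        assert split.is_optimal
        assert split.objective == pytest.approx(
            madrid_solution.objective, rel=1e-6
        )
        # and the split deliveries recompose the supplied masses
        assert np.allclose(
            (split.c_ap + split.d_ap).to_numpy(), split.s.to_numpy(), atol=1e-6
        )

    def test_one_food_solution_matches_closed_form(self):
        for don in (0.0, 2.0, 100.0):
            inst = make_tiny_instance(
                requirement_protein=0.322, headcount=10.0, donation=don
            )
            sol = lp_core.solve_instance(inst)
            assert sol.is_optimal
            assert sol.objective == pytest.approx(tiny_closed_form(inst), rel=1e-9)

    def test_expensive_food_triggers_shortfall(self):
        # penalty below the cost of supplying via food: slack wins
        inst = make_tiny_instance(price=2.9, penalty=10.0, requirement_energy=1.0)
        sol = lp_core.solve_instance(inst)
        assert sol.is_optimal
        assert sol.cns.loc["women 19-30", "protein"] > 0

    def test_contradictory_caps_surface_infeasible(self):
        # the protein energy cap makes delivering any food impossible while
        # the fruit/veg floor demands two kg per person: no feasible plan
        inst = make_tiny_instance(protein_cap=0.001, requirement_energy=1.0)
        inst = dataclasses.replace(
            inst,
            params=inst.params.model_copy(update={"min_fruit_veg_per_person": 2.0}),
        )
        sol = lp_core.solve_instance(inst)
        assert sol.status == "infeasible"

    def test_relaxing_side_constraints_never_costs_more(self, madrid, madrid_solution):
        for kwargs in (
            {"enable_fruit_veg": False},
            {"enable_bioavailability": False},
            {"enable_caloric_caps": False},
        ):
            relaxed = lp_core.solve_instance(madrid, **kwargs)
            assert relaxed.is_optimal
            assert relaxed.objective <= madrid_solution.objective * (1 + 1e-9)

    def test_donation_increase_never_raises_cost(self):
        rng = np.random.default_rng(7)
        for seed in rng.integers(0, 2**31 - 1, size=5):
            inst = fb.generate_instance(
                fb.GeneratorConfig(seed=int(seed), donation_intensity=0.3)
            )
            base = lp_core.solve_instance(inst)
            more = lp_core.solve_instance(
                inst.with_donations(inst.donations * 1.5 + 1.0)
            )
            assert base.is_optimal and more.is_optimal
            assert more.objective <= base.objective * (1 + 1e-9)
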
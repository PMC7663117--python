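import numpy as np
import pandas as pd
import pytest

import foodbanklp as fb


@pytest.fixture(scope="session")
def madrid():
    return fb.load_dataset("madrid2018")


@pytest.fixture(scope="session")
def madrid_solution(madrid):
    sol = fb.solve_instance(madrid)
    assert sol.is_optimal
    return sol


@pytest.fixture(scope="session")
def madrid_report(madrid, madrid_solution):
    return fb.cost_report(madrid, madrid_solution)


@pytest.fixture(scope="session")
def madrid_zero_donation(madrid):
    inst = madrid.with_donations(0.0)
    sol = fb.solve_instance(inst)
    assert sol.is_optimal
    return inst, sol, fb.cost_report(inst, sol)


def make_tiny_instance(
    nut_protein=179.292,  # g/kg, pulses-like
    nut_energy=2952.075,  # kcal/kg
    price=2.90,
    requirement_protein=0.322,
    requirement_energy=100.0,
    headcount=10.0,
    donation=0.0,
    penalty=1000.0,
    coverage=1.0,
    protein_cap=None,
):
    """One food, one population group, protein + energy.

    The food is vegetable-protein and counts as fruit/vegetable so that the
    fruit/veg and (vacuous) bioavailability machinery stays exercised.
    """
    water = 1000.0 - nut_protein
    inst = fb.ProblemInstance(
        food_groups=[fb.FoodGroup("pulses", "vegetable", True)],
        population_groups=[fb.PopulationGroup("women", 19, 30, headcount)],
        nutrients=[
            fb.NutrientSpec(
                "protein", caloric_density=4.0, max_caloric_fraction=protein_cap
            ),
            fb.NutrientSpec("energy", is_energy=True),
        ],
        requirements=pd.DataFrame(
            {"protein": [requirement_protein], "energy": [requirement_energy]},
            index=["women 19-30"],
        ),
        densities=pd.DataFrame(
            {"protein": [nut_protein], "water": [water], "energy": [nut_energy]},
            index=pd.Index(["pulses"], name="food_group"),
        ),
        prices=pd.Series([price], index=["pulses"]),
        donations=pd.Series([float(donation)], index=["pulses"]),
        params=fb.ModelParams(
            shortfall_penalty=penalty,
            energy_shortfall_penalty=penalty,
            min_fruit_veg_per_person=1e-9,
            coverage_fraction=coverage,
        ),
    )
    return inst.validate(check_mass_sum=False)


@pytest.fixture
def tiny_instance():
    return make_tiny_instance()


def tiny_closed_form(inst):
    """Independent optimum for the one-food instance of make_tiny_instance.

    With a single food the objective as a function of the supplied mass s is
    piecewise linear: cost(s) = PRE·max(s − DON, 0) + PEN·(unmet protein) +
    PEN_e·(unmet energy).  Its minimum lies at a breakpoint, so enumerating
    s ∈ {0, DON, R_protein/NUT_protein, R_energy/NUT_energy} is exact.
    """
    card = float(inst.effective_headcounts().iloc[0])
    npro = float(inst.densities.iloc[0]["protein"]) / 1000.0
    nen = float(inst.densities.iloc[0]["energy"]) / 1000.0  # Mcal/kg
    rp = float(inst.requirements.iloc[0]["protein"]) * card
    re = float(inst.requirements.iloc[0]["energy"]) / 1000.0 * card
    pre = float(inst.prices.iloc[0])
    don = float(inst.donations.iloc[0])
    pen = inst.params.shortfall_penalty
    pen_e = inst.params.energy_shortfall_penalty

    def cost(s):
        return (
            pre * max(s - don, 0.0)
            + pen * max(rp - s * npro, 0.0)
            + pen_e * max(re - s * nen, 0.0)
        )

    candidates = [0.0, don, rp / npro if npro else np.inf, re / nen]
    return min(cost(s) for s in candidates if np.isfinite(s))
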
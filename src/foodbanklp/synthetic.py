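"""Randomized problem instances with known feasibility, plus an LP oracle.

The generator works backwards from a hidden feasible allocation: it draws
density, price and headcount tables, fixes a random supply plan ``s0``, and
then sets every requirement to ``tightness`` times what the plan delivers.
With ``tightness ≤ 1`` the plan itself satisfies every constraint with zero
shortfall, so a zero-penalty optimum is guaranteed to exist; with
``tightness > 1`` requirements may exceed what any affordable purchase can
deliver and shortfalls appear.  The fruit/vegetable minimum, the
animal-protein ratio and the caloric caps are calibrated from the same plan
so the guarantee covers every constraint family.

``brute_force_solve`` is an independent oracle for tiny instances: it
enumerates basic feasible solutions (vertices of the constraint polytope)
and never calls the LP solver.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .datamodel import (
    FoodGroup,
    ModelParams,
    NutrientSpec,
    PopulationGroup,
    ProblemInstance,
    ValidationError,
)
from . import lp_core
from .lp_core import AssembledLP, Solution

__all__ = ["GeneratorConfig", "generate_instance", "brute_force_solve"]


class GeneratorConfig(BaseModel):
    """Shape and difficulty knobs of a generated instance."""

    model_config = ConfigDict(frozen=True)

    n_foods: int = Field(ge=1, default=4)
    n_groups: int = Field(ge=1, default=3)
    n_nutrients: int = Field(ge=1, default=3, description="mass nutrients; energy is always added")
    price_scale: float = Field(gt=0, default=1.0)
    requirement_tightness: float = Field(gt=0, default=0.5)
    donation_intensity: float = Field(ge=0, default=0.5)
    seed: int = 0


def _food_groups(n: int) -> list[FoodGroup]:
    # deterministic classification: cycle vegetable/animal/none so that any
    # n ≥ 2 has both protein classes; food 0 is always fruit-or-vegetable
    classes = ["vegetable", "animal", "none"]
    return [
        FoodGroup(
            name=f"food{i}",
            protein_class=classes[i % 3],
            is_fruit_or_vegetable=(i % 6 == 0),
        )
        for i in range(n)
    ]


def generate_instance(config: GeneratorConfig) -> ProblemInstance:
    """Draw a validated instance; fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    foods = _food_groups(config.n_foods)
    food_names = [f.name for f in foods]

    mass_names = ["protein"] + [f"m{i}" for i in range(1, config.n_nutrients)]
    cal_density = {"protein": 4.0}
    for name in mass_names[1:]:
        cal_density[name] = float(np.round(rng.uniform(2.0, 9.0), 3))

    # density rows: symmetric Dirichlet over mass nutrients + water (water
    # weighted heavily so food is mostly water, as in real tables), ×1000 g
    alpha = np.ones(len(mass_names) + 1)
    alpha[-1] = 5.0
    dens_rows = rng.dirichlet(alpha, size=config.n_foods) * 1000.0
    densities = pd.DataFrame(
        dens_rows, index=food_names, columns=mass_names + ["water"]
    )
    densities["energy"] = sum(
        densities[r] * cal_density[r] for r in mass_names
    )  # kcal/kg

    prices = pd.Series(
        rng.uniform(0.5, 5.0, size=config.n_foods) * config.price_scale,
        index=food_names,
        name="price",
    )

    sexes = ["men", "women"]
    population = [
        PopulationGroup(
            sex=sexes[i % 2],
            age_lo=9 + 5 * (i // 2),
            age_hi=13 + 5 * (i // 2),
            headcount=float(rng.integers(100, 5000)),
        )
        for i in range(config.n_groups)
    ]
    group_labels = [g.label for g in population]
    card = np.array([g.headcount for g in population])  # coverage 1.0

    # hidden feasible plan: roughly 0.2-2 kg per person of each food
    s0 = rng.uniform(0.2, 2.0, size=(config.n_foods, config.n_groups)) * card
    t = config.requirement_tightness

    delivered = {}  # (group, nutrient) -> kg (Mcal for energy)
    nut_frac = densities[mass_names].to_numpy() / 1000.0  # kg/kg
    for j, p in enumerate(group_labels):
        for k, r in enumerate(mass_names):
            delivered[(p, r)] = float(s0[:, j] @ nut_frac[:, k])
        delivered[(p, "energy")] = float(
            s0[:, j] @ (densities["energy"].to_numpy() / 1000.0)
        )

    requirements = pd.DataFrame(
        {
            r: [t * delivered[(p, r)] / g.headcount for p, g in zip(group_labels, population)]
            for r in mass_names
        },
        index=pd.Index(group_labels, name="group"),
    )
    requirements["energy"] = [
        t * delivered[(p, "energy")] * 1000.0 / g.headcount  # kcal
        for p, g in zip(group_labels, population)
    ]

    donations = pd.Series(
        config.donation_intensity * rng.uniform(0.0, 1.0, config.n_foods) * s0.sum(axis=1),
        index=food_names,
        name="donation",
    )

    # caloric caps calibrated so the hidden plan keeps 10% headroom under
    # the per-food-group cap scope; a cap that would exceed 100% of any
    # group's energy requirement is simply not imposed
    nutrients = [NutrientSpec("energy", is_energy=True)]
    for k, r in enumerate(mass_names):
        mcal = 1.1 * max(
            cal_density[r]
            * s0[i, j]
            * nut_frac[i, k]
            / (t * delivered[(p, "energy")])
            for i in range(config.n_foods)
            for j, p in enumerate(group_labels)
        )
        nutrients.insert(
            -1,
            NutrientSpec(
                r,
                caloric_density=cal_density[r],
                max_caloric_fraction=float(mcal) if mcal < 1.0 else None,
            ),
        )

    # fruit/veg minimum and animal:vegetable ratio calibrated from the plan;
    # scaled by min(t, 1) so they never conflict with the caps above — with
    # t > 1 the binding caps then surface as nutrient shortfalls rather than
    # as an infeasible instance
    teff = min(t, 1.0)
    fv_idx = [i for i, f in enumerate(foods) if f.is_fruit_or_vegetable]
    if fv_idx:
        qfv = teff * min(s0[fv_idx, j].sum() / card[j] for j in range(config.n_groups))
    else:
        qfv = 1e-9
    an_idx = [i for i, f in enumerate(foods) if f.is_animal_protein]
    ve_idx = [i for i, f in enumerate(foods) if f.is_vegetable_protein]
    if an_idx and ve_idx:
        kp = mass_names.index("protein")
        avsp = teff * min(
            (s0[an_idx, j] @ nut_frac[an_idx, kp])
            / (s0[ve_idx, j] @ nut_frac[ve_idx, kp])
            for j in range(config.n_groups)
        )
    else:
        avsp = 1.0 / 3.0

    # penalty far above the cheapest marginal source of every nutrient, so
    # a zero-shortfall optimum is also the cost-minimal one when it exists
    marginal = max(
        min(prices[a] / max(nut_frac[i, k], 1e-12) for i, a in enumerate(food_names))
        for k in range(len(mass_names))
    )
    marginal_energy = min(
        prices[a] / (densities.loc[a, "energy"] / 1000.0) for a in food_names
    )
    params = ModelParams(
        shortfall_penalty=100.0 * marginal,
        energy_shortfall_penalty=100.0 * max(marginal, marginal_energy),
        min_animal_to_vegetable_protein_ratio=max(avsp, 1e-9),
        min_fruit_veg_per_person=max(qfv, 1e-9),
        coverage_fraction=1.0,
        weeks_per_year=52.0,
        weeks_per_month=52.0 / 12.0,
    )

    instance = ProblemInstance(
        food_groups=foods,
        population_groups=population,
        nutrients=nutrients,
        requirements=requirements,
        densities=densities,
        prices=prices,
        donations=donations,
        params=params,
    )
    return instance.validate()


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_solve(
    instance: ProblemInstance, max_variables: int = 6
) -> Solution:
    """Solve a tiny instance by vertex enumeration; independent of HiGHS.

    Every basic solution — the intersection of ``n`` active constraints
    drawn from the equality rows, inequality rows and variable bounds — is
    enumerated, checked for feasibility, and scored; the best feasible one
    is optimal.  Only valid for ≤ ``max_variables`` decision variables.
    """
    lp = lp_core.assemble(instance, "aggregate")
    n = lp.n_variables
    if n > max_variables:
        raise ValidationError(
            f"instance has {n} variables; the oracle enumerates at most "
            f"{max_variables}"
        )
    rows = [lp.a_ub[i] for i in range(len(lp.b_ub))]
    rhs = list(lp.b_ub)
    for i, (lo, hi) in enumerate(lp.bounds):
        vec = np.zeros(n)
        vec[i] = -1.0
        rows.append(vec)
        rhs.append(-lo)
        if hi is not None:
            vec = np.zeros(n)
            vec[i] = 1.0
            rows.append(vec)
            rhs.append(hi)
    ineq_a = np.array(rows)
    ineq_b = np.array(rhs)

    n_eq = len(lp.b_eq)
    if n_eq > n:
        raise ValidationError("more equality rows than variables")

    tol = 1e-7
    best_x, best_obj = None, np.inf
    for combo in combinations(range(len(ineq_b)), n - n_eq):
        a = np.vstack([lp.a_eq, ineq_a[list(combo)]]) if n_eq else ineq_a[list(combo)]
        b = np.concatenate([lp.b_eq, ineq_b[list(combo)]]) if n_eq else ineq_b[list(combo)]
        try:
            x = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            continue
        if np.any(ineq_a @ x > ineq_b + tol):
            continue
        if n_eq and np.any(np.abs(lp.a_eq @ x - lp.b_eq) > tol):
            continue
        obj = float(lp.objective @ x)
        if obj < best_obj - 1e-12:
            best_obj, best_x = obj, x

    if best_x is None:
        return Solution(status="infeasible", objective=None, lp=lp,
                        message="no feasible vertex found by enumeration")
    return _unpack(instance, lp, best_x, best_obj)


def _unpack(
    instance: ProblemInstance, lp: AssembledLP, x: np.ndarray, obj: float
) -> Solution:
    foods, groups, nutrients = (
        instance.food_names,
        instance.group_labels,
        instance.nutrient_names,
    )
    return Solution(
        status="optimal",
        objective=obj,
        c=pd.Series([x[lp.var_index[("c", a)]] for a in foods], index=foods),
        s=pd.DataFrame(
            [[x[lp.var_index[("s", a, p)]] for p in groups] for a in foods],
            index=foods,
            columns=groups,
        ),
        cns=pd.DataFrame(
            [[x[lp.var_index[("cns", p, r)]] for r in nutrients] for p in groups],
            index=groups,
            columns=nutrients,
        ),
        e=pd.Series([x[lp.var_index[("e", a)]] for a in foods], index=foods),
        x=x,
        lp=lp,
        message="vertex enumeration",
    )
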
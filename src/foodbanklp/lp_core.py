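"""Assembly and solution of the weekly provisioning linear program.

Decision variables (all non-negative, all kg/week unless noted):

- ``c[a]`` — purchased mass of food group *a*
- ``s[a,p]`` — mass of food group *a* supplied to population group *p*
- ``cns[p,r]`` — non-supplied nutrient *r* for group *p* (Mcal/week for the
  energy row)
- ``e[a]`` — donation surplus of food group *a*, bounded by the donation
- split formulation only: ``cap[a,p]`` / ``dap[a,p]`` — purchased / donated
  mass delivered to group *p*

Objective: minimize Σ_a PRE_a·c_a + Σ_{p,r} PEN_r·cns_{p,r}, i.e. purchase
cost plus penalized shortfalls.  Constraints: per-group nutrient
satisfaction, AMDRS caps on the energy share of capped macronutrients, food
mass balance against purchases and donations (aggregate or split form), a
fruit-and-vegetable minimum per group, and an animal-protein floor that
guarantees bioavailability of vegetable protein.

The solver backend is HiGHS via :func:`scipy.optimize.linprog`; optimal
solutions satisfy every constraint within 1e-6 absolute tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .datamodel import ProblemInstance, ValidationError

__all__ = [
    "Formulation",
    "ConstraintRow",
    "AssembledLP",
    "Solution",
    "build_objective",
    "build_nutrient_constraints",
    "build_caloric_caps",
    "build_mass_balance",
    "build_fruit_veg_minimum",
    "build_bioavailability",
    "assemble",
    "solve",
    "solve_instance",
]

Formulation = Literal["aggregate", "split"]

#: absolute feasibility tolerance the returned solutions honour
FEASIBILITY_TOL = 1e-6

VarKey = tuple  # ("c", a) | ("s", a, p) | ("cns", p, r) | ("e", a) | ...


@dataclass
class ConstraintRow:
    """One constraint as a sparse coefficient map with sense and origin tag."""

    coeffs: dict[VarKey, float]
    sense: Literal["<=", ">=", "=="]
    rhs: float
    tag: str


def _nut(instance: ProblemInstance, a: str, r: str) -> float:
    """Nutrient content of 1 kg of food *a*: kg/kg, or Mcal/kg for energy."""
    return float(instance.densities.loc[a, r]) / 1000.0


def _nec(instance: ProblemInstance, p: str, r: str) -> float:
    """Per-person weekly requirement: kg, or Mcal for energy."""
    v = float(instance.requirements.loc[p, r])
    return v / 1000.0 if r == instance.energy_nutrient else v


def build_objective(instance: ProblemInstance) -> dict[VarKey, float]:
    """Cost coefficients: price on purchases, penalty on shortfall slacks."""
    obj: dict[VarKey, float] = {}
    for a in instance.food_names:
        obj[("c", a)] = float(instance.prices[a])
    energy = instance.energy_nutrient
    for p in instance.group_labels:
        for r in instance.nutrient_names:
            pen = (
                instance.params.energy_shortfall_penalty
                if r == energy
                else instance.params.shortfall_penalty
            )
            obj[("cns", p, r)] = pen
    return obj


def build_nutrient_constraints(instance: ProblemInstance) -> list[ConstraintRow]:
    """Delivered nutrients plus slack must cover each group's requirement."""
    card = instance.effective_headcounts()
    rows = []
    for p in instance.group_labels:
        for r in instance.nutrient_names:
            coeffs: dict[VarKey, float] = {
                ("s", a, p): _nut(instance, a, r) for a in instance.food_names
            }
            coeffs[("cns", p, r)] = 1.0
            rows.append(
                ConstraintRow(
                    coeffs,
                    ">=",
                    _nec(instance, p, r) * card[p],
                    f"requirement[{p},{r}]",
                )
            )
    return rows


CapScope = Literal["per_food_group", "total"]


def build_caloric_caps(
    instance: ProblemInstance, cap_scope: CapScope = "per_food_group"
) -> list[ConstraintRow]:
    """AMDRS upper bounds on the energy share of capped macronutrients.

    Default scope ``"per_food_group"``: one row per (food group *a*,
    population group *p*, capped nutrient *r*) limiting the energy a single
    food group may contribute through that macronutrient,
    CAL_r·s_ap·NUT_ar ≤ MCAL_r·NEC_{p,energy}·CARD_p (Mcal).  This bounds
    how much of a group's caloric budget any one food may cover and thereby
    enforces dietary variety alongside the AMDRS.

    Scope ``"total"`` pools food and population groups into one row per
    capped nutrient: CAL_r·Σ_{p,a} s_ap·NUT_ar ≤ MCAL_r·Σ_p NEC·CARD_p —
    the classical AMDRS ceiling on the whole diet.
    """
    card = instance.effective_headcounts()
    energy = instance.energy_nutrient
    rows = []
    for spec in instance.nutrients:
        if spec.max_caloric_fraction is None:
            continue
        if spec.caloric_density is None:
            raise ValidationError(
                f"nutrient {spec.name} has an energy cap but no caloric density"
            )
        if cap_scope == "per_food_group":
            for a in instance.food_names:
                for p in instance.group_labels:
                    rows.append(
                        ConstraintRow(
                            {
                                ("s", a, p): spec.caloric_density
                                * _nut(instance, a, spec.name)
                            },
                            "<=",
                            spec.max_caloric_fraction
                            * _nec(instance, p, energy)
                            * card[p],
                            f"caloric_cap[{spec.name},{a},{p}]",
                        )
                    )
        elif cap_scope == "total":
            total_energy_req = sum(
                _nec(instance, p, energy) * card[p]
                for p in instance.group_labels
            )
            coeffs = {
                ("s", a, p): spec.caloric_density * _nut(instance, a, spec.name)
                for a in instance.food_names
                for p in instance.group_labels
            }
            rows.append(
                ConstraintRow(
                    coeffs,
                    "<=",
                    spec.max_caloric_fraction * total_energy_req,
                    f"caloric_cap[{spec.name}]",
                )
            )
        else:
            raise ValidationError(f"unknown cap_scope {cap_scope!r}")
    return rows


def build_mass_balance(
    instance: ProblemInstance, formulation: Formulation = "aggregate"
) -> list[ConstraintRow]:
    """Distributed food equals purchases plus donations net of surplus.

    Aggregate form: Σ_p s_ap = c_a + DON_a − e_a per food group.  Split form
    separates purchased and donated deliveries: Σ_p d_ap = DON_a − e_a,
    s_ap = c_ap + d_ap, c_a = Σ_p c_ap.
    """
    rows = []
    if formulation == "aggregate":
        for a in instance.food_names:
            coeffs: dict[VarKey, float] = {
                ("s", a, p): 1.0 for p in instance.group_labels
            }
            coeffs[("c", a)] = -1.0
            coeffs[("e", a)] = 1.0
            rows.append(
                ConstraintRow(
                    coeffs, "==", float(instance.donations[a]), f"mass_balance[{a}]"
                )
            )
    elif formulation == "split":
        for a in instance.food_names:
            coeffs = {("dap", a, p): 1.0 for p in instance.group_labels}
            coeffs[("e", a)] = 1.0
            rows.append(
                ConstraintRow(
                    coeffs, "==", float(instance.donations[a]), f"donation_balance[{a}]"
                )
            )
            for p in instance.group_labels:
                rows.append(
                    ConstraintRow(
                        {("s", a, p): 1.0, ("cap", a, p): -1.0, ("dap", a, p): -1.0},
                        "==",
                        0.0,
                        f"supply_split[{a},{p}]",
                    )
                )
            coeffs = {("cap", a, p): 1.0 for p in instance.group_labels}
            coeffs[("c", a)] = -1.0
            rows.append(ConstraintRow(coeffs, "==", 0.0, f"purchase_total[{a}]"))
    else:
        raise ValidationError(f"unknown formulation {formulation!r}")
    return rows


def build_fruit_veg_minimum(instance: ProblemInstance) -> list[ConstraintRow]:
    """Per-group floor on fruit + vegetable mass, scaled by headcount."""
    fv = instance.fruit_veg_foods
    if not fv:
        return []
    card = instance.effective_headcounts()
    qfv = instance.params.min_fruit_veg_per_person
    return [
        ConstraintRow(
            {("s", a, p): 1.0 for a in fv},
            ">=",
            qfv * card[p],
            f"fruit_veg_minimum[{p}]",
        )
        for p in instance.group_labels
    ]


def build_bioavailability(instance: ProblemInstance) -> list[ConstraintRow]:
    """Animal protein must be at least AVSP times vegetable protein.

    Co-ingested animal protein supplies the micronutrients (e.g. B12) needed
    to absorb vegetable protein, hence the floor per population group.
    """
    animal = instance.animal_protein_foods
    veg = instance.vegetable_protein_foods
    if not animal or not veg:
        return []
    ratio = instance.params.min_animal_to_vegetable_protein_ratio
    protein = "protein"
    rows = []
    for p in instance.group_labels:
        coeffs = {("s", a, p): _nut(instance, a, protein) for a in animal}
        for a in veg:
            coeffs[("s", a, p)] = -ratio * _nut(instance, a, protein)
        rows.append(ConstraintRow(coeffs, ">=", 0.0, f"bioavailability[{p}]"))
    return rows


@dataclass
class AssembledLP:
    """A fully assembled LP in matrix form with a label-to-column map."""

    variables: list[VarKey]
    objective: np.ndarray
    a_ub: np.ndarray
    b_ub: np.ndarray
    tags_ub: list[str]
    a_eq: np.ndarray
    b_eq: np.ndarray
    tags_eq: list[str]
    bounds: list[tuple[float, float | None]]
    formulation: Formulation = "aggregate"
    var_index: dict[VarKey, int] = field(init=False)

    def __post_init__(self) -> None:
        self.var_index = {v: i for i, v in enumerate(self.variables)}

    @property
    def n_variables(self) -> int:
        return len(self.variables)


def _variables(instance: ProblemInstance, formulation: Formulation) -> list[VarKey]:
    foods, groups, nutrients = (
        instance.food_names,
        instance.group_labels,
        instance.nutrient_names,
    )
    keys: list[VarKey] = [("c", a) for a in foods]
    keys += [("s", a, p) for a in foods for p in groups]
    keys += [("cns", p, r) for p in groups for r in nutrients]
    keys += [("e", a) for a in foods]
    if formulation == "split":
        keys += [("cap", a, p) for a in foods for p in groups]
        keys += [("dap", a, p) for a in foods for p in groups]
    return keys


def assemble(
    instance: ProblemInstance,
    formulation: Formulation = "aggregate",
    enable_caloric_caps: bool = True,
    enable_fruit_veg: bool = True,
    enable_bioavailability: bool = True,
    cap_scope: CapScope = "per_food_group",
) -> AssembledLP:
    """Concatenate every constraint family into one tagged LP.

    The ``enable_*`` switches drop individual constraint families for
    relaxation studies; non-negativity and the ``e_a ≤ DON_a`` surplus bound
    always apply.
    """
    if formulation not in ("aggregate", "split"):
        raise ValidationError(f"unknown formulation {formulation!r}")
    instance.validate(check_mass_sum=False)
    variables = _variables(instance, formulation)
    index = {v: i for i, v in enumerate(variables)}
    n = len(variables)

    obj = np.zeros(n)
    for key, coef in build_objective(instance).items():
        obj[index[key]] = coef

    rows = build_nutrient_constraints(instance)
    if enable_caloric_caps:
        rows += build_caloric_caps(instance, cap_scope)
    rows += build_mass_balance(instance, formulation)
    if enable_fruit_veg:
        rows += build_fruit_veg_minimum(instance)
    if enable_bioavailability:
        rows += build_bioavailability(instance)

    ub_rows, eq_rows = [], []
    for row in rows:
        (eq_rows if row.sense == "==" else ub_rows).append(row)

    def densify(subset: Iterable[ConstraintRow], flip_ge: bool):
        mat, rhs, tags = [], [], []
        for row in subset:
            vec = np.zeros(n)
            sign = -1.0 if (flip_ge and row.sense == ">=") else 1.0
            for key, coef in row.coeffs.items():
                vec[index[key]] = sign * coef
            mat.append(vec)
            rhs.append(sign * row.rhs)
            tags.append(row.tag)
        if not mat:
            return np.zeros((0, n)), np.zeros(0), []
        return np.vstack(mat), np.asarray(rhs), tags

    a_ub, b_ub, tags_ub = densify(ub_rows, flip_ge=True)
    a_eq, b_eq, tags_eq = densify(eq_rows, flip_ge=False)

    bounds: list[tuple[float, float | None]] = []
    for key in variables:
        if key[0] == "e":
            bounds.append((0.0, float(instance.donations[key[1]])))
        else:
            bounds.append((0.0, None))
    return AssembledLP(
        variables=variables,
        objective=obj,
        a_ub=a_ub,
        b_ub=b_ub,
        tags_ub=tags_ub,
        a_eq=a_eq,
        b_eq=b_eq,
        tags_eq=tags_eq,
        bounds=bounds,
        formulation=formulation,
    )


@dataclass
class Solution:
    """Optimal (or terminal) state of a provisioning LP."""

    status: Literal["optimal", "infeasible", "unbounded", "failed"]
    objective: float | None
    c: pd.Series | None = None
    s: pd.DataFrame | None = None
    cns: pd.DataFrame | None = None
    e: pd.Series | None = None
    c_ap: pd.DataFrame | None = None
    d_ap: pd.DataFrame | None = None
    x: np.ndarray | None = None
    lp: AssembledLP | None = None
    message: str = ""

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"

    def recomputed_objective(self) -> float:
        """Objective re-evaluated from the returned variables."""
        if self.x is None or self.lp is None:
            raise ValidationError("solution carries no variable vector")
        return float(self.lp.objective @ self.x)

    def residuals(self) -> pd.Series:
        """Signed constraint violations (positive = violated), by tag."""
        if self.x is None or self.lp is None:
            raise ValidationError("solution carries no variable vector")
        ub = self.lp.a_ub @ self.x - self.lp.b_ub
        eq = np.abs(self.lp.a_eq @ self.x - self.lp.b_eq)
        return pd.Series(
            np.concatenate([ub, eq]),
            index=self.lp.tags_ub + self.lp.tags_eq,
        )

    def to_dict(self) -> dict:
        """JSON-serializable view keyed by variable label tuples."""
        if not self.is_optimal:
            return {"status": self.status, "message": self.message}
        out = {
            "status": self.status,
            "objective": self.objective,
            "purchases": {a: float(v) for a, v in self.c.items()},
            "surplus": {a: float(v) for a, v in self.e.items()},
            "supplied": {
                f"{a}|{p}": float(self.s.loc[a, p])
                for a in self.s.index
                for p in self.s.columns
            },
            "non_supplied": {
                f"{p}|{r}": float(self.cns.loc[p, r])
                for p in self.cns.index
                for r in self.cns.columns
            },
            "max_abs_residual": float(self.residuals().max()),
        }
        return out


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve(lp: AssembledLP, instance: ProblemInstance, **options) -> Solution:
    """Solve an assembled LP with HiGHS and unpack labelled variables."""
    res = linprog(
        lp.objective,
        A_ub=lp.a_ub if len(lp.b_ub) else None,
        b_ub=lp.b_ub if len(lp.b_ub) else None,
        A_eq=lp.a_eq if len(lp.b_eq) else None,
        b_eq=lp.b_eq if len(lp.b_eq) else None,
        bounds=lp.bounds,
        method="highs",
        options=options or None,
    )
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return Solution(status=status, objective=None, lp=lp, message=res.message)

    x = res.x
    foods, groups, nutrients = (
        instance.food_names,
        instance.group_labels,
        instance.nutrient_names,
    )

    def series(prefix: str, labels: list[str]) -> pd.Series:
        return pd.Series(
            [x[lp.var_index[(prefix, a)]] for a in labels], index=labels, name=prefix
        )

    def frame(prefix: str, rows: list[str], cols: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            [[x[lp.var_index[(prefix, a, p)]] for p in cols] for a in rows],
            index=rows,
            columns=cols,
        )

    sol = Solution(
        status="optimal",
        objective=float(res.fun),
        c=series("c", foods),
        s=frame("s", foods, groups),
        cns=pd.DataFrame(
            [
                [x[lp.var_index[("cns", p, r)]] for r in nutrients]
                for p in groups
            ],
            index=groups,
            columns=nutrients,
        ),
        e=series("e", foods),
        x=x,
        lp=lp,
        message=res.message,
    )
    if lp.formulation == "split":
        sol.c_ap = frame("cap", foods, groups)
        sol.d_ap = frame("dap", foods, groups)
    return sol


def solve_instance(
    instance: ProblemInstance,
    formulation: Formulation = "aggregate",
    **assemble_kwargs,
) -> Solution:
    """Convenience wrapper: assemble then solve in one call."""
    lp = assemble(instance, formulation, **assemble_kwargs)
    return solve(lp, instance)
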
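"""Reported quantities derived from an optimal solution.

Cost decomposition follows food-bank accounting: purchases are priced at
median market prices; donated food is a sunk cost, valued at the same median
prices only for reporting; the total provisioning cost is purchases plus the
donation valuation (shortfall penalties are tracked separately, since they
represent social rather than monetary cost).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .datamodel import ProblemInstance, ValidationError
from .lp_core import Solution

__all__ = [
    "CostReport",
    "ScenarioComparison",
    "donation_valuation",
    "cost_report",
    "per_person_monthly_cost",
    "compare_scenarios",
    "shortfall_summary",
]


def donation_valuation(donations: pd.Series, prices: pd.Series) -> float:
    """Market value (EUR/week) of the donated food: Σ_a DON_a·PRE_a."""
    missing = set(donations.index) ^ set(prices.index)
    if missing:
        raise ValidationError(
            f"donation/price food groups differ on {sorted(missing)}"
        )
    return float((donations * prices.loc[donations.index]).sum())


def per_person_monthly_cost(
    total_weekly_cost: float, effective_persons: float, weeks_per_month: float
) -> float:
    """EUR per person per month implied by a weekly total."""
    if effective_persons <= 0:
        raise ValidationError("effective_persons must be > 0")
    return total_weekly_cost / effective_persons * weeks_per_month


def shortfall_summary(
    instance: ProblemInstance, solution: Solution, atol: float = 1e-6
) -> pd.DataFrame:
    """Non-zero nutrient shortfalls with their relative size.

    One row per (population group, nutrient) with ``non_supplied`` (kg/week;
    Mcal/week for energy) and ``relative`` = cns / (requirement × effective
    headcount); rows below ``atol`` are dropped.
    """
    if not solution.is_optimal:
        raise ValidationError("shortfall summary requires an optimal solution")
    card = instance.effective_headcounts()
    energy = instance.energy_nutrient
    records = []
    for p in instance.group_labels:
        for r in instance.nutrient_names:
            cns = float(solution.cns.loc[p, r])
            if cns <= atol:
                continue
            req = float(instance.requirements.loc[p, r])
            if r == energy:
                req /= 1000.0  # kcal -> Mcal, the unit cns uses
            records.append(
                {
                    "group": p,
                    "nutrient": r,
                    "non_supplied": cns,
                    "relative": cns / (req * card[p]),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["group", "nutrient", "non_supplied", "relative"]
    )


@dataclass
class CostReport:
    """Weekly cost decomposition and aggregate mass of one scenario."""

    purchase_cost: float
    penalty_cost: float
    donation_valuation: float
    per_person_monthly_cost: float
    total_food_mass: float
    shortfalls: pd.DataFrame = field(repr=False)

    @property
    def total_provisioning_cost(self) -> float:
        return self.purchase_cost + self.donation_valuation

    def to_dict(self) -> dict:
        return {
            "purchase_cost_eur_week": self.purchase_cost,
            "penalty_cost_eur_week": self.penalty_cost,
            "donation_valuation_eur_week": self.donation_valuation,
            "total_provisioning_cost_eur_week": self.total_provisioning_cost,
            "per_person_monthly_cost_eur": self.per_person_monthly_cost,
            "total_food_mass_kg_week": self.total_food_mass,
            "shortfalls": self.shortfalls.to_dict(orient="records"),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def summary(self) -> str:
        lines = [
            f"purchase cost        {self.purchase_cost / 1e3:10.1f} kEUR/week",
            f"donation valuation   {self.donation_valuation / 1e3:10.1f} kEUR/week",
            f"total provisioning   {self.total_provisioning_cost / 1e3:10.1f} kEUR/week",
            f"shortfall penalty    {self.penalty_cost / 1e3:10.1f} kEUR/week",
            f"food distributed     {self.total_food_mass / 1e3:10.1f} t/week",
            f"cost per person      {self.per_person_monthly_cost:10.1f} EUR/month",
        ]
        return "\n".join(lines)


def cost_report(instance: ProblemInstance, solution: Solution) -> CostReport:
    """Decompose an optimal solution into the reported cost figures."""
    if not solution.is_optimal:
        raise ValidationError(
            f"cost report requires an optimal solution, got {solution.status!r}"
        )
    purchase = float((instance.prices * solution.c).sum())
    energy = instance.energy_nutrient
    pen_mass = float(
        solution.cns.drop(columns=[energy]).to_numpy().sum()
        * instance.params.shortfall_penalty
    )
    pen_energy = float(
        solution.cns[energy].sum() * instance.params.energy_shortfall_penalty
    )
    donated = donation_valuation(instance.donations, instance.prices)
    mass = float(solution.s.to_numpy().sum())
    persons = float(instance.effective_headcounts().sum())
    monthly = per_person_monthly_cost(
        purchase + donated, persons, instance.params.weeks_per_month
    )
    return CostReport(
        purchase_cost=purchase,
        penalty_cost=pen_mass + pen_energy,
        donation_valuation=donated,
        per_person_monthly_cost=monthly,
        total_food_mass=mass,
        shortfalls=shortfall_summary(instance, solution),
    )


@dataclass
class ScenarioComparison:
    """Paired cost reports with relative deltas, (base − alt)/base."""

    base: CostReport
    alternative: CostReport

    @property
    def cost_delta_fraction(self) -> float:
        return (
            self.base.total_provisioning_cost
            - self.alternative.total_provisioning_cost
        ) / self.base.total_provisioning_cost

    @property
    def mass_delta_fraction(self) -> float:
        return (
            self.base.total_food_mass - self.alternative.total_food_mass
        ) / self.base.total_food_mass

    def to_dict(self) -> dict:
        return {
            "base": self.base.to_dict(),
            "alternative": self.alternative.to_dict(),
            "cost_delta_fraction": self.cost_delta_fraction,
            "mass_delta_fraction": self.mass_delta_fraction,
        }


def compare_scenarios(base: CostReport, alternative: CostReport) -> ScenarioComparison:
    """Relative cost and mass change of an alternative scenario."""
    return ScenarioComparison(base=base, alternative=alternative)
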
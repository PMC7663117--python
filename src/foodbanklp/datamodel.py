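"""Domain types for the weekly food-bank provisioning model.

Index sets
----------
``a`` — food groups (e.g. cereal, dairy), each classified by protein origin
(animal / vegetable / neither) and by whether it counts toward the
fruit-and-vegetable minimum.

``p`` — population groups (sex × age band) with a beneficiary headcount.

``r`` — nutrients: mass macronutrients (kg/week requirements, g/kg
densities) plus exactly one energy "nutrient" (kcal/week requirements,
kcal/kg densities).  Fatty-acid fractions such as omega-3/omega-6 are
sub-components of lipids and therefore do not count toward the 1000 g/kg
mass normalization of a density row (``counts_toward_mass=False``).

Units are fixed package-wide: food masses in kg/week, nutrient requirements
in kg/week per person (energy in kcal/week), densities in g per kg of food
(energy in kcal/kg), prices in EUR/kg, penalties in EUR/kg (energy slack in
EUR/Mcal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ValidationError",
    "FoodGroup",
    "PopulationGroup",
    "NutrientSpec",
    "ModelParams",
    "ProblemInstance",
]

#: tolerance (g) on the 1000 g mass-sum invariant of a corrected density row
MASS_SUM_TOL = 0.01


class ValidationError(ValueError):
    """An input table violates a structural or numeric invariant."""


@dataclass(frozen=True)
class FoodGroup:
    """A food group with its protein-origin and fruit/vegetable flags."""

    name: str
    protein_class: Literal["animal", "vegetable", "none"] = "none"
    is_fruit_or_vegetable: bool = False

    @property
    def is_animal_protein(self) -> bool:
        return self.protein_class == "animal"

    @property
    def is_vegetable_protein(self) -> bool:
        return self.protein_class == "vegetable"


@dataclass(frozen=True)
class PopulationGroup:
    """A sex × age-band beneficiary group with its yearly headcount."""

    sex: str
    age_lo: int
    age_hi: int
    headcount: float

    @property
    def label(self) -> str:
        return f"{self.sex} {self.age_lo}-{self.age_hi}"

    def __post_init__(self) -> None:
        if self.headcount < 0:
            raise ValidationError(
                f"headcount for {self.sex} {self.age_lo}-{self.age_hi} "
                f"is negative ({self.headcount})"
            )
        if self.age_hi < self.age_lo:
            raise ValidationError(
                f"age range {self.age_lo}-{self.age_hi} is inverted"
            )


@dataclass(frozen=True)
class NutrientSpec:
    """A nutrient, optionally capped in its share of total energy.

    ``caloric_density`` is in kcal per g (numerically equal to Mcal per kg),
    required for any nutrient carrying a ``max_caloric_fraction`` cap.
    """

    name: str
    caloric_density: float | None = None
    max_caloric_fraction: float | None = None
    is_energy: bool = False
    counts_toward_mass: bool = True

    def __post_init__(self) -> None:
        if self.max_caloric_fraction is not None:
            if not 0 < self.max_caloric_fraction <= 1:
                raise ValidationError(
                    f"max_caloric_fraction for {self.name} must lie in (0, 1], "
                    f"got {self.max_caloric_fraction}"
                )
            if self.caloric_density is None:
                raise ValidationError(
                    f"nutrient {self.name} has an energy-share cap but no "
                    "caloric density"
                )


class ModelParams(BaseModel):
    """Scalar parameters of the provisioning model."""

    model_config = ConfigDict(frozen=True)

    shortfall_penalty: float = Field(gt=0, default=1000.0)
    energy_shortfall_penalty: float = Field(gt=0, default=1000.0)
    min_animal_to_vegetable_protein_ratio: float = Field(gt=0, default=1 / 3)
    min_fruit_veg_per_person: float = Field(gt=0, default=2.0)
    coverage_fraction: float = Field(gt=0, le=1, default=0.5)
    weeks_per_year: float = Field(gt=0, default=52.0)
    weeks_per_month: float = Field(gt=0, default=52.0 / 12.0)


@dataclass
class ProblemInstance:
    """The complete, validated input of one provisioning problem.

    Tables are label-indexed pandas objects; nothing is positional:

    - ``requirements``: population-group label × nutrient, per person per week
    - ``densities``: food group × (nutrient ∪ "water"), per kg of food
    - ``prices``: food group → EUR/kg
    - ``donations``: food group → effective kg/week
    """

    food_groups: list[FoodGroup]
    population_groups: list[PopulationGroup]
    nutrients: list[NutrientSpec]
    requirements: pd.DataFrame
    densities: pd.DataFrame
    prices: pd.Series
    donations: pd.Series
    params: ModelParams = field(default_factory=ModelParams)

    # -- index helpers -------------------------------------------------

    @property
    def food_names(self) -> list[str]:
        return [f.name for f in self.food_groups]

    @property
    def group_labels(self) -> list[str]:
        return [p.label for p in self.population_groups]

    @property
    def nutrient_names(self) -> list[str]:
        return [n.name for n in self.nutrients]

    @property
    def energy_nutrient(self) -> str:
        return next(n.name for n in self.nutrients if n.is_energy)

    @property
    def mass_nutrients(self) -> list[str]:
        return [n.name for n in self.nutrients if not n.is_energy]

    def nutrient(self, name: str) -> NutrientSpec:
        return next(n for n in self.nutrients if n.name == name)

    @property
    def animal_protein_foods(self) -> list[str]:
        return [f.name for f in self.food_groups if f.is_animal_protein]

    @property
    def vegetable_protein_foods(self) -> list[str]:
        return [f.name for f in self.food_groups if f.is_vegetable_protein]

    @property
    def fruit_veg_foods(self) -> list[str]:
        return [f.name for f in self.food_groups if f.is_fruit_or_vegetable]

    def effective_headcounts(self) -> pd.Series:
        """Headcount × coverage fraction per group, kept fractional."""
        from . import preprocess

        return preprocess.effective_headcounts(
            self.population_groups, self.params.coverage_fraction
        )

    # -- validation ----------------------------------------------------

    def validate(self, check_mass_sum: bool = True) -> "ProblemInstance":
        """Cross-check every table against the index sets; raise on defects.

        ``check_mass_sum=False`` skips the 1000 g/kg row-sum invariant, for
        density tables not yet normalized (raw published values).
        """
        foods = self.food_names
        groups = self.group_labels
        nutrients = self.nutrient_names

        if not foods:
            raise ValidationError("instance has no food groups")
        if not groups:
            raise ValidationError("instance has no population groups")
        if len(set(foods)) != len(foods):
            raise ValidationError("duplicate food-group names")
        if len(set(groups)) != len(groups):
            raise ValidationError("duplicate population-group labels")
        n_energy = sum(n.is_energy for n in self.nutrients)
        if n_energy != 1:
            raise ValidationError(
                f"exactly one nutrient must be the energy row, found {n_energy}"
            )

        self._check_age_bands()
        self._check_table(
            "requirements", self.requirements, groups, nutrients
        )
        self._check_table(
            "densities", self.densities, foods, nutrients + ["water"]
        )
        self._check_series("prices", self.prices, foods, strict_positive=True)
        self._check_series("donations", self.donations, foods)

        energy = self.energy_nutrient
        if (self.requirements[energy] <= 0).any():
            bad = self.requirements[energy].idxmin()
            raise ValidationError(
                f"requirements[{bad!r}, {energy!r}] must be strictly positive"
            )
        if check_mass_sum:
            self._check_density_mass_sums()
        return self

    def _check_age_bands(self) -> None:
        by_sex: dict[str, list[PopulationGroup]] = {}
        for g in self.population_groups:
            by_sex.setdefault(g.sex, []).append(g)
        for sex, gs in by_sex.items():
            gs = sorted(gs, key=lambda g: g.age_lo)
            for lo, hi in zip(gs[1:], gs[:-1]):
                if lo.age_lo <= hi.age_hi:
                    raise ValidationError(
                        f"overlapping age ranges for {sex}: "
                        f"{hi.age_lo}-{hi.age_hi} and {lo.age_lo}-{lo.age_hi}"
                    )

    @staticmethod
    def _check_table(
        name: str,
        table: pd.DataFrame,
        rows: Sequence[str],
        cols: Sequence[str],
    ) -> None:
        missing_r = set(rows) - set(table.index)
        if missing_r:
            raise ValidationError(f"{name} is missing rows {sorted(missing_r)}")
        missing_c = set(cols) - set(table.columns)
        if missing_c:
            raise ValidationError(
                f"{name} is missing columns {sorted(missing_c)}"
            )
        sub = table.loc[list(rows), list(cols)]
        if sub.isna().any().any():
            r = sub.index[sub.isna().any(axis=1)][0]
            c = sub.columns[sub.isna().any(axis=0)][0]
            raise ValidationError(f"{name}[{r!r}, {c!r}] is missing")
        if (sub < 0).any().any():
            mask = sub < 0
            r = sub.index[mask.any(axis=1)][0]
            c = sub.columns[mask.any(axis=0)][0]
            raise ValidationError(
                f"{name}[{r!r}, {c!r}] is negative ({sub.loc[r, c]})"
            )

    @staticmethod
    def _check_series(
        name: str,
        series: pd.Series,
        index: Sequence[str],
        strict_positive: bool = False,
    ) -> None:
        missing = set(index) - set(series.index)
        if missing:
            raise ValidationError(f"{name} is missing entries {sorted(missing)}")
        sub = series.loc[list(index)]
        if sub.isna().any():
            raise ValidationError(f"{name}[{sub.index[sub.isna()][0]!r}] is missing")
        bad = sub <= 0 if strict_positive else sub < 0
        if bad.any():
            k = sub.index[bad][0]
            word = "must be > 0" if strict_positive else "is negative"
            raise ValidationError(f"{name}[{k!r}] {word} ({sub[k]})")

    def _check_density_mass_sums(self) -> None:
        mass_cols = [
            n.name
            for n in self.nutrients
            if not n.is_energy and n.counts_toward_mass
        ] + ["water"]
        sums = self.densities[mass_cols].sum(axis=1)
        off = (sums - 1000.0).abs() > MASS_SUM_TOL
        if off.any():
            food = sums.index[off][0]
            raise ValidationError(
                f"densities mass sum for {food!r} is {sums[food]:.3f} g, "
                "expected 1000 g (run the density correction first)"
            )

    # -- comparison ----------------------------------------------------

    def equals(self, other: "ProblemInstance", rtol: float = 1e-9) -> bool:
        """Table-by-table equality within a relative tolerance."""
        if (
            self.food_groups != other.food_groups
            or self.population_groups != other.population_groups
            or self.nutrients != other.nutrients
            or self.params != other.params
        ):
            return False
        for mine, theirs in (
            (self.requirements, other.requirements),
            (self.densities, other.densities),
        ):
            if not mine.index.equals(theirs.index):
                return False
            if not np.allclose(
                mine.to_numpy(float), theirs[mine.columns].to_numpy(float), rtol=rtol
            ):
                return False
        for mine, theirs in ((self.prices, other.prices), (self.donations, other.donations)):
            if not mine.index.equals(theirs.index):
                return False
            if not np.allclose(mine.to_numpy(float), theirs.to_numpy(float), rtol=rtol):
                return False
        return True

    def with_donations(self, donations: pd.Series | float) -> "ProblemInstance":
        """A copy with the donation vector replaced (scalar broadcasts)."""
        if np.isscalar(donations):
            donations = pd.Series(float(donations), index=self.donations.index)
        return ProblemInstance(
            food_groups=self.food_groups,
            population_groups=self.population_groups,
            nutrients=self.nutrients,
            requirements=self.requirements,
            densities=self.densities,
            prices=self.prices,
            donations=donations,
            params=self.params,
        )
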
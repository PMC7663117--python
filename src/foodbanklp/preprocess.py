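"""Deterministic input transformations applied before optimization.

Three steps: normalizing published nutrient-density rows so that each kg of
food accounts for exactly 1000 g of mass (macronutrients + water; fatty-acid
sub-fractions of lipids are not double counted), spreading annual donations
evenly over the weeks of the year, and scaling registered headcounts by the
coverage fraction actually served each week.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .datamodel import PopulationGroup, ValidationError

__all__ = ["correct_density", "weekly_donations", "effective_headcounts"]

#: density columns that are sub-fractions of another mass column (fatty
#: acids within lipids) and therefore excluded from the 1000 g mass sum
DEFAULT_SUBFRACTIONS = ("omega6", "omega3")


def correct_density(
    raw: pd.DataFrame,
    subfraction_columns: Sequence[str] = DEFAULT_SUBFRACTIONS,
    energy_column: str = "energy",
    water_column: str = "water",
) -> pd.DataFrame:
    """Scale each density row uniformly so its mass entries sum to 1000 g.

    The factor for a row is ``1000 / (sum of mass contributions incl.
    water)``, where fatty-acid sub-fractions already contained in the lipids
    column are excluded from the sum.  The factor is applied to *every*
    column — mass, water, sub-fractions and energy alike — so within-row
    nutrient-to-energy ratios are preserved and the operation is idempotent.

    Parameters
    ----------
    raw
        Density table, one row per food group, g per kg of food (energy in
        kcal/kg).
    subfraction_columns, energy_column, water_column
        Column roles; sub-fraction and energy columns are scaled but not
        counted in the mass sum.

    Raises
    ------
    ValidationError
        If any row has a non-positive mass sum.
    """
    excluded = set(subfraction_columns) | {energy_column}
    mass_cols = [c for c in raw.columns if c not in excluded]
    if water_column not in mass_cols:
        raise ValidationError(f"density table lacks a {water_column!r} column")
    mass_sum = raw[mass_cols].sum(axis=1)
    if (mass_sum <= 0).any():
        food = mass_sum.index[mass_sum <= 0][0]
        raise ValidationError(
            f"density row {food!r} has non-positive mass sum ({mass_sum[food]})"
        )
    factor = 1000.0 / mass_sum
    return raw.mul(factor, axis=0)


def weekly_donations(
    annual_donations: pd.Series, weeks_per_year: float
) -> pd.Series:
    """Spread annual donated mass (kg/year) evenly into kg/week."""
    if weeks_per_year <= 0:
        raise ValidationError(f"weeks_per_year must be > 0, got {weeks_per_year}")
    return annual_donations / weeks_per_year


def effective_headcounts(
    groups: Iterable[PopulationGroup], coverage_fraction: float
) -> pd.Series:
    """Headcounts scaled by the fraction of beneficiaries served weekly.

    The result is kept fractional (the model is continuous); index is the
    group label.
    """
    if not 0 < coverage_fraction <= 1:
        raise ValidationError(
            f"coverage_fraction must lie in (0, 1], got {coverage_fraction}"
        )
    groups = list(groups)
    return pd.Series(
        [g.headcount * coverage_fraction for g in groups],
        index=[g.label for g in groups],
        name="effective_headcount",
    )
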
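"""Readers and writers for the tabular instance format.

An instance on disk is a directory of label-keyed CSV tables plus one YAML
parameter file::

    requirements.csv   sex, age_lo, age_hi, <one column per nutrient>
    densities.csv      food_group, <one column per nutrient>, water
    prices.csv         food_group, price            [EUR/kg]
    headcounts.csv     sex, age_lo, age_hi, headcount
    donations.csv      food_group, donation         [kg/week]
    params.yaml        scalar params + food-group / nutrient classifications

The 2018 Madrid case-study dataset ships with the package and is available
as ``load_dataset("madrid2018")``.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd
import yaml

from .datamodel import (
    FoodGroup,
    ModelParams,
    NutrientSpec,
    PopulationGroup,
    ProblemInstance,
    ValidationError,
)

__all__ = ["load_instance", "write_instance", "load_dataset", "dataset_path"]


def _full_precision(value: float) -> str:
    """Shortest representation that round-trips the float exactly."""
    return repr(float(value))

TABLE_FILES = {
    "requirements": "requirements.csv",
    "densities": "densities.csv",
    "prices": "prices.csv",
    "headcounts": "headcounts.csv",
    "donations": "donations.csv",
    "params": "params.yaml",
}


def dataset_path(name: str) -> Path:
    """Filesystem path of a bundled dataset directory."""
    root = importlib.resources.files("foodbanklp") / "data" / name
    path = Path(str(root))
    if not path.is_dir():
        raise ValidationError(f"no bundled dataset named {name!r}")
    return path


def load_dataset(name: str = "madrid2018") -> ProblemInstance:
    """Load and validate a bundled dataset."""
    return load_instance(dataset_path(name))


def _read_csv(directory: Path, filename: str) -> pd.DataFrame:
    path = directory / filename
    if not path.is_file():
        raise ValidationError(f"missing table file: {path}")
    return pd.read_csv(path)


def _group_label(row: pd.Series) -> str:
    return f"{row['sex']} {int(row['age_lo'])}-{int(row['age_hi'])}"


def load_instance(directory: str | Path) -> ProblemInstance:
    """Read an instance directory, cross-validate it and return it.

    Raises :class:`ValidationError` naming the offending file or cell on any
    missing table, unknown label, missing cell or out-of-range value.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise ValidationError(f"instance directory not found: {directory}")

    cfg_path = directory / TABLE_FILES["params"]
    if not cfg_path.is_file():
        raise ValidationError(f"missing parameter file: {cfg_path}")
    cfg = yaml.safe_load(cfg_path.read_text())
    params = ModelParams(**cfg.get("params", {}))

    food_groups = [
        FoodGroup(
            name=name,
            protein_class=spec.get("protein_class", "none"),
            is_fruit_or_vegetable=bool(spec.get("fruit_or_vegetable", False)),
        )
        for name, spec in cfg["food_groups"].items()
    ]
    nutrients = [
        NutrientSpec(
            name=name,
            caloric_density=spec.get("caloric_density"),
            max_caloric_fraction=spec.get("max_caloric_fraction"),
            is_energy=bool(spec.get("is_energy", False)),
            counts_toward_mass=bool(spec.get("counts_toward_mass", True)),
        )
        for name, spec in cfg["nutrients"].items()
    ]

    heads = _read_csv(directory, TABLE_FILES["headcounts"])
    population_groups = [
        PopulationGroup(
            sex=str(row["sex"]),
            age_lo=int(row["age_lo"]),
            age_hi=int(row["age_hi"]),
            headcount=float(row["headcount"]),
        )
        for _, row in heads.iterrows()
    ]

    req = _read_csv(directory, TABLE_FILES["requirements"])
    req.index = pd.Index([_group_label(r) for _, r in req.iterrows()], name="group")
    requirements = req.drop(columns=["sex", "age_lo", "age_hi"]).astype(float)

    densities = (
        _read_csv(directory, TABLE_FILES["densities"])
        .set_index("food_group")
        .astype(float)
    )
    prices = (
        _read_csv(directory, TABLE_FILES["prices"])
        .set_index("food_group")["price"]
        .astype(float)
    )
    donations = (
        _read_csv(directory, TABLE_FILES["donations"])
        .set_index("food_group")["donation"]
        .astype(float)
    )

    instance = ProblemInstance(
        food_groups=food_groups,
        population_groups=population_groups,
        nutrients=nutrients,
        requirements=requirements,
        densities=densities,
        prices=prices,
        donations=donations,
        params=params,
    )
    instance.validate()
    # canonical row order: population groups as listed in headcounts.csv,
    # food groups as listed in params.yaml (files may order rows freely)
    instance.requirements = instance.requirements.loc[instance.group_labels]
    instance.densities = instance.densities.loc[instance.food_names]
    instance.prices = instance.prices.loc[instance.food_names]
    instance.donations = instance.donations.loc[instance.food_names]
    return instance


def write_instance(instance: ProblemInstance, directory: str | Path) -> Path:
    """Write an instance as the CSV + YAML file set; round-trips exactly.

    Numbers are written in full ``repr`` precision so that
    ``load_instance(write_instance(x))`` reproduces every table.
    """
    instance.validate(check_mass_sum=False)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    cfg = {
        "params": {k: float(v) for k, v in instance.params.model_dump().items()},
        "food_groups": {
            f.name: {
                "protein_class": f.protein_class,
                "fruit_or_vegetable": f.is_fruit_or_vegetable,
            }
            for f in instance.food_groups
        },
        "nutrients": {
            n.name: {
                k: v
                for k, v in (
                    ("caloric_density", None if n.caloric_density is None else float(n.caloric_density)),
                    ("max_caloric_fraction", None if n.max_caloric_fraction is None else float(n.max_caloric_fraction)),
                    ("is_energy", n.is_energy or None),
                    ("counts_toward_mass", None if n.counts_toward_mass else False),
                )
                if v is not None
            }
            for n in instance.nutrients
        },
    }
    (directory / TABLE_FILES["params"]).write_text(
        yaml.safe_dump(cfg, sort_keys=False)
    )

    demo = pd.DataFrame(
        {
            "sex": [g.sex for g in instance.population_groups],
            "age_lo": [g.age_lo for g in instance.population_groups],
            "age_hi": [g.age_hi for g in instance.population_groups],
        }
    )
    heads = demo.assign(headcount=[g.headcount for g in instance.population_groups])
    heads.to_csv(directory / TABLE_FILES["headcounts"], index=False)

    req_rows = instance.requirements.loc[
        [g.label for g in instance.population_groups]
    ].reset_index(drop=True)
    req = pd.concat([demo, req_rows], axis=1)
    req.to_csv(directory / TABLE_FILES["requirements"], index=False, float_format=_full_precision)

    instance.densities.to_csv(
        directory / TABLE_FILES["densities"],
        float_format=_full_precision,
        index_label="food_group",
    )
    instance.prices.rename("price").to_csv(
        directory / TABLE_FILES["prices"],
        float_format=_full_precision,
        index_label="food_group",
    )
    instance.donations.rename("donation").to_csv(
        directory / TABLE_FILES["donations"],
        float_format=_full_precision,
        index_label="food_group",
    )
    return directory
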
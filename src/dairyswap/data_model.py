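"""Domain types, unit conventions and tabular IO for the replacement pipeline.

Conventions
-----------
* Nutrient profiles are stored **per 100 g** edible portion; the optimiser
  works per gram (divide by 100).
* Energy is carried in kJ.  ``kcal_to_kj`` / ``kj_to_kcal`` (1 kcal = 4.184 kJ)
  are display helpers only.
* Vitamin D is carried in micrograms, vitamin A in micrograms RAE.

Eleven nutrient fields are *constrained* in the optimisation (protein plus
the ten shortfall nutrients); four further fields (energy, sodium, added
sugars, saturated fat) are *reported only* and never constrained.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import IntegrityError, SchemaError, ValidationError

__all__ = [
    "CONSTRAINED_NUTRIENTS",
    "REPORTED_ONLY_FIELDS",
    "ALL_NUTRIENT_FIELDS",
    "KJ_PER_KCAL",
    "NutrientVector",
    "FoodCategory",
    "DairyReference",
    "IntakeSample",
    "kcal_to_kj",
    "kj_to_kcal",
    "build_dairy_reference",
    "load_food_table",
    "write_food_table",
    "load_intake_table",
    "write_intake_table",
    "load_dairy_reference",
    "write_dairy_reference",
]

#: Protein plus the ten shortfall nutrients — the LP constraint rows.
CONSTRAINED_NUTRIENTS: tuple[str, ...] = (
    "protein",
    "calcium",
    "choline",
    "fibre",
    "iron",
    "magnesium",
    "potassium",
    "vitamin_a",
    "vitamin_c",
    "vitamin_d",
    "vitamin_e",
)

#: Carried through for reporting but never constrained.
REPORTED_ONLY_FIELDS: tuple[str, ...] = (
    "energy",
    "sodium",
    "added_sugars",
    "saturated_fat",
)

ALL_NUTRIENT_FIELDS: tuple[str, ...] = CONSTRAINED_NUTRIENTS + REPORTED_ONLY_FIELDS

KJ_PER_KCAL = 4.184


def kcal_to_kj(kcal: float) -> float:
    return kcal * KJ_PER_KCAL


def kj_to_kcal(kj: float) -> float:
    return kj / KJ_PER_KCAL


@dataclass(frozen=True)
class NutrientVector:
    """Amounts of the 11 constrained nutrients plus the 4 reported-only fields.

    Units: protein g, calcium mg, choline mg, fibre g, iron mg, magnesium mg,
    potassium mg, vitamin_a µg RAE, vitamin_c mg, vitamin_d µg, vitamin_e mg,
    energy kJ, sodium mg, added_sugars g, saturated_fat g.
    """

    protein: float = 0.0
    calcium: float = 0.0
    choline: float = 0.0
    fibre: float = 0.0
    iron: float = 0.0
    magnesium: float = 0.0
    potassium: float = 0.0
    vitamin_a: float = 0.0
    vitamin_c: float = 0.0
    vitamin_d: float = 0.0
    vitamin_e: float = 0.0
    energy: float = 0.0
    sodium: float = 0.0
    added_sugars: float = 0.0
    saturated_fat: float = 0.0

    def __post_init__(self) -> None:
        for name in ALL_NUTRIENT_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValidationError(f"nutrient {name!r} is not finite: {value!r}")
            if value < 0:
                raise ValidationError(f"nutrient {name!r} must be >= 0, got {value!r}")

    def as_array(self, fields: Sequence[str] = ALL_NUTRIENT_FIELDS) -> np.ndarray:
        return np.array([getattr(self, f) for f in fields], dtype=float)

    @classmethod
    def from_array(
        cls, values: Iterable[float], fields: Sequence[str] = ALL_NUTRIENT_FIELDS
    ) -> "NutrientVector":
        return cls(**dict(zip(fields, map(float, values), strict=True)))

    def scaled(self, factor: float) -> "NutrientVector":
        if factor < 0:
            raise ValidationError(f"scale factor must be >= 0, got {factor!r}")
        return NutrientVector.from_array(self.as_array() * factor)

    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector.from_array(self.as_array() + other.as_array())

    @staticmethod
    def combine(
        vectors: Sequence["NutrientVector"], weights: Sequence[float]
    ) -> "NutrientVector":
        """Weight-fraction combination of nutrient vectors."""
        if len(vectors) != len(weights):
            raise ValidationError("vectors and weights must have equal length")
        total = np.zeros(len(ALL_NUTRIENT_FIELDS))
        for v, w in zip(vectors, weights):
            total += w * v.as_array()
        return NutrientVector.from_array(total)


@dataclass(frozen=True)
class FoodCategory:
    """A food category: nutrient density per 100 g, unit cost, serving size."""

    code: int
    name: str
    nutrients_per_100g: NutrientVector
    cost_per_100g: float
    racc_g: float
    is_beverage: bool = False

    def __post_init__(self) -> None:
        if self.cost_per_100g < 0:
            raise ValidationError(
                f"category {self.code}: cost_per_100g must be >= 0, "
                f"got {self.cost_per_100g!r}"
            )
        if self.racc_g <= 0:
            raise ValidationError(
                f"category {self.code}: racc_g must be > 0, got {self.racc_g!r}"
            )

    def with_cost(self, cost_per_100g: float) -> "FoodCategory":
        return dataclasses.replace(self, cost_per_100g=cost_per_100g)


@dataclass(frozen=True)
class DairyReference:
    """Right-hand side of the replacement problem: one cup-equivalent serving."""

    per_serving: NutrientVector
    cost_per_serving: float
    weight_per_serving: float
    composite_weights: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        w = np.asarray(self.composite_weights, dtype=float)
        if w.shape != (3,):
            raise ValidationError("composite_weights must have exactly 3 entries")
        if np.any(w < 0) or np.any(w > 1):
            raise ValidationError("composite_weights must each lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"composite_weights must sum to 1 within 1e-9, got {w.sum()!r}"
            )
        if self.cost_per_serving < 0 or self.weight_per_serving < 0:
            raise ValidationError("per-serving cost and weight must be >= 0")

    def targets(self, fields: Sequence[str] = CONSTRAINED_NUTRIENTS) -> np.ndarray:
        return self.per_serving.as_array(fields)


@dataclass(frozen=True)
class IntakeSample:
    """One person's single-day recall: survey weight and grams per category."""

    person_id: str
    sample_weight: float
    grams_by_category: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_weight <= 0:
            raise ValidationError(
                f"person {self.person_id}: sample_weight must be > 0"
            )
        for code, grams in self.grams_by_category.items():
            if grams < 0:
                raise ValidationError(
                    f"person {self.person_id}: grams for code {code} must be >= 0"
                )


def build_dairy_reference(
    milk: tuple[NutrientVector, float, float],
    cheese: tuple[NutrientVector, float, float],
    yogurt: tuple[NutrientVector, float, float],
    weights: Sequence[float],
) -> DairyReference:
    """Combine (profile, cost, weight) triples into a composite serving.

    Every field of the result is the weight-fraction combination of the three
    component values.  ``weights`` must sum to 1 within 1e-9.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ValidationError("weights must have exactly 3 entries")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValidationError(f"weights must sum to 1 within 1e-9, got {w.sum()!r}")
    components = (milk, cheese, yogurt)
    per_serving = NutrientVector.combine([c[0] for c in components], w)
    cost = float(np.dot(w, [c[1] for c in components]))
    weight = float(np.dot(w, [c[2] for c in components]))
    return DairyReference(
        per_serving=per_serving,
        cost_per_serving=cost,
        weight_per_serving=weight,
        composite_weights=tuple(w),
    )


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

#: Food-table column -> NutrientVector field (all per 100 g).
NUTRIENT_COLUMNS: dict[str, str] = {
    "protein_g": "protein",
    "calcium_mg": "calcium",
    "choline_mg": "choline",
    "fibre_g": "fibre",
    "iron_mg": "iron",
    "magnesium_mg": "magnesium",
    "potassium_mg": "potassium",
    "vit_a_ug_rae": "vitamin_a",
    "vit_c_mg": "vitamin_c",
    "vit_d_ug": "vitamin_d",
    "vit_e_mg": "vitamin_e",
    "energy_kj": "energy",
    "sodium_mg": "sodium",
    "added_sugars_g": "added_sugars",
    "sat_fat_g": "saturated_fat",
}

FOOD_TABLE_COLUMNS: tuple[str, ...] = (
    "code",
    "name",
    *NUTRIENT_COLUMNS.keys(),
    "cost_usd_per_100g",
    "racc_g",
    "is_beverage",
)

INTAKE_TABLE_COLUMNS: tuple[str, ...] = ("person_id", "sample_weight", "code", "grams")


def load_food_table(path: str | Path) -> list[FoodCategory]:
    """Read a delimited food table (see :data:`FOOD_TABLE_COLUMNS`)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FOOD_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"food table missing required column(s): {missing}")
    dupes = df["code"][df["code"].duplicated()].tolist()
    if dupes:
        raise IntegrityError(f"duplicate category code(s): {sorted(set(dupes))}")
    foods: list[FoodCategory] = []
    for idx, row in df.iterrows():
        nutrient_values = {
            fld: float(row[col]) for col, fld in NUTRIENT_COLUMNS.items()
        }
        bad = [c for c, v in nutrient_values.items() if v < 0]
        if bad or float(row["cost_usd_per_100g"]) < 0:
            raise ValidationError(f"negative amount at row {idx} (code {row['code']})")
        try:
            foods.append(
                FoodCategory(
                    code=int(row["code"]),
                    name=str(row["name"]),
                    nutrients_per_100g=NutrientVector(**nutrient_values),
                    cost_per_100g=float(row["cost_usd_per_100g"]),
                    racc_g=float(row["racc_g"]),
                    is_beverage=bool(row["is_beverage"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
    return foods


def write_food_table(foods: Sequence[FoodCategory], path: str | Path) -> None:
    rows = []
    for f in foods:
        row: dict[str, object] = {"code": f.code, "name": f.name}
        for col, fld in NUTRIENT_COLUMNS.items():
            row[col] = repr(getattr(f.nutrients_per_100g, fld))
        row["cost_usd_per_100g"] = repr(f.cost_per_100g)
        row["racc_g"] = repr(f.racc_g)
        row["is_beverage"] = f.is_beverage
        rows.append(row)
    pd.DataFrame(rows, columns=list(FOOD_TABLE_COLUMNS)).to_csv(path, index=False)


def load_intake_table(path: str | Path) -> list[IntakeSample]:
    """Read a long-format intake table (person_id, sample_weight, code, grams)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in INTAKE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"intake table missing required column(s): {missing}")
    samples: list[IntakeSample] = []
    for pid, group in df.groupby("person_id", sort=False):
        weights = group["sample_weight"].unique()
        if len(weights) > 1:
            raise IntegrityError(
                f"person {pid!r} has inconsistent sample weights: {weights.tolist()}"
            )
        samples.append(
            IntakeSample(
                person_id=str(pid),
                sample_weight=float(weights[0]),
                grams_by_category={
                    int(c): float(g) for c, g in zip(group["code"], group["grams"])
                },
            )
        )
    return samples


def write_intake_table(samples: Sequence[IntakeSample], path: str | Path) -> None:
    rows = [
        {
            "person_id": s.person_id,
            "sample_weight": repr(s.sample_weight),
            "code": code,
            "grams": repr(grams),
        }
        for s in samples
        for code, grams in sorted(s.grams_by_category.items())
    ]
    pd.DataFrame(rows, columns=list(INTAKE_TABLE_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dairy-reference config (YAML)
# ---------------------------------------------------------------------------

_COMPONENT_KEYS = ("milk", "cheese", "yogurt")


def _component_from_mapping(block: Mapping) -> tuple[NutrientVector, float, float]:
    nutrients = {k: float(v) for k, v in block.get("nutrients", {}).items()}
    unknown = set(nutrients) - set(ALL_NUTRIENT_FIELDS)
    if unknown:
        raise SchemaError(f"unknown nutrient field(s) in config: {sorted(unknown)}")
    return (
        NutrientVector(**nutrients),
        float(block["cost"]),
        float(block["weight_g"]),
    )


def load_dairy_reference(path: str | Path) -> DairyReference:
    """Read a dairy-reference config: either per-serving targets or components.

    Two layouts are accepted::

        per_serving: {nutrients: {...}, cost: 0.41, weight_g: 152}

    or::

        components:
          milk:   {nutrients: {...}, cost: ..., weight_g: ...}
          cheese: {...}
          yogurt: {...}
        weights: [0.53, 0.45, 0.02]
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise SchemaError("dairy reference config must be a mapping")
    if "per_serving" in cfg:
        nv, cost, weight = _component_from_mapping(cfg["per_serving"])
        return DairyReference(nv, cost, weight)
    if "components" in cfg:
        comps = cfg["components"]
        missing = [k for k in _COMPONENT_KEYS if k not in comps]
        if missing:
            raise SchemaError(f"missing component block(s): {missing}")
        return build_dairy_reference(
            *(_component_from_mapping(comps[k]) for k in _COMPONENT_KEYS),
            weights=cfg.get("weights", (0.53, 0.45, 0.02)),
        )
    raise SchemaError("config needs either 'per_serving' or 'components'")


def write_dairy_reference(reference: DairyReference, path: str | Path) -> None:
    cfg = {
        "per_serving": {
            "nutrients": {
                f: getattr(reference.per_serving, f) for f in ALL_NUTRIENT_FIELDS
            },
            "cost": reference.cost_per_serving,
            "weight_g": reference.weight_per_serving,
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
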
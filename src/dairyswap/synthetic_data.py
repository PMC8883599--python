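"""Seeded generators for food databases, intake samples, planted-optimum LP
instances and the dairy-reference fixture.

All generators are pure functions of their seeds; every generated table
passes the package's own validation.  The archetype nutrient/price ranges
live in an editable YAML parameter file (``data/archetypes.yaml``) so the
generator can be pushed toward different regimes without code changes.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .data_model import (
    ALL_NUTRIENT_FIELDS,
    CONSTRAINED_NUTRIENTS,
    DairyReference,
    FoodCategory,
    IntakeSample,
    NutrientVector,
    build_dairy_reference,
)
from .errors import GenerationError, ValidationError
from .lp_core import build_lp, optimal_vertices

__all__ = [
    "generate_food_db",
    "generate_intakes",
    "consumption_params",
    "planted_optimum_instance",
    "PlantedInstance",
    "dairy_fixture",
    "DairyFixture",
    "load_archetypes",
]

# Fixed category codes so the phase exclusion lists bite on synthetic data.
_DAIRY_CODES = (1006, 1008, 1206, 1208, 1804, 1404,
                1002, 1004, 1202, 1204, 1402, 1802, 1602, 1604, 3720)
_WATER_CODES = (7702, 7704, 7302, 7102, 7106)
_BABY_CODES = (9002, 9004, 9006, 9008, 9010, 9012, 9202, 9402, 9404)
_RESERVED = set(_DAIRY_CODES) | set(_WATER_CODES) | set(_BABY_CODES) | {7208, 9802}


def load_archetypes(path: str | Path | None = None) -> dict[str, dict]:
    """Load archetype parameters (package default or a user-supplied file)."""
    if path is None:
        text = (
            resources.files("dairyswap").joinpath("data/archetypes.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)["archetypes"]


def _sample_range(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Log-uniform when the range is positive, uniform otherwise."""
    if lo > hi:
        raise ValidationError(f"bad range [{lo}, {hi}]")
    if lo == hi:
        return float(lo)
    if lo > 0:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


def _make_category(
    rng: np.random.Generator, code: int, archetype: str, params: Mapping
) -> FoodCategory:
    nutrients = {
        fld: _sample_range(rng, *params["nutrients"][fld])
        for fld in ALL_NUTRIENT_FIELDS
    }
    return FoodCategory(
        code=code,
        name=f"{params['display']} {code}",
        nutrients_per_100g=NutrientVector(**nutrients),
        cost_per_100g=_sample_range(rng, *params["cost_range"]),
        racc_g=_sample_range(rng, *params["racc_range"]),
        is_beverage=bool(params["is_beverage"]),
    )


def _roster(n_categories: int, archetypes: Mapping[str, Mapping],
            rng: np.random.Generator) -> list[tuple[str, int]]:
    """Deterministic (archetype, code) assignment for the table."""
    # one of every archetype first (pinning the archetypes with fixed codes
    # to their first code) so small tables still span the food space, then
    # the remaining fixed codes so the phase exclusion lists are meaningful
    first_code = {"water_like": _WATER_CODES[0], "dairy": _DAIRY_CODES[0],
                  "baby_food": _BABY_CODES[0], "nutritional_beverage": 7208,
                  "protein_powder": 9802}
    slots: list[tuple[str, int | None]] = [
        (a, first_code.get(a)) for a in archetypes
    ]
    slots += [("water_like", c) for c in _WATER_CODES[1:]]
    slots += [("dairy", c) for c in _DAIRY_CODES[1:]]
    slots += [("baby_food", c) for c in _BABY_CODES[1:]]
    # random fill for the remainder
    names = sorted(archetypes)
    weights = np.array([archetypes[a]["fill_weight"] for a in names], dtype=float)
    weights /= weights.sum()
    while len(slots) < n_categories:
        slots.append((str(rng.choice(names, p=weights)), None))
    slots = slots[:n_categories]
    # assign generic 4-digit codes to unpinned slots
    out: list[tuple[str, int]] = []
    next_code = 2000
    for archetype, code in slots:
        if code is None:
            while next_code in _RESERVED:
                next_code += 2
            code, next_code = next_code, next_code + 2
        out.append((archetype, code))
    return out


def generate_food_db(
    n_categories: int = 150,
    seed: int = 0,
    archetype_file: str | Path | None = None,
) -> list[FoodCategory]:
    """Generate a seeded archetype-based food-category table.

    The table always carries the fixed dairy / water / baby-food codes (as
    capacity allows) so the phase exclusion sets are exercised; remaining
    rows are drawn across archetypes by their fill weights.
    """
    if n_categories < 20:
        raise ValidationError(f"n_categories must be >= 20, got {n_categories}")
    archetypes = load_archetypes(archetype_file)
    rng = np.random.default_rng(seed)
    return [
        _make_category(rng, code, archetype, archetypes[archetype])
        for archetype, code in _roster(n_categories, archetypes, rng)
    ]


def consumption_params(
    foods: Sequence[FoodCategory],
    seed: int = 0,
    archetype_file: str | Path | None = None,
) -> dict[int, tuple[float, float, float]]:
    """Per-category (consumption probability, median g, log-sd) for intakes.

    Categories generated by :func:`generate_food_db` carry their archetype in
    the name; anything unrecognised falls back to a generic prior keyed on
    the category's serving size.
    """
    archetypes = load_archetypes(archetype_file)
    by_display = {p["display"]: p for p in archetypes.values()}
    rng = np.random.default_rng(seed)
    params: dict[int, tuple[float, float, float]] = {}
    for f in foods:
        display = f.name.rsplit(" ", 1)[0]
        p = by_display.get(display)
        if p is not None:
            params[f.code] = (
                float(p["consumption_prob"]),
                float(p["amount_g_median"]),
                float(p["amount_logsd"]),
            )
        else:
            params[f.code] = (
                float(rng.uniform(0.05, 0.5)),
                f.racc_g * float(rng.uniform(0.8, 2.0)),
                float(rng.uniform(0.4, 0.8)),
            )
    return params


def generate_intakes(
    foods: Sequence[FoodCategory],
    n_persons: int = 2000,
    seed: int = 0,
    params: Mapping[int, tuple[float, float, float]] | None = None,
) -> list[IntakeSample]:
    """Zero-inflated log-normal single-day intakes with dispersed weights.

    ``params`` maps code to (consumption probability, median grams, log-sd)
    and defaults to :func:`consumption_params` for the same seed.
    """
    if n_persons < 10:
        raise ValidationError(f"n_persons must be >= 10, got {n_persons}")
    if not foods:
        raise ValidationError("empty food table")
    if params is None:
        params = consumption_params(foods, seed)
    rng = np.random.default_rng(seed)
    samples: list[IntakeSample] = []
    codes = [f.code for f in foods]
    probs = np.array([params[c][0] for c in codes])
    medians = np.array([params[c][1] for c in codes])
    logsds = np.array([params[c][2] for c in codes])
    for i in range(n_persons):
        consumed = rng.random(len(codes)) < probs
        amounts = np.exp(
            np.log(medians) + logsds * rng.standard_normal(len(codes))
        )
        grams = {
            code: float(amount)
            for code, flag, amount in zip(codes, consumed, amounts)
            if flag
        }
        samples.append(
            IntakeSample(
                person_id=f"P{i:05d}",
                sample_weight=float(np.exp(rng.normal(0.0, 0.5))),
                grams_by_category=grams,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Planted-optimum instances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedInstance:
    """A small LP whose unique optimum is known by construction."""

    foods: list[FoodCategory]
    target: DairyReference
    solution: dict[int, float]  # grams per code at the unique optimum
    binding: frozenset[str]
    objective_value: float


def _try_plant(
    rng: np.random.Generator, n_foods: int, binding: tuple[str, ...]
) -> PlantedInstance | None:
    k = len(binding)
    n_nut = len(CONSTRAINED_NUTRIENTS)
    # per-gram coefficients, strictly positive so every nutrient is delivered
    a = rng.uniform(0.1, 5.0, size=(n_nut, n_foods))
    x_star = np.zeros(n_foods)
    x_star[:k] = rng.uniform(50.0, 300.0, size=k)

    binding_idx = [CONSTRAINED_NUTRIENTS.index(b) for b in binding]
    basis = a[np.ix_(binding_idx, range(k))]
    if abs(np.linalg.det(basis)) < 1e-6:
        return None

    delivered = a @ x_star
    b = np.where(
        np.isin(np.arange(n_nut), binding_idx), delivered, 0.5 * delivered
    )

    # price via duality: zero reduced cost on the support, strictly positive
    # reduced cost elsewhere -> the planted vertex is the unique optimum
    y = rng.uniform(0.5, 2.0, size=k)
    c = a[binding_idx, :].T @ y
    c[k:] += rng.uniform(0.1, 1.0, size=n_foods - k)
    if np.any(c <= 0):
        return None

    codes = [4000 + 2 * i for i in range(n_foods)]
    foods = []
    for i, code in enumerate(codes):
        nutrients = dict(zip(CONSTRAINED_NUTRIENTS, a[:, i] * 100.0))
        nutrients["energy"] = float(rng.uniform(100.0, 1500.0))
        foods.append(
            FoodCategory(
                code=code,
                name=f"planted food {code}",
                nutrients_per_100g=NutrientVector(**nutrients),
                cost_per_100g=float(c[i] * 100.0),
                racc_g=100.0,
            )
        )
    per_serving = dict(zip(CONSTRAINED_NUTRIENTS, map(float, b)))
    objective = float(c @ x_star)
    target = DairyReference(
        per_serving=NutrientVector(**per_serving),
        cost_per_serving=objective,
        weight_per_serving=float(x_star.sum()),
    )

    # certify with the exact oracle before returning
    spec = build_lp(foods, target, "cost")
    optima = optimal_vertices(spec, rel=1e-9)
    if len(optima) != 1:
        return None
    if not np.allclose(optima[0], x_star, rtol=1e-7, atol=1e-7):
        return None
    return PlantedInstance(
        foods=foods,
        target=target,
        solution=dict(zip(codes, map(float, x_star))),
        binding=frozenset(binding),
        objective_value=objective,
    )


def planted_optimum_instance(
    n_foods: int,
    binding: Iterable[str],
    seed: int = 0,
    max_retries: int = 50,
) -> PlantedInstance:
    """Construct an instance whose unique minimum-cost optimum is known.

    The requested ``binding`` nutrients (a subset of the 11 constrained ones,
    at most ``n_foods`` of them) are exactly the constraints with zero slack
    at the optimum; every other constrained nutrient is strictly slack.  The
    construction is certified against the brute-force oracle before return.
    """
    binding = tuple(dict.fromkeys(binding))
    if not 2 <= n_foods <= 6:
        raise ValidationError(f"n_foods must be in [2, 6], got {n_foods}")
    unknown = set(binding) - set(CONSTRAINED_NUTRIENTS)
    if unknown:
        raise ValidationError(f"unknown binding nutrient(s): {sorted(unknown)}")
    if not 1 <= len(binding) <= n_foods:
        raise ValidationError(
            f"need 1..{n_foods} binding nutrients, got {len(binding)}"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        instance = _try_plant(rng, n_foods, binding)
        if instance is not None:
            return instance
    raise GenerationError(
        f"could not plant an instance after {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# Dairy-reference fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DairyFixture:
    """Milk/cheese/yogurt component profiles plus their 53/45/2 composite."""

    milk: tuple[NutrientVector, float, float]
    cheese: tuple[NutrientVector, float, float]
    yogurt: tuple[NutrientVector, float, float]
    reference: DairyReference


COMPOSITE_WEIGHTS = (0.53, 0.45, 0.02)

# Fixture composite per-serving targets.  Energy (435 kJ), cost (0.41 US$)
# and sodium (133 mg) are pinned to published per-serving figures; all other
# amounts are plausible stand-ins and are meant to be overridden with real
# reference data where available.
_FIXTURE_TARGET: dict[str, float] = {
    "protein": 9.3,
    "calcium": 330.0,
    "choline": 30.0,
    "fibre": 0.0,
    "iron": 0.1,
    "magnesium": 29.0,
    "potassium": 380.0,
    "vitamin_a": 140.0,
    "vitamin_c": 0.6,
    "vitamin_d": 2.9,
    "vitamin_e": 0.06,
    "energy": 435.0,
    "sodium": 133.0,
    "added_sugars": 0.0,
    "saturated_fat": 2.6,
}
_FIXTURE_COST = 0.41
_FIXTURE_WEIGHT = 152.0

# Per-component-serving fixture profiles for fat-free milk and low-fat
# yogurt; the cheese profile is derived so the composite hits the target
# exactly.
_MILK = {
    "protein": 8.3, "calcium": 300.0, "choline": 38.0, "fibre": 0.0,
    "iron": 0.07, "magnesium": 27.0, "potassium": 382.0, "vitamin_a": 149.0,
    "vitamin_c": 0.0, "vitamin_d": 2.9, "vitamin_e": 0.03, "energy": 347.0,
    "sodium": 103.0, "added_sugars": 0.0, "saturated_fat": 0.1,
}
_MILK_COST, _MILK_WEIGHT = 0.23, 245.0
_YOGURT = {
    "protein": 12.9, "calcium": 448.0, "choline": 38.0, "fibre": 0.0,
    "iron": 0.2, "magnesium": 42.0, "potassium": 573.0, "vitamin_a": 35.0,
    "vitamin_c": 2.0, "vitamin_d": 1.2, "vitamin_e": 0.06, "energy": 644.0,
    "sodium": 86.0, "added_sugars": 0.0, "saturated_fat": 2.0,
}
_YOGURT_COST, _YOGURT_WEIGHT = 0.55, 163.0


def dairy_fixture() -> DairyFixture:
    """Fixture dairy components and their composite reference serving.

    The cheese profile is solved from the target so the 0.53/0.45/0.02
    composite reproduces the pinned per-serving energy, cost and sodium
    exactly; the derivation keeps every component amount nonnegative.
    """
    w_milk, w_cheese, w_yogurt = COMPOSITE_WEIGHTS

    def _cheese_value(target: float, milk: float, yogurt: float) -> float:
        value = (target - w_milk * milk - w_yogurt * yogurt) / w_cheese
        if value < 0:
            raise GenerationError("fixture cheese profile went negative")
        return value

    cheese = {
        fld: _cheese_value(_FIXTURE_TARGET[fld], _MILK[fld], _YOGURT[fld])
        for fld in ALL_NUTRIENT_FIELDS
    }
    cheese_cost = _cheese_value(_FIXTURE_COST, _MILK_COST, _YOGURT_COST)
    cheese_weight = _cheese_value(_FIXTURE_WEIGHT, _MILK_WEIGHT, _YOGURT_WEIGHT)

    milk = (NutrientVector(**_MILK), _MILK_COST, _MILK_WEIGHT)
    cheese_t = (NutrientVector(**cheese), cheese_cost, cheese_weight)
    yogurt = (NutrientVector(**_YOGURT), _YOGURT_COST, _YOGURT_WEIGHT)
    reference = build_dairy_reference(milk, cheese_t, yogurt, COMPOSITE_WEIGHTS)
    return DairyFixture(milk=milk, cheese=cheese_t, yogurt=yogurt,
                        reference=reference)
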
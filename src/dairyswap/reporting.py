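"""Translate optimisation results into reporting quantities: servings
scaling, RACC servings, ratios versus the dairy reference, nutrients to
limit, and calcium-matched profile comparisons.

The machine-readable outputs carry unambiguous ratios (combination divided by
reference) and absolute excesses; "times more" prose renderings are left to
display code because that phrase is used inconsistently in the wild.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .data_model import (
    ALL_NUTRIENT_FIELDS,
    DairyReference,
    FoodCategory,
    NutrientVector,
)
from .errors import StateError, ValidationError
from .lp_core import OptimisationResult, binding_nutrients

__all__ = [
    "ScaledReport",
    "scale_to_servings",
    "to_racc_servings",
    "ratios_vs_reference",
    "nutrients_to_limit_summary",
    "compare_to_reference",
    "grid_report",
    "write_grid_report",
]

#: Added-sugar teaspoon conversion (USDA labelling convention).
GRAMS_PER_TSP_SUGAR = 4.2

#: Energy densities used for percent-of-energy threshold flags.
KJ_PER_G_SUGAR = 16.736      # 4 kcal/g
KJ_PER_G_SAT_FAT = 37.656    # 9 kcal/g

SODIUM_LIMIT_MG_PER_DAY = 2300.0


@dataclass(frozen=True)
class ScaledReport:
    """An optimisation result scaled to ``multiplier`` servings per day."""

    multiplier: float
    daily_cost_usd: float
    daily_energy_kj: float
    daily_weight_g: float
    daily_grams: dict[int, float]
    racc_servings: dict[int, float] = field(default_factory=dict)


def scale_to_servings(
    result: OptimisationResult,
    multiplier: float,
    foods: Sequence[FoodCategory] | None = None,
) -> ScaledReport:
    """Scale per-serving totals and per-category grams to a daily multiple.

    When ``foods`` is supplied, approximate RACC servings (grams / RACC,
    one decimal place) are included for every selected category.
    """
    if result.status != "optimal":
        raise StateError(f"cannot scale a {result.status!r} result")
    if multiplier <= 0:
        raise ValidationError(f"multiplier must be > 0, got {multiplier!r}")
    daily = {c: g * multiplier for c, g in result.selected().items()}
    servings: dict[int, float] = {}
    if foods is not None:
        racc = {f.code: f.racc_g for f in foods}
        servings = {c: to_racc_servings(g, racc[c]) for c, g in daily.items() if c in racc}
    return ScaledReport(
        multiplier=multiplier,
        daily_cost_usd=result.cost_total * multiplier,
        daily_energy_kj=result.energy_total * multiplier,
        daily_weight_g=result.weight_total * multiplier,
        daily_grams=daily,
        racc_servings=servings,
    )


def to_racc_servings(grams: float, racc_g: float) -> float:
    """Approximate number of reference servings, to one decimal place."""
    if racc_g <= 0:
        raise ValidationError(f"racc_g must be > 0, got {racc_g!r}")
    if grams < 0:
        raise ValidationError(f"grams must be >= 0, got {grams!r}")
    return round(grams / racc_g, 1)


def ratios_vs_reference(
    result: OptimisationResult, reference: DairyReference
) -> dict[str, float]:
    """Cost/energy/weight ratios (combination / reference) and excesses."""
    if result.status != "optimal":
        raise StateError(f"cannot compare a {result.status!r} result")
    ref = {
        "cost": reference.cost_per_serving,
        "energy": reference.per_serving.energy,
        "weight": reference.weight_per_serving,
    }
    combo = {
        "cost": result.cost_total,
        "energy": result.energy_total,
        "weight": result.weight_total,
    }
    out: dict[str, float] = {}
    for key in ("cost", "energy", "weight"):
        if ref[key] <= 0:
            raise ValidationError(f"reference {key} must be > 0 for ratios")
        out[f"{key}_ratio"] = combo[key] / ref[key]
        out[f"{key}_excess"] = combo[key] - ref[key]
    return out


def nutrients_to_limit_summary(
    result: OptimisationResult,
    reference: DairyReference,
    daily_energy_kj: float | None = None,
) -> dict[str, float | bool | None]:
    """Sodium, added sugars (g and tsp) and saturated fat in the combination.

    Ratios versus the reference serving are included where the reference
    amount is positive (None otherwise, e.g. added sugars in plain dairy).
    Guideline threshold flags are evaluated only when a daily energy intake
    is supplied; sugar and saturated-fat limits are fractions of energy,
    sodium is an absolute daily amount.
    """
    if result.status != "optimal":
        raise StateError(f"cannot summarise a {result.status!r} result")
    sodium = result.delivered.get("sodium", 0.0)
    sugars = result.delivered.get("added_sugars", 0.0)
    sat_fat = result.delivered.get("saturated_fat", 0.0)
    ref = reference.per_serving

    def _ratio(value: float, ref_value: float) -> float | None:
        return value / ref_value if ref_value > 0 else None

    summary: dict[str, float | bool | None] = {
        "sodium_mg": sodium,
        "added_sugars_g": sugars,
        "added_sugars_tsp": sugars / GRAMS_PER_TSP_SUGAR,
        "saturated_fat_g": sat_fat,
        "sodium_ratio": _ratio(sodium, ref.sodium),
        "added_sugars_ratio": _ratio(sugars, ref.added_sugars),
        "saturated_fat_ratio": _ratio(sat_fat, ref.saturated_fat),
    }
    if daily_energy_kj is not None:
        if daily_energy_kj <= 0:
            raise ValidationError("daily_energy_kj must be > 0 when supplied")
        summary["added_sugars_exceeds_10pct_energy"] = (
            sugars * KJ_PER_G_SUGAR > 0.10 * daily_energy_kj
        )
        summary["saturated_fat_exceeds_10pct_energy"] = (
            sat_fat * KJ_PER_G_SAT_FAT > 0.10 * daily_energy_kj
        )
        summary["sodium_exceeds_limit"] = sodium > SODIUM_LIMIT_MG_PER_DAY
    return summary


def compare_to_reference(
    profile: NutrientVector,
    cost: float,
    reference: DairyReference,
    match_on: str = "calcium",
) -> dict[str, float | None]:
    """Percent difference per field after matching one nutrient's level.

    The profile is rescaled so its ``match_on`` amount equals the reference
    serving's, then each field is reported as ``100 * (scaled - ref) / ref``
    (None where the reference amount is zero).  Invariant to any positive
    rescaling of the input profile.
    """
    if match_on not in ALL_NUTRIENT_FIELDS:
        raise ValidationError(f"unknown nutrient {match_on!r}")
    anchor = getattr(profile, match_on)
    if anchor <= 0:
        raise ValidationError(f"profile {match_on} must be > 0 to match on it")
    ref_anchor = getattr(reference.per_serving, match_on)
    if ref_anchor <= 0:
        raise ValidationError(f"reference {match_on} must be > 0 to match on it")
    factor = ref_anchor / anchor
    out: dict[str, float | None] = {}
    for fld in ALL_NUTRIENT_FIELDS:
        ref_value = getattr(reference.per_serving, fld)
        scaled = getattr(profile, fld) * factor
        out[fld] = 100.0 * (scaled - ref_value) / ref_value if ref_value > 0 else None
    ref_cost = reference.cost_per_serving
    out["cost"] = (
        100.0 * (cost * factor - ref_cost) / ref_cost if ref_cost > 0 else None
    )
    return out


def grid_report(
    results: dict[str, OptimisationResult],
    foods: Sequence[FoodCategory],
    reference: DairyReference,
    multipliers: Sequence[float] = (1.0, 1.8, 3.0),
) -> pd.DataFrame:
    """One wide summary row per scenario at each servings multiplier."""
    racc = {f.code: f.racc_g for f in foods}
    names = {f.code: f.name for f in foods}
    rows = []
    for label, result in results.items():
        if result.status != "optimal":
            rows.append({"scenario": label, "status": result.status})
            continue
        ratios = ratios_vs_reference(result, reference)
        for s in multipliers:
            report = scale_to_servings(result, s, foods)
            rows.append(
                {
                    "scenario": label,
                    "status": result.status,
                    "multiplier": s,
                    "cost_usd": report.daily_cost_usd,
                    "energy_kj": report.daily_energy_kj,
                    "weight_g": report.daily_weight_g,
                    "cost_ratio": ratios["cost_ratio"],
                    "energy_ratio": ratios["energy_ratio"],
                    "weight_ratio": ratios["weight_ratio"],
                    "binding": ";".join(binding_nutrients(result)),
                    "foods": "; ".join(
                        f"{names.get(c, c)} {g:.0f}g ({to_racc_servings(g, racc[c]):.1f} srv)"
                        for c, g in sorted(report.daily_grams.items())
                        if c in racc
                    ),
                }
            )
    return pd.DataFrame(rows)


def write_grid_report(
    results: dict[str, OptimisationResult],
    foods: Sequence[FoodCategory],
    reference: DairyReference,
    out_dir: str | Path,
    multipliers: Sequence[float] = (1.0, 1.8, 3.0),
) -> None:
    """Write the wide summary table (CSV) and a structured JSON mirror."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = grid_report(results, foods, reference, multipliers)
    table.to_csv(out / "grid_report.csv", index=False)
    mirror = {}
    for label, result in results.items():
        entry: dict[str, object] = {"status": result.status}
        if result.status == "optimal":
            entry.update(
                {
                    "objective": result.objective,
                    "objective_value": result.objective_value,
                    "cost_usd": result.cost_total,
                    "energy_kj": result.energy_total,
                    "weight_g": result.weight_total,
                    "grams_by_category": {
                        str(c): g for c, g in result.selected().items()
                    },
                    "slack": result.slack,
                    "binding": binding_nutrients(result),
                    "ratios": ratios_vs_reference(result, reference),
                }
            )
        else:
            entry["message"] = result.message
        mirror[label] = entry
    with open(out / "grid_report.json", "w") as fh:
        json.dump(mirror, fh, indent=2)
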
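"""Price attachment and adjustment: CPI inflation, mixed-dish component
regression, and explicit per-category price overrides."""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .data_model import FoodCategory
from .errors import EstimationError, ValidationError

__all__ = [
    "CpiSeries",
    "ComponentMatrix",
    "ComponentCostFit",
    "PriceOverride",
    "adjust_for_inflation",
    "estimate_component_costs",
    "apply_price_overrides",
    "apply_code_crosswalk",
    "load_cpi_series",
    "load_price_overrides",
]


@dataclass(frozen=True)
class CpiSeries:
    """Monthly CPI values spanning one named 2-year survey cycle."""

    cycle: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValidationError(f"CPI series {self.cycle!r} is empty")
        if any(v <= 0 for v in self.values):
            raise ValidationError(f"CPI series {self.cycle!r} has non-positive values")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def load_cpi_series(path: str | Path, cycle: str = "") -> CpiSeries:
    """Read a ``month,index_value`` delimited file into a :class:`CpiSeries`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if "index_value" not in df.columns:
        raise ValidationError("CPI file must have an 'index_value' column")
    return CpiSeries(cycle=cycle or str(path), values=tuple(df["index_value"]))


def adjust_for_inflation(price: float, base: CpiSeries, target: CpiSeries) -> float:
    """Inflate ``price`` from the base cycle to the target cycle.

    Uses the ratio of arithmetic means of the monthly index over each cycle:
    ``price * mean(target) / mean(base)``.
    """
    return price * target.mean / base.mean


@dataclass(frozen=True)
class ComponentMatrix:
    """Design matrix for the mixed-dish cost regression.

    Rows are dishes with an observed total cost per 100 g; columns are
    food-pattern components; entries are component amounts per 100 g of dish.
    """

    dish_names: tuple[str, ...]
    component_names: tuple[str, ...]
    amounts: np.ndarray  # (n_dishes, n_components)

    def __post_init__(self) -> None:
        a = np.asarray(self.amounts, dtype=float)
        object.__setattr__(self, "amounts", a)
        if a.ndim != 2 or a.shape != (len(self.dish_names), len(self.component_names)):
            raise ValidationError("amounts shape does not match dish/component names")
        if np.any(a < 0):
            raise ValidationError("component amounts must be >= 0")
        zero_rows = np.where(~a.any(axis=1))[0]
        if zero_rows.size:
            raise ValidationError(
                f"all-zero dish row(s): {[self.dish_names[i] for i in zero_rows]}"
            )


@dataclass(frozen=True)
class ComponentCostFit:
    """Nonnegative least-squares unit costs plus fitted dish costs."""

    unit_costs: Mapping[str, float]
    intercept: float
    fitted: np.ndarray
    residuals: np.ndarray

    def predict(self, amounts: Sequence[float]) -> float:
        costs = np.array(list(self.unit_costs.values()))
        return float(np.dot(np.asarray(amounts, dtype=float), costs) + self.intercept)


def _dependent_columns(a: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that are (numerically) linear combinations of earlier ones."""
    dependent: list[str] = []
    basis: list[np.ndarray] = []
    for j in range(a.shape[1]):
        col = a[:, j]
        if basis:
            b = np.column_stack(basis)
            resid = col - b @ np.linalg.lstsq(b, col, rcond=None)[0]
        else:
            resid = col
        if np.linalg.norm(resid) <= 1e-10 * max(1.0, np.linalg.norm(col)):
            dependent.append(names[j])
        else:
            basis.append(col)
    return dependent


def estimate_component_costs(
    dishes: ComponentMatrix,
    dish_costs: Sequence[float],
    *,
    intercept: bool = False,
    weights: Sequence[float] | None = None,
) -> ComponentCostFit:
    """Recover per-unit component costs from observed total dish costs.

    Ordinary least squares on component amounts with unit costs constrained
    nonnegative; no intercept by default (a zero-amount dish costs ~0).  An
    optional unconstrained intercept and observation weights are exposed
    because the originating regression form is not fully documented.
    """
    a = dishes.amounts
    y = np.asarray(dish_costs, dtype=float)
    if y.shape != (a.shape[0],):
        raise ValidationError("dish_costs length must equal the number of dishes")
    if a.shape[0] < a.shape[1]:
        raise EstimationError(
            f"need at least as many dishes ({a.shape[0]}) as components ({a.shape[1]})"
        )
    if np.linalg.matrix_rank(a) < a.shape[1]:
        raise EstimationError(
            "component matrix is rank deficient; dependent column(s): "
            f"{_dependent_columns(a, dishes.component_names)}"
        )
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        a, y = a * w[:, None], y * w
    design = a
    lower: list[float] = [0.0] * a.shape[1]
    upper = [np.inf] * a.shape[1]
    if intercept:
        design = np.column_stack([a, np.ones(a.shape[0])])
        lower, upper = lower + [-np.inf], upper + [np.inf]
    sol = lsq_linear(design, y, bounds=(lower, upper), method="bvls")
    coef = sol.x
    fitted = design @ coef
    return ComponentCostFit(
        unit_costs=dict(zip(dishes.component_names, coef[: a.shape[1]])),
        intercept=float(coef[-1]) if intercept else 0.0,
        fitted=fitted,
        residuals=y - fitted,
    )


@dataclass(frozen=True)
class PriceOverride:
    """An explicit price rule: ``basis`` is ``per_100g`` or ``per_litre``."""

    price: float
    basis: str = "per_100g"

    def __post_init__(self) -> None:
        if self.basis not in ("per_100g", "per_litre"):
            raise ValidationError(f"unknown price basis {self.basis!r}")
        if self.price < 0:
            raise ValidationError("override price must be >= 0")

    def cost_per_100g(self) -> float:
        # per-litre rules assume density 1 g/ml (water-dominant beverages)
        if self.basis == "per_litre":
            return self.price / 10.0
        return self.price


def load_price_overrides(path: str | Path) -> dict[int, PriceOverride]:
    """Read a ``code,price,basis`` delimited override file."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("code", "price", "basis"):
        if col not in df.columns:
            raise ValidationError(f"override file missing column {col!r}")
    return {
        int(r.code): PriceOverride(price=float(r.price), basis=str(r.basis))
        for r in df.itertuples()
    }


def apply_price_overrides(
    foods: Sequence[FoodCategory], overrides: Mapping[int, PriceOverride]
) -> list[FoodCategory]:
    """Return a new table with the named categories re-priced."""
    known = {f.code for f in foods}
    unknown = sorted(set(overrides) - known)
    if unknown:
        raise ValidationError(f"override code(s) not in food table: {unknown}")
    return [
        f.with_cost(overrides[f.code].cost_per_100g()) if f.code in overrides else f
        for f in foods
    ]


def apply_code_crosswalk(
    foods: Sequence[FoodCategory], crosswalk: Mapping[int, int]
) -> tuple[list[FoodCategory], list[int]]:
    """Re-map category codes between database vintages.

    Returns the remapped table and the list of codes that had no mapping
    (reported, never silently dropped).
    """
    remapped: list[FoodCategory] = []
    unmapped: list[int] = []
    import dataclasses

    for f in foods:
        if f.code in crosswalk:
            remapped.append(dataclasses.replace(f, code=crosswalk[f.code]))
        else:
            remapped.append(f)
            unmapped.append(f.code)
    return remapped, unmapped
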
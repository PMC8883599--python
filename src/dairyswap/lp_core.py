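"""Build and solve the nutrient-replacement linear programme.

The programme minimises cost (US$), energy (kJ) or food weight (g) of a
combination of food categories subject to delivering at least the reference
serving's amount of each of the 11 constrained nutrients::

    min  c . x
    s.t. A x >= b        (11 nutrient rows, per-gram coefficients)
         0 <= x <= u     (per-category gram caps; excluded categories fixed 0)

Nutrient units span g/mg/µg, so feasibility is judged on *scaled* rows (each
row divided by its target when the target is positive).

``brute_force_oracle`` enumerates basic solutions exactly and is the
correctness anchor for the solver on small instances.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping, Sequence, Set
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .data_model import (
    ALL_NUTRIENT_FIELDS,
    CONSTRAINED_NUTRIENTS,
    DairyReference,
    FoodCategory,
)
from .errors import SizeError, SpecificationError, StateError, ValidationError

__all__ = [
    "LpSpec",
    "OptimisationResult",
    "OracleResult",
    "build_lp",
    "solve_lp",
    "binding_nutrients",
    "brute_force_oracle",
]

#: Default absolute feasibility tolerance on scaled constraint rows.
DEFAULT_TOLERANCE = 1e-9


@dataclass(frozen=True)
class LpSpec:
    """A fully materialised instance of the replacement programme."""

    codes: tuple[int, ...]
    objective: str  # cost | energy | weight
    c: np.ndarray  # (n,) objective coefficients per gram
    A: np.ndarray  # (11, n) constrained-nutrient amounts per gram
    b: np.ndarray  # (11,) per-serving targets
    upper: np.ndarray  # (n,) gram caps, np.inf when uncapped
    excluded: frozenset[int] = frozenset()
    cost_per_g: np.ndarray | None = None
    energy_per_g: np.ndarray | None = None
    full_per_g: np.ndarray | None = None  # (15, n) all nutrient fields per gram
    nutrient_names: tuple[str, ...] = CONSTRAINED_NUTRIENTS

    def __post_init__(self) -> None:
        n = len(self.codes)
        for name in ("c", "A", "b", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.A.shape != (len(self.nutrient_names), n):
            raise ValidationError(f"A must be {(len(self.nutrient_names), n)}")
        if self.c.shape != (n,) or self.upper.shape != (n,):
            raise ValidationError("c and upper must have one entry per category")
        if self.b.shape != (len(self.nutrient_names),):
            raise ValidationError("b must have one entry per constrained nutrient")
        if np.any(self.A < 0) or np.any(self.b < 0) or np.any(self.upper < 0):
            raise ValidationError("A, b and upper bounds must all be >= 0")
        for code in self.excluded:
            if code in self.codes and self.upper[self.codes.index(code)] != 0:
                raise ValidationError(f"excluded code {code} has a non-zero bound")

    @property
    def n_vars(self) -> int:
        return len(self.codes)

    def row_scale(self) -> np.ndarray:
        """Per-row divisor: the target where positive, 1 otherwise."""
        return np.where(self.b > 0, self.b, 1.0)


@dataclass(frozen=True)
class OptimisationResult:
    """Solver output: selected grams, totals, slacks and status."""

    status: str  # optimal | infeasible | unbounded
    objective: str
    codes: tuple[int, ...]
    grams: np.ndarray
    objective_value: float | None
    cost_total: float | None
    energy_total: float | None
    weight_total: float | None
    delivered: dict[str, float] = field(default_factory=dict)
    targets: dict[str, float] = field(default_factory=dict)
    slack: dict[str, float] = field(default_factory=dict)
    message: str = ""

    @property
    def grams_by_category(self) -> dict[int, float]:
        return {c: float(g) for c, g in zip(self.codes, self.grams)}

    def selected(self, threshold: float = 1e-9) -> dict[int, float]:
        """Categories with more than ``threshold`` grams in the solution."""
        return {c: g for c, g in self.grams_by_category.items() if g > threshold}


def build_lp(
    foods: Sequence[FoodCategory],
    target: DairyReference,
    objective: str,
    *,
    caps: Mapping[int, float] | pd.DataFrame | None = None,
    exclusions: Set[int] = frozenset(),
) -> LpSpec:
    """Assemble the LP from a food table, a reference serving and options.

    ``caps`` maps category code to a gram upper bound (NaN entries mean no
    cap); a caps table with ``code`` and ``p90_g`` columns is also accepted.
    Exclusion codes absent from the food table are ignored.
    """
    if objective not in ("cost", "energy", "weight"):
        raise SpecificationError(f"unknown objective {objective!r}")
    if not foods:
        raise SpecificationError("empty food table")
    if all(f.code in exclusions for f in foods):
        raise SpecificationError("all categories are excluded")

    if isinstance(caps, pd.DataFrame):
        caps = {
            int(r.code): float(r.p90_g)
            for r in caps.itertuples()
            if np.isfinite(r.p90_g)
        }
    caps = caps or {}

    codes = tuple(f.code for f in foods)
    per_g = (
        np.column_stack([f.nutrients_per_100g.as_array() for f in foods]) / 100.0
    )  # (15, n) in ALL_NUTRIENT_FIELDS order
    constrained_idx = [ALL_NUTRIENT_FIELDS.index(f) for f in CONSTRAINED_NUTRIENTS]
    a = per_g[constrained_idx, :]
    cost_per_g = np.array([f.cost_per_100g for f in foods]) / 100.0
    energy_per_g = per_g[ALL_NUTRIENT_FIELDS.index("energy"), :]

    if objective == "cost":
        c = cost_per_g.copy()
    elif objective == "energy":
        c = energy_per_g.copy()
    else:
        c = np.ones(len(foods))

    upper = np.full(len(foods), np.inf)
    for i, code in enumerate(codes):
        if code in exclusions:
            upper[i] = 0.0
        elif code in caps and np.isfinite(caps[code]):
            upper[i] = caps[code]

    return LpSpec(
        codes=codes,
        objective=objective,
        c=c,
        A=a,
        b=target.targets(),
        upper=upper,
        excluded=frozenset(exclusions) & set(codes),
        cost_per_g=cost_per_g,
        energy_per_g=energy_per_g,
        full_per_g=per_g,
    )


def _most_limited_nutrient(spec: LpSpec) -> str | None:
    """Nutrient whose target is least attainable given the bounds alone."""
    worst, worst_ratio = None, np.inf
    for j, name in enumerate(spec.nutrient_names):
        if spec.b[j] <= 0:
            continue
        row = spec.A[j]
        if np.any((row > 0) & ~np.isfinite(spec.upper)):
            continue  # unbounded supply of this nutrient
        achievable = float(np.sum(row * np.where(np.isfinite(spec.upper), spec.upper, 0)))
        ratio = achievable / spec.b[j]
        if ratio < worst_ratio:
            worst, worst_ratio = name, ratio
    return worst if worst_ratio < 1 else None


def _assemble_result(
    spec: LpSpec, status: str, x: np.ndarray | None, message: str = ""
) -> OptimisationResult:
    if x is None:
        return OptimisationResult(
            status=status,
            objective=spec.objective,
            codes=spec.codes,
            grams=np.full(spec.n_vars, np.nan),
            objective_value=None,
            cost_total=None,
            energy_total=None,
            weight_total=None,
            message=message,
        )
    x = np.clip(x, 0.0, None)
    delivered_constrained = spec.A @ x
    delivered: dict[str, float] = {}
    if spec.full_per_g is not None:
        full = spec.full_per_g @ x
        delivered = dict(zip(ALL_NUTRIENT_FIELDS, map(float, full)))
    else:
        delivered = dict(
            zip(spec.nutrient_names, map(float, delivered_constrained))
        )
    cost_total = (
        float(spec.cost_per_g @ x) if spec.cost_per_g is not None else None
    )
    energy_total = (
        float(spec.energy_per_g @ x)
        if spec.energy_per_g is not None
        else delivered.get("energy")
    )
    return OptimisationResult(
        status=status,
        objective=spec.objective,
        codes=spec.codes,
        grams=x,
        objective_value=float(spec.c @ x),
        cost_total=cost_total,
        energy_total=energy_total,
        weight_total=float(np.sum(x)),
        delivered=delivered,
        targets=dict(zip(spec.nutrient_names, map(float, spec.b))),
        slack=dict(
            zip(spec.nutrient_names, map(float, delivered_constrained - spec.b))
        ),
        message=message,
    )


def solve_lp(spec: LpSpec, tolerance: float = DEFAULT_TOLERANCE) -> OptimisationResult:
    """Solve the programme with the HiGHS backend."""
    scale = spec.row_scale()
    a_s = spec.A / scale[:, None]
    b_s = spec.b / scale
    bounds = [(0.0, u if np.isfinite(u) else None) for u in spec.upper]
    res = linprog(
        spec.c,
        A_ub=-a_s,
        b_ub=-b_s,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": max(tolerance, 1e-10)},
    )
    if res.status == 2:
        culprit = _most_limited_nutrient(spec)
        detail = f"; most limited nutrient: {culprit}" if culprit else ""
        return _assemble_result(spec, "infeasible", None, f"infeasible{detail}")
    if res.status == 3:
        zero_cost = [c for c, ci in zip(spec.codes, spec.c) if ci <= 0]
        return _assemble_result(
            spec, "unbounded", None, f"unbounded; zero-cost columns: {zero_cost}"
        )
    if res.status != 0:
        return _assemble_result(spec, "infeasible", None, res.message)
    result = _assemble_result(spec, "optimal", res.x)
    worst = min(
        (result.slack[n] / s for n, s in zip(spec.nutrient_names, scale)),
        default=0.0,
    )
    if worst < -max(tolerance, 1e-7):
        return _assemble_result(
            spec, "infeasible", None, f"solution violates constraints by {-worst:.2e}"
        )
    return result


def binding_nutrients(
    result: OptimisationResult, tol: float = 1e-6
) -> list[str]:
    """Constrained nutrients whose slack is (scaled-)zero at the optimum.

    Rows with a zero target are trivially satisfied and never reported as
    binding.  Ordered by scaled slack, tightest first.
    """
    if result.status != "optimal":
        raise StateError(f"binding analysis requires an optimal result, "
                         f"got {result.status!r}")
    scored = []
    for name, target in result.targets.items():
        if target <= 0:
            continue
        scored.append((result.slack[name] / target, name))
    scored.sort()
    return [name for s, name in scored if s <= tol]


@dataclass(frozen=True)
class OracleResult:
    status: str
    objective_value: float | None
    x: np.ndarray | None


def _feasible_vertices(
    spec: LpSpec, tol: float
) -> list[tuple[float, np.ndarray]]:
    n = spec.n_vars
    scale = spec.row_scale()
    a_s = spec.A / scale[:, None]
    b_s = spec.b / scale
    m = len(b_s)

    # candidate active constraints: nutrient rows, lower bounds, finite uppers
    rows: list[tuple[np.ndarray, float]] = [(a_s[j], b_s[j]) for j in range(m)]
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        rows.append((e, 0.0))
        if np.isfinite(spec.upper[i]):
            rows.append((e.copy(), float(spec.upper[i])))

    vertices: list[tuple[float, np.ndarray]] = []
    seen: set[tuple[int, ...]] = set()
    for combo in itertools.combinations(range(len(rows)), n):
        mat = np.array([rows[k][0] for k in combo])
        rhs = np.array([rows[k][1] for k in combo])
        # normalise rows before the singularity test so the verdict does not
        # depend on the scale of the constraint units
        norms = np.linalg.norm(mat, axis=1)
        if np.any(norms < 1e-12):
            continue
        mat_n = mat / norms[:, None]
        if abs(np.linalg.det(mat_n)) < 1e-10:
            continue
        x = np.linalg.solve(mat_n, rhs / norms)
        if np.any(x < -tol) or np.any(x > spec.upper + tol):
            continue
        if np.any(a_s @ x < b_s - tol):
            continue
        key = tuple(np.round(x, 9))
        if key in seen:
            continue
        seen.add(key)
        vertices.append((float(spec.c @ x), np.clip(x, 0.0, None)))
    return vertices


def brute_force_oracle(
    spec: LpSpec, tol: float = 1e-7, max_vars: int = 6
) -> OracleResult:
    """Exact optimum by enumerating every basic solution.

    The feasible region ``{x >= 0, Ax >= b, x <= u}`` is pointed, so it has a
    vertex whenever it is non-empty, and with nonnegative objective
    coefficients some vertex attains the minimum.  Feasibility of a candidate
    vertex is judged with absolute tolerance ``tol`` on scaled rows and
    bounds.
    """
    if spec.n_vars > max_vars:
        raise SizeError(
            f"oracle limited to {max_vars} decision variables, got {spec.n_vars}"
        )
    if np.any(spec.c < 0):
        raise ValidationError("oracle requires nonnegative objective coefficients")
    vertices = _feasible_vertices(spec, tol)
    if not vertices:
        return OracleResult(status="infeasible", objective_value=None, x=None)
    obj, x = min(vertices, key=lambda t: t[0])
    return OracleResult(status="optimal", objective_value=obj, x=x)


def optimal_vertices(
    spec: LpSpec, tol: float = 1e-7, rel: float = 1e-9, max_vars: int = 6
) -> list[np.ndarray]:
    """All vertices attaining the oracle optimum within relative ``rel``.

    Used by the planted-instance generator to certify uniqueness.
    """
    if spec.n_vars > max_vars:
        raise SizeError(f"oracle limited to {max_vars} decision variables")
    vertices = _feasible_vertices(spec, tol)
    if not vertices:
        return []
    best = min(v[0] for v in vertices)
    span = max(abs(best), 1.0)
    return [x for obj, x in vertices if obj - best <= rel * span]
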
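"""Orchestrate the full factorial of runs: 2 phases x 3 objectives x 2 cap
settings, with the fixed exclusion code lists for each phase."""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import pandas as pd

from .data_model import DairyReference, FoodCategory, IntakeSample
from .errors import DairySwapError, ScenarioError, ValidationError
from .lp_core import OptimisationResult, binding_nutrients, build_lp, solve_lp
from .survey_stats import compute_caps

__all__ = [
    "PHASE1_EXCLUSIONS",
    "PHASE2_EXCLUSIONS",
    "ScenarioSpec",
    "phase_exclusions",
    "run_scenario",
    "run_all",
    "all_scenarios",
]

logger = logging.getLogger(__name__)

#: Dairy categories (incl. the dairy component of cheese sandwiches), always
#: excluded: low-fat milk/yogurt, higher-fat milk/yogurt, cheese, cheese
#: sandwiches.
PHASE1_EXCLUSIONS: frozenset[int] = frozenset(
    {1006, 1008, 1206, 1208, 1804, 1404,  # low-fat milk / yogurt
     1002, 1004, 1202, 1204, 1402, 1802,  # higher-fat milk / yogurt
     1602, 1604,                          # cheese
     3720}                                # cheese sandwiches
)

#: Additionally excluded in phase 2: baby foods, infant formulas, protein /
#: nutritional powders, nutritional beverages, and near-zero-energy beverages
#: (coffee, tap water, bottled water, diet drinks).
_PHASE2_EXTRA: frozenset[int] = frozenset(
    {9002, 9004, 9006, 9008, 9010, 9012, 9202,  # baby foods
     9402, 9404,                                # infant formulas
     9802,                                      # protein/nutritional powders
     7208,                                      # nutritional beverages
     7302, 7702, 7704, 7102, 7106}              # coffee, waters, diet drinks
)

PHASE2_EXCLUSIONS: frozenset[int] = PHASE1_EXCLUSIONS | _PHASE2_EXTRA

OBJECTIVES = ("cost", "energy", "weight")
CAP_MODES = ("none", "p90")


def phase_exclusions(phase: int) -> frozenset[int]:
    """Category codes fixed to zero for the given analysis phase."""
    if phase == 1:
        return PHASE1_EXCLUSIONS
    if phase == 2:
        return PHASE2_EXCLUSIONS
    raise ValidationError(f"phase must be 1 or 2, got {phase!r}")


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the run grid."""

    phase: int
    objective: str
    cap_mode: str

    def __post_init__(self) -> None:
        phase_exclusions(self.phase)  # validates phase
        if self.objective not in OBJECTIVES:
            raise ValidationError(f"objective must be one of {OBJECTIVES}")
        if self.cap_mode not in CAP_MODES:
            raise ValidationError(f"cap_mode must be one of {CAP_MODES}")

    @property
    def exclusions(self) -> frozenset[int]:
        return phase_exclusions(self.phase)

    @property
    def label(self) -> str:
        return f"phase{self.phase}/{self.objective}/{self.cap_mode}"

    @classmethod
    def parse(cls, label: str) -> "ScenarioSpec":
        """Parse a ``phaseN/objective/capmode`` label."""
        try:
            phase_part, objective, cap_mode = label.split("/")
            phase = int(phase_part.removeprefix("phase"))
        except (ValueError, AttributeError) as exc:
            raise ValidationError(f"malformed scenario label {label!r}") from exc
        return cls(phase=phase, objective=objective, cap_mode=cap_mode)


def all_scenarios() -> list[ScenarioSpec]:
    """The 12 scenarios in deterministic order."""
    return [
        ScenarioSpec(phase=p, objective=o, cap_mode=m)
        for p in (1, 2)
        for o in OBJECTIVES
        for m in CAP_MODES
    ]


def run_scenario(
    foods: Sequence[FoodCategory],
    intakes: Sequence[IntakeSample],
    target: DairyReference,
    spec: ScenarioSpec,
    *,
    consumers_only: bool = True,
) -> OptimisationResult:
    """Compute caps (when requested), build the LP and solve it."""
    try:
        caps = None
        if spec.cap_mode == "p90":
            codes = [f.code for f in foods if f.code not in spec.exclusions]
            caps = compute_caps(intakes, codes, consumers_only=consumers_only)
        lp = build_lp(
            foods,
            target,
            spec.objective,
            caps=caps,
            exclusions=spec.exclusions,
        )
        result = solve_lp(lp)
    except DairySwapError as exc:
        raise ScenarioError(spec.label, str(exc)) from exc
    logger.info(
        "scenario %s: status=%s objective=%s",
        spec.label,
        result.status,
        result.objective_value,
    )
    return result


@dataclass(frozen=True)
class GridResults:
    """All 12 scenario outcomes plus a flat summary table."""

    results: dict[str, OptimisationResult]
    errors: dict[str, str] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for label, r in self.results.items():
            rows.append(
                {
                    "scenario": label,
                    "status": r.status,
                    "objective": r.objective,
                    "cost_usd": r.cost_total,
                    "energy_kj": r.energy_total,
                    "weight_g": r.weight_total,
                    "n_selected": len(r.selected()) if r.status == "optimal" else 0,
                    "binding": ";".join(binding_nutrients(r))
                    if r.status == "optimal"
                    else "",
                }
            )
        for label, msg in self.errors.items():
            rows.append({"scenario": label, "status": "error", "binding": msg})
        return pd.DataFrame(rows)


def run_all(
    foods: Sequence[FoodCategory],
    intakes: Sequence[IntakeSample],
    target: DairyReference,
    *,
    consumers_only: bool = True,
) -> GridResults:
    """Run the full 2x3x2 grid; failures are recorded per label, not raised."""
    results: dict[str, OptimisationResult] = {}
    errors: dict[str, str] = {}
    for spec in all_scenarios():
        try:
            results[spec.label] = run_scenario(
                foods, intakes, target, spec, consumers_only=consumers_only
            )
        except ScenarioError as exc:
            logger.warning("scenario %s failed: %s", spec.label, exc)
            errors[spec.label] = str(exc)
    return GridResults(results=results, errors=errors)
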
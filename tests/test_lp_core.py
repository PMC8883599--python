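import numpy as np
import pytest

from dairyswap.data_model import (
    CONSTRAINED_NUTRIENTS,
    DairyReference,
    FoodCategory,
    NutrientVector,
)
from dairyswap.errors import SizeError, SpecificationError, StateError, ValidationError
from dairyswap.lp_core import (
    LpSpec,
    OptimisationResult,
    binding_nutrients,
    brute_force_oracle,
    build_lp,
    solve_lp,
)
from dairyswap.synthetic_data import planted_optimum_instance

from .conftest import random_small_spec


def single_food_instance(cap=None):
    """One food with 100 mg calcium per 100 g; target 300 mg -> x = 300 g."""
    food = FoodCategory(
        code=2000,
        name="calcium source",
        nutrients_per_100g=NutrientVector(calcium=100.0, energy=500.0),
        cost_per_100g=0.40,
        racc_g=100.0,
    )
    target = DairyReference(
        per_serving=NutrientVector(calcium=300.0),
        cost_per_serving=0.41,
        weight_per_serving=152.0,
    )
    caps = {2000: cap} if cap is not None else None
    return build_lp([food], target, "cost", caps=caps)


class TestBuildLp:
    def test_weight_objective_is_all_ones(self, small_foods, fixture_reference):
        spec = build_lp(small_foods, fixture_reference, "weight")
        np.testing.assert_array_equal(spec.c, np.ones(len(small_foods)))

    def test_cost_objective_is_per_gram(self, small_foods, fixture_reference):
        spec = build_lp(small_foods, fixture_reference, "cost")
        np.testing.assert_allclose(
            spec.c, [f.cost_per_100g / 100.0 for f in small_foods]
        )

    def test_energy_objective_is_per_gram(self, small_foods, fixture_reference):
        spec = build_lp(small_foods, fixture_reference, "energy")
        np.testing.assert_allclose(
            spec.c, [f.nutrients_per_100g.energy / 100.0 for f in small_foods]
        )

    def test_caps_pass_through(self, small_foods, fixture_reference):
        code = small_foods[0].code
        spec = build_lp(small_foods, fixture_reference, "cost", caps={code: 123.0})
        assert spec.upper[spec.codes.index(code)] == 123.0

    def test_exclusions_fix_zero(self, small_foods, fixture_reference):
        excluded = {small_foods[0].code, small_foods[3].code}
        spec = build_lp(small_foods, fixture_reference, "cost", exclusions=excluded)
        for code in excluded:
            assert spec.upper[spec.codes.index(code)] == 0.0
        result = solve_lp(spec)
        assert result.status == "optimal"
        for code in excluded:
            assert result.grams_by_category[code] == 0.0

    def test_all_excluded_rejected(self, small_foods, fixture_reference):
        with pytest.raises(SpecificationError, match="excluded"):
            build_lp(
                small_foods,
                fixture_reference,
                "cost",
                exclusions={f.code for f in small_foods},
            )

    def test_unknown_objective_rejected(self, small_foods, fixture_reference):
        with pytest.raises(SpecificationError):
            build_lp(small_foods, fixture_reference, "calories")


class TestSolveLp:
    def test_closed_form_single_food(self):
        result = solve_lp(single_food_instance())
        assert result.status == "optimal"
        assert result.grams_by_category[2000] == pytest.approx(300.0)
        assert result.objective_value == pytest.approx(300.0 * 0.004)
        assert result.weight_total == pytest.approx(300.0)
        assert result.energy_total == pytest.approx(300.0 * 5.0)

    def test_totals_are_dot_products(self, small_foods, fixture_reference):
        spec = build_lp(small_foods, fixture_reference, "cost")
        result = solve_lp(spec)
        x = result.grams
        assert result.cost_total == pytest.approx(float(spec.cost_per_g @ x))
        assert result.energy_total == pytest.approx(float(spec.energy_per_g @ x))
        assert result.weight_total == pytest.approx(float(np.sum(x)))

    def test_feasibility_of_optimum(self, small_foods, fixture_reference):
        for objective in ("cost", "energy", "weight"):
            result = solve_lp(build_lp(small_foods, fixture_reference, objective))
            assert result.status == "optimal"
            for name in CONSTRAINED_NUTRIENTS:
                target = result.targets[name]
                assert result.slack[name] >= -1e-7 * max(target, 1.0)

    def test_infeasible_caps_name_nutrient(self):
        result = solve_lp(single_food_instance(cap=100.0))  # can reach only 100 mg
        assert result.status == "infeasible"
        assert "calcium" in result.message

    def test_planted_instance_recovered(self):
        instance = planted_optimum_instance(3, ["calcium", "vitamin_d"], seed=11)
        result = solve_lp(build_lp(instance.foods, instance.target, "cost"))
        assert result.status == "optimal"
        for code, grams in instance.solution.items():
            assert result.grams_by_category[code] == pytest.approx(
                grams, rel=1e-6, abs=1e-6
            )
        assert result.objective_value == pytest.approx(
            instance.objective_value, rel=1e-8
        )

    def test_homogeneity_in_targets(self, small_foods, fixture_reference):
        # no caps: scaling every target by k scales solution and objective by k
        base = solve_lp(build_lp(small_foods, fixture_reference, "cost"))
        for k in (1.8, 3.0):
            scaled_ref = DairyReference(
                per_serving=fixture_reference.per_serving.scaled(k),
                cost_per_serving=fixture_reference.cost_per_serving * k,
                weight_per_serving=fixture_reference.weight_per_serving * k,
                composite_weights=fixture_reference.composite_weights,
            )
            scaled = solve_lp(build_lp(small_foods, scaled_ref, "cost"))
            assert scaled.objective_value == pytest.approx(
                k * base.objective_value, rel=1e-8
            )

    def test_cap_monotonicity(self, small_foods, fixture_reference):
        uncapped = solve_lp(build_lp(small_foods, fixture_reference, "cost"))
        caps = {f.code: 200.0 for f in small_foods}
        capped = solve_lp(build_lp(small_foods, fixture_reference, "cost", caps=caps))
        if capped.status == "optimal":
            assert capped.objective_value >= uncapped.objective_value - 1e-9

    def test_cross_objective_consistency(self, small_foods, fixture_reference):
        by_objective = {
            o: solve_lp(build_lp(small_foods, fixture_reference, o))
            for o in ("cost", "energy", "weight")
        }
        tol = 1 + 1e-9
        assert by_objective["cost"].cost_total <= tol * by_objective["energy"].cost_total
        assert by_objective["cost"].cost_total <= tol * by_objective["weight"].cost_total
        assert (
            by_objective["energy"].energy_total
            <= tol * by_objective["cost"].energy_total
        )
        assert (
            by_objective["weight"].weight_total
            <= tol * by_objective["cost"].weight_total
        )


class TestBindingNutrients:
    def test_single_food_single_nutrient_binds(self):
        result = solve_lp(single_food_instance())
        assert binding_nutrients(result) == ["calcium"]

    def test_planted_binding_set(self):
        instance = planted_optimum_instance(4, ["calcium", "vitamin_d"], seed=2)
        result = solve_lp(build_lp(instance.foods, instance.target, "cost"))
        assert set(binding_nutrients(result)) == {"calcium", "vitamin_d"}

    def test_all_slack_positive_gives_empty_list(self):
        result = OptimisationResult(
            status="optimal",
            objective="cost",
            codes=(1,),
            grams=np.array([10.0]),
            objective_value=1.0,
            cost_total=1.0,
            energy_total=1.0,
            weight_total=10.0,
            targets={"calcium": 100.0, "protein": 5.0},
            slack={"calcium": 50.0, "protein": 2.0},
        )
        assert binding_nutrients(result) == []

    def test_requires_optimal_status(self):
        result = solve_lp(single_food_instance(cap=10.0))
        assert result.status == "infeasible"
        with pytest.raises(StateError):
            binding_nutrients(result)

    def test_at_least_one_constraint_binds(self, small_foods, fixture_reference):
        # strictly positive costs: some constraint must be tight at the optimum
        result = solve_lp(build_lp(small_foods, fixture_reference, "cost"))
        assert binding_nutrients(result)


class TestBruteForceOracle:
    def test_closed_form_single_food(self):
        oracle = brute_force_oracle(single_food_instance())
        assert oracle.status == "optimal"
        assert oracle.x[0] == pytest.approx(300.0)

    def test_infeasible_matches_solver(self):
        spec = single_food_instance(cap=100.0)
        assert brute_force_oracle(spec).status == "infeasible"
        assert solve_lp(spec).status == "infeasible"

    def test_size_limit(self, small_foods, fixture_reference):
        spec = build_lp(small_foods, fixture_reference, "cost")
        with pytest.raises(SizeError):
            brute_force_oracle(spec)

    def test_three_food_fixed_seed_matches_solver(self):
        rng = np.random.default_rng(99)
        spec = random_small_spec(rng, max_foods=3, max_nutrients=3)
        oracle = brute_force_oracle(spec)
        solved = solve_lp(spec)
        assert oracle.status == solved.status
        if oracle.status == "optimal":
            assert solved.objective_value == pytest.approx(
                oracle.objective_value, rel=1e-6, abs=1e-9
            )

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(314)
        statuses = {"optimal": 0, "infeasible": 0}
        for _ in range(50):
            spec = random_small_spec(rng)
            oracle = brute_force_oracle(spec)
            solved = solve_lp(spec)
            assert oracle.status == solved.status
            statuses[oracle.status] += 1
            if oracle.status == "optimal":
                assert solved.objective_value == pytest.approx(
                    oracle.objective_value, rel=1e-6, abs=1e-9
                )
        assert statuses["optimal"] > 0  # the sweep exercises both outcomes


class TestLpSpecValidation:
    def test_negative_entries_rejected(self):
        with pytest.raises(ValidationError):
            LpSpec(
                codes=(1,),
                objective="cost",
                c=np.array([1.0]),
                A=np.array([[-1.0]]),
                b=np.array([1.0]),
                upper=np.array([np.inf]),
                nutrient_names=("calcium",),
            )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            LpSpec(
                codes=(1, 2),
                objective="cost",
                c=np.array([1.0]),
                A=np.array([[1.0, 1.0]]),
                b=np.array([1.0]),
                upper=np.array([np.inf, np.inf]),
                nutrient_names=("calcium",),
            )
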
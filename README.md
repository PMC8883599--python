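# dairyswap

Linear-programming search for combinations of non-dairy food categories that
replace the protein and ten shortfall nutrients (Ca, choline, fibre, Fe, Mg,
K, vitamins A, C, D and E) delivered by a reference cup-equivalent serving of
dairy, while minimising cost (US$), energy (kJ) or food weight (g).

The pipeline mirrors a two-phase analysis design: phase 1 excludes only dairy
categories; phase 2 additionally excludes categories that are unreasonable
substitutes on a population basis (baby foods, infant formulas, nutritional
powders/beverages, coffee, tap/bottled water, diet drinks). Each phase runs
three objectives, with and without per-category caps at the survey-weighted
90th percentile of current intake — a 2 × 3 × 2 grid of twelve scenarios.

Real food-composition, price and intake tables are not bundled; a seeded
synthetic-data module generates archetype-based food databases (staples,
fortified cereals, fish, leafy greens, juices, nutrition bars, water-like
beverages, milk substitutes, …), zero-inflated log-normal single-day intakes,
and planted-optimum LP instances whose unique solution is known by
construction.

## Modules

| module | role |
|---|---|
| `dairyswap.data_model` | domain types (`NutrientVector`, `FoodCategory`, `DairyReference`, `IntakeSample`), delimited-text readers/writers, dairy composite construction |
| `dairyswap.cost_adjust` | CPI inflation adjustment, mixed-dish component-cost regression (NNLS), explicit price overrides (e.g. bottled water priced per litre) |
| `dairyswap.survey_stats` | survey-weighted quantiles (left-continuous ECDF inverse) and per-category p90 intake caps |
| `dairyswap.lp_core` | LP assembly and solution (scipy/HiGHS), binding-nutrient analysis, exact brute-force vertex-enumeration oracle for small instances |
| `dairyswap.scenarios` | phase exclusion sets, single-scenario runs, the 12-run grid |
| `dairyswap.reporting` | servings scaling (×1.8 / ×3.0), RACC servings, ratios vs the dairy reference, nutrients-to-limit summaries, Ca-matched profile comparisons |
| `dairyswap.synthetic_data` | seeded generators and the dairy-reference fixture |

The dairy reference shipped in `synthetic_data.dairy_fixture()` is a labelled
fixture: its composite (53 % fat-free milk, 45 % low-fat cheese, 2 % yogurt)
pins per-serving energy (435 kJ), cost (US$0.41) and sodium (133 mg) to
published per-serving figures; all other amounts are plausible stand-ins and
every target is configurable so real reference data can be substituted.

## CLI

```bash
# generate a synthetic food database and intake table
dairyswap synth foods --n 150 --seed 1 --out foods.csv
dairyswap synth intakes --foods foods.csv --n-persons 2000 --seed 1 --out intakes.csv

# run the full 12-scenario grid (fixture dairy reference by default)
dairyswap run --foods foods.csv --intakes intakes.csv --out results/

# or a single scenario
dairyswap run --foods foods.csv --intakes intakes.csv \
    --scenario phase2/cost/p90 --out results/

# construct a planted-optimum verification instance
dairyswap synth planted --n-foods 4 --binding calcium,vitamin_d --seed 1
```

`run` writes `grid_report.csv` (one wide row per scenario × servings
multiplier), `grid_report.json` (per-category grams, slacks, binding
nutrients, ratios) and `run_manifest.json`.

A custom dairy reference is given with `--config ref.yaml`, either as a
direct per-serving target or as milk/cheese/yogurt component profiles with
composite weights (see `dairyswap.data_model.load_dairy_reference`).

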
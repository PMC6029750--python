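# nutrisim

Country-level microsimulation of the disease burden attributable to
CO2-induced declines in the zinc and iron concentrations of crops,
2015–2050, with mitigation-strategy comparison and sensitivity analysis.

The pipeline:

1. **`synthetic_data`** — generates `CountryProfile`s (diet, nutrient
   composition, demographics, disease epidemiology, WtdEARs) from three
   archetypes whose margins to the deficiency cut-point span the realistic
   range of baseline deficiency prevalence (~4%–32% for zinc).  No external
   data downloads are needed.
2. **`exposure`** — a linear CO2 trajectory (400 → 550 ppm unmitigated by
   2050), linear crop nutrient concentration declines scaled by the
   fraction of the CO2 rise prevented, and per-capita zinc/iron supply
   from food-supply × composition tables.
3. **`deficiency`** — parametric intake distributions (normal CV 25% by
   default; lognormal CV 40% as the iron alternative) and EAR cut-point
   classification: a person is deficient when their intake quantile falls
   below the population-weighted estimated average requirement (WtdEAR).
4. **`microsim`** — paired exposed/counterfactual populations stepped
   annually with common random numbers (persistent intake quantiles,
   shared per-cause death streams, deterministic birth schedule), disease
   rates RR-partitioned between deficient and non-deficient strata, and
   DALY (YLL + YLD) accounting by cause.  With zero declines the arms are
   bit-identical and attributable burden is exactly zero.
5. **`scenarios`** — the six mitigation strategies (Paris-style climate
   mitigation preventing 47% of the CO2 rise; zinc/iron supplementation at
   80% coverage; malaria/pneumonia/diarrhea control portfolios; a combined
   public-health portfolio) and averted-fraction arithmetic.
6. **`sensitivity`** — one-way ±10% perturbations ranked in tornado order
   (common random numbers within each low/high pair) and probabilistic
   Monte Carlo over jointly sampled inputs with percentile credible
   intervals.
7. **`io_reporting`** — CSV schemas for country inputs, WHO-region
   aggregation, and the end-to-end `run_pipeline` with a deterministic
   run log.

## CLI

```bash
# write synthetic input CSVs for 6 countries
nutrisim synth --n-countries 6 --seed 0 --out data/

# attributable burden per country
nutrisim burden --profiles data/ --n 2000 --reps 3 --seed 0 --out burden.csv

# averted fractions per strategy
nutrisim mitigate --profiles data/ --n 2000 --reps 3 --out mitigation.csv

# one-way or probabilistic sensitivity
nutrisim sensitivity --profiles data/ --mode one-way --out sensitivity.csv

# full pipeline from a YAML config
nutrisim report --config config.yaml --out results/
```

Every command echoes its effective configuration; all outputs regenerate
byte-identically from config + seed.

## Input CSV schemas

`food_supply.csv` (country_id, category, supply_kcal_per_capita_day),
`nutrients.csv` (category, kcal_per_100g, zinc_mg_per_100g,
iron_mg_per_100g, zinc_decline_2050, iron_decline_2050, optional
country_id), `epi.csv` (country_id, disease, prevalence_2015,
prevalence_apc, mortality_2015, mortality_apc, disability_weight,
rr_zinc), `demography.csv` (country_id, who_region, population_2015,
age_band, sex, weight, background_mortality, life_expectancy_remaining,
crude_birth_rate, wtdear_zinc, wtdear_iron).
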
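"""CSV schemas, region aggregation, and the end-to-end pipeline.

Input directory layout (UTF-8 CSVs, header row):

* ``food_supply.csv`` — country_id, category, supply_kcal_per_capita_day
* ``nutrients.csv`` — category, kcal_per_100g, zinc_mg_per_100g,
  iron_mg_per_100g, zinc_decline_2050, iron_decline_2050, and an optional
  country_id column.  Without it the composition table is global
  (USDA-style) and broadcast to every country; with it, composition is
  country-specific (as written by :func:`write_profiles`, whose synthetic
  profiles calibrate concentrations per country).
* ``epi.csv`` — country_id, disease, prevalence_2015, prevalence_apc,
  mortality_2015, mortality_apc, disability_weight, rr_zinc
* ``demography.csv`` — country_id, who_region, population_2015, age_band,
  sex, weight, background_mortality, life_expectancy_remaining,
  crude_birth_rate, wtdear_zinc, wtdear_iron

Validation failures name the file and row.  All outputs regenerate
byte-identically from config + seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .exposure import CO2Scenario, FoodRecord
from .microsim import SimConfig, run_paired
from .scenarios import averted_fraction, builtin_strategies, get_strategy
from .sensitivity import credible_interval, default_parameter_paths, one_way
from .synthetic_data import (AGE_BANDS, CountryProfile, DISEASES, DiseaseEpi,
                             SEXES, WHO_REGIONS, make_world)

_UNDER5_DISEASES = ("malaria", "pneumonia", "diarrhea")


@dataclass(frozen=True)
class CountryResult:
    """National-scale burden for one country (DALYs at population scale)."""

    country_id: str
    who_region: str
    population: float
    attributable_dalys: float
    baseline_dalys: float

    @property
    def attributable_dalys_per_1000(self) -> float:
        return self.attributable_dalys / self.population * 1000.0

    @property
    def baseline_dalys_per_1000(self) -> float:
        return self.baseline_dalys / self.population * 1000.0


@dataclass(frozen=True)
class RegionAggregate:
    """Population-weighted aggregate of country results."""

    who_region: str
    cumulative_dalys: float
    dalys_per_1000: float
    population: float
    baseline_dalys_per_1000: float


def write_profiles(profiles: Sequence[CountryProfile], outdir) -> None:
    """Write the four-CSV schema for a list of profiles."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    supply_rows, nutrient_rows, epi_rows, demo_rows = [], [], [], []
    for p in profiles:
        for f in p.foods:
            supply_rows.append({
                "country_id": p.country_id, "category": f.category,
                "supply_kcal_per_capita_day": f.supply_kcal,
            })
            nutrient_rows.append({
                "country_id": p.country_id, "category": f.category,
                "kcal_per_100g": f.energy_density,
                "zinc_mg_per_100g": f.zinc_conc_2015,
                "iron_mg_per_100g": f.iron_conc_2015,
                "zinc_decline_2050": f.zinc_decline_2050,
                "iron_decline_2050": f.iron_decline_2050,
            })
        for d in DISEASES:
            epi = p.disease_epi[d]
            epi_rows.append({
                "country_id": p.country_id, "disease": d,
                "prevalence_2015": epi.prevalence_2015,
                "prevalence_apc": epi.prevalence_apc,
                "mortality_2015": epi.mortality_2015,
                "mortality_apc": epi.mortality_apc,
                "disability_weight": epi.disability_weight,
                "rr_zinc": epi.rr_given_zinc_deficient,
            })
        for band in AGE_BANDS:
            for sex in SEXES:
                demo_rows.append({
                    "country_id": p.country_id, "who_region": p.who_region,
                    "population_2015": p.population_2015,
                    "age_band": band, "sex": sex,
                    "weight": p.demographic_weights[(band, sex)],
                    "background_mortality": p.background_mortality[band],
                    "life_expectancy_remaining": p.life_expectancy_at_death[band],
                    "crude_birth_rate": p.crude_birth_rate,
                    "wtdear_zinc": p.wtdear_zinc,
                    "wtdear_iron": p.wtdear_iron,
                })

    for name, rows in (("food_supply.csv", supply_rows),
                       ("nutrients.csv", nutrient_rows),
                       ("epi.csv", epi_rows),
                       ("demography.csv", demo_rows)):
        pd.DataFrame(rows).to_csv(outdir / name, index=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{fname}: missing columns {missing}")


def _check_nonneg(df: pd.DataFrame, col: str, fname: str) -> None:
    bad = df.index[df[col] < 0]
    if len(bad):
        raise ValidationError(
            f"{fname}: negative value in column {col!r} at row {int(bad[0])}"
        )


def read_profiles(directory) -> List[CountryProfile]:
    """Read and validate the four-CSV schema into CountryProfiles."""
    directory = Path(directory)
    paths = {name: directory / f"{name}.csv"
             for name in ("food_supply", "nutrients", "epi", "demography")}
    for name, path in paths.items():
        if not path.exists():
            raise ValidationError(f"missing input file {path}")

    supply = pd.read_csv(paths["food_supply"], float_precision="round_trip")
    nutrients = pd.read_csv(paths["nutrients"], float_precision="round_trip")
    epi = pd.read_csv(paths["epi"], float_precision="round_trip")
    demo = pd.read_csv(paths["demography"], float_precision="round_trip")

    _require_columns(supply, ["country_id", "category",
                              "supply_kcal_per_capita_day"], "food_supply.csv")
    _require_columns(nutrients, ["category", "kcal_per_100g", "zinc_mg_per_100g",
                                 "iron_mg_per_100g", "zinc_decline_2050",
                                 "iron_decline_2050"], "nutrients.csv")
    _require_columns(epi, ["country_id", "disease", "prevalence_2015",
                           "prevalence_apc", "mortality_2015", "mortality_apc",
                           "disability_weight", "rr_zinc"], "epi.csv")
    _require_columns(demo, ["country_id", "who_region", "population_2015",
                            "age_band", "sex", "weight", "background_mortality",
                            "life_expectancy_remaining", "crude_birth_rate",
                            "wtdear_zinc", "wtdear_iron"], "demography.csv")

    _check_nonneg(supply, "supply_kcal_per_capita_day", "food_supply.csv")
    for col in ("zinc_mg_per_100g", "iron_mg_per_100g"):
        _check_nonneg(nutrients, col, "nutrients.csv")
    _check_nonneg(demo, "weight", "demography.csv")

    per_country_nutrients = "country_id" in nutrients.columns

    profiles = []
    for country_id, cdemo in demo.groupby("country_id", sort=True):
        region = cdemo["who_region"].iloc[0]
        if region not in WHO_REGIONS:
            raise ValidationError(
                f"demography.csv: unknown who_region {region!r} for "
                f"country {country_id}"
            )
        weights = {}
        for _, row in cdemo.iterrows():
            if row["age_band"] not in AGE_BANDS or row["sex"] not in SEXES:
                raise ValidationError(
                    f"demography.csv: unknown age_band/sex "
                    f"({row['age_band']!r}, {row['sex']!r}) for {country_id}"
                )
            weights[(row["age_band"], row["sex"])] = row["weight"]
        bg = {row["age_band"]: row["background_mortality"]
              for _, row in cdemo.iterrows()}
        le = {row["age_band"]: row["life_expectancy_remaining"]
              for _, row in cdemo.iterrows()}

        csupply = supply[supply["country_id"] == country_id]
        if csupply.empty:
            raise ValidationError(
                f"food_supply.csv: no rows for country {country_id}"
            )
        cnut = (nutrients[nutrients["country_id"] == country_id]
                if per_country_nutrients else nutrients)
        nut_by_cat = {row["category"]: row for _, row in cnut.iterrows()}
        foods = []
        for _, row in csupply.iterrows():
            cat = row["category"]
            if cat not in nut_by_cat:
                raise ValidationError(
                    f"nutrients.csv: missing category {cat!r} needed by "
                    f"country {country_id} in food_supply.csv"
                )
            nrow = nut_by_cat[cat]
            foods.append(FoodRecord(
                category=cat,
                supply_kcal=float(row["supply_kcal_per_capita_day"]),
                energy_density=float(nrow["kcal_per_100g"]),
                zinc_conc_2015=float(nrow["zinc_mg_per_100g"]),
                iron_conc_2015=float(nrow["iron_mg_per_100g"]),
                zinc_decline_2050=float(nrow["zinc_decline_2050"]),
                iron_decline_2050=float(nrow["iron_decline_2050"]),
            ))

        cepi = epi[epi["country_id"] == country_id]
        disease_epi: Dict[str, DiseaseEpi] = {}
        for _, row in cepi.iterrows():
            d = row["disease"]
            if d not in DISEASES:
                raise ValidationError(
                    f"epi.csv: unknown disease {d!r} for country {country_id}"
                )
            disease_epi[d] = DiseaseEpi(
                disease=d,
                prevalence_2015=float(row["prevalence_2015"]),
                prevalence_apc=float(row["prevalence_apc"]),
                mortality_2015=float(row["mortality_2015"]),
                mortality_apc=float(row["mortality_apc"]),
                disability_weight=float(row["disability_weight"]),
                rr_given_zinc_deficient=float(row["rr_zinc"]),
                applies_to_under5_only=d in _UNDER5_DISEASES,
            )
        missing = set(DISEASES) - set(disease_epi)
        if missing:
            raise ValidationError(
                f"epi.csv: country {country_id} missing diseases {sorted(missing)}"
            )

        profiles.append(CountryProfile(
            country_id=str(country_id),
            who_region=region,
            population_2015=float(cdemo["population_2015"].iloc[0]),
            demographic_weights=weights,
            crude_birth_rate=float(cdemo["crude_birth_rate"].iloc[0]),
            background_mortality=bg,
            life_expectancy_at_death=le,
            foods=tuple(foods),
            wtdear_zinc=float(cdemo["wtdear_zinc"].iloc[0]),
            wtdear_iron=float(cdemo["wtdear_iron"].iloc[0]),
            disease_epi=disease_epi,
        ))
    if not profiles:
        raise ValidationError(f"no countries found in {directory}")
    return profiles


def aggregate(results: Sequence[CountryResult]) -> List[RegionAggregate]:
    """Exact population-weighted sums per WHO region, plus a GLOBAL row."""
    if not results:
        raise ValidationError("aggregate: no country results supplied")
    for r in results:
        if r.who_region not in WHO_REGIONS:
            raise ValidationError(
                f"aggregate: country {r.country_id} has unknown region "
                f"{r.who_region!r}"
            )
    out = []
    groups = {region: [r for r in results if r.who_region == region]
              for region in WHO_REGIONS}
    groups["GLOBAL"] = list(results)
    for region, rs in groups.items():
        if not rs:
            continue
        dalys = sum(r.attributable_dalys for r in rs)
        base = sum(r.baseline_dalys for r in rs)
        pop = sum(r.population for r in rs)
        out.append(RegionAggregate(
            who_region=region,
            cumulative_dalys=dalys,
            dalys_per_1000=dalys / pop * 1000.0,
            population=pop,
            baseline_dalys_per_1000=base / pop * 1000.0,
        ))
    return out


DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "n_countries": 6,
    "n": 2000,               # individuals per simulated sample
    "reps": 3,               # paired replicates per country
    "scenario": "baseline",  # or "paris"
    "strategies": None,      # None = all builtin strategies
    "constant_prevalence": False,
    "iron_lognormal": False,
    "independent_intakes": False,
    "run_sensitivity": False,
    "sensitivity_reps": 2,
    "outdir": "results",
}


def run_pipeline(config: Optional[Dict] = None) -> Dict:
    """Run burden, mitigation and (optionally) sensitivity end to end.

    Deterministic for fixed config + seed; writes ``burden_by_country.csv``,
    ``burden_by_region.csv``, ``mitigation.csv``, optionally
    ``sensitivity.csv``, and ``run_log.json`` under ``config['outdir']``.
    Returns the results bundle in memory.
    """
    cfg = dict(DEFAULT_PIPELINE_CONFIG)
    cfg.update(config or {})
    unknown = set(cfg) - set(DEFAULT_PIPELINE_CONFIG)
    if unknown:
        raise ValidationError(f"run_pipeline: unknown config keys {sorted(unknown)}")

    seed, n, reps = cfg["seed"], cfg["n"], cfg["reps"]
    if reps < 1 or n < 1:
        raise ValidationError("run_pipeline: n and reps must be >= 1")
    scn = CO2Scenario(fraction_rise_prevented=0.47 if cfg["scenario"] == "paris"
                      else 0.0)
    sim_config = SimConfig(
        constant_prevalence=cfg["constant_prevalence"],
        iron_lognormal=cfg["iron_lognormal"],
        independent_intakes=cfg["independent_intakes"],
    )
    strategy_names = cfg["strategies"] or [s.name for s in builtin_strategies()
                                           if s.name != "none"]
    none_strategy = get_strategy("none")

    world = make_world(cfg["n_countries"], seed)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    # --- burden (no strategy), one paired run per rep per country ---------
    country_results = []
    base_attributable: Dict[str, List[float]] = {}
    for profile in world:
        runs = [run_paired(profile, scn, none_strategy, n=n, seed=seed + r,
                           config=sim_config) for r in range(reps)]
        att = float(np.mean([r.attributable_dalys_per_1000 for r in runs]))
        base = float(np.mean([r.counterfactual.cumulative_dalys_per_1000()
                              for r in runs]))
        base_attributable[profile.country_id] = [
            r.attributable_dalys_per_1000 for r in runs
        ]
        country_results.append(CountryResult(
            country_id=profile.country_id,
            who_region=profile.who_region,
            population=profile.population_2015,
            attributable_dalys=att * profile.population_2015 / 1000.0,
            baseline_dalys=base * profile.population_2015 / 1000.0,
        ))

    burden_df = pd.DataFrame([{
        "country_id": r.country_id,
        "who_region": r.who_region,
        "population": r.population,
        "attributable_dalys": r.attributable_dalys,
        "attributable_dalys_per_1000": r.attributable_dalys_per_1000,
        "baseline_dalys": r.baseline_dalys,
        "baseline_dalys_per_1000": r.baseline_dalys_per_1000,
    } for r in country_results])
    burden_df.to_csv(outdir / "burden_by_country.csv", index=False)

    regions = aggregate(country_results)
    region_df = pd.DataFrame([dataclasses.asdict(r) for r in regions])
    region_df.to_csv(outdir / "burden_by_region.csv", index=False)

    # --- mitigation comparison -------------------------------------------
    mitigation_rows = []
    for name in strategy_names:
        strategy = get_strategy(name)
        for profile in world:
            fracs = []
            for r in range(reps):
                b0 = base_attributable[profile.country_id][r]
                res = run_paired(profile, scn, strategy, n=n, seed=seed + r,
                                 config=sim_config)
                if b0 > 0:
                    fracs.append(averted_fraction(
                        b0, res.attributable_dalys_per_1000))
            if not fracs:
                continue
            if len(fracs) >= 2:
                lo, hi = credible_interval(fracs, 0.95)
            else:
                lo = hi = fracs[0]
            mitigation_rows.append({
                "strategy": name, "country_id": profile.country_id,
                "who_region": profile.who_region,
                "averted_fraction": float(np.mean(fracs)),
                "ci_low": lo, "ci_high": hi, "reps": len(fracs),
            })
    mitigation_df = pd.DataFrame(mitigation_rows)
    mitigation_df.to_csv(outdir / "mitigation.csv", index=False)

    # --- one-way sensitivity on the first country (optional) -------------
    sensitivity_df = None
    if cfg["run_sensitivity"]:
        records = one_way(world[0], scn, none_strategy,
                          default_parameter_paths(world[0]),
                          n=min(n, 2000), reps=cfg["sensitivity_reps"],
                          seed=seed, config=sim_config)
        sensitivity_df = pd.DataFrame(records)
        sensitivity_df.to_csv(outdir / "sensitivity.csv", index=False)

    log = {"config": {k: cfg[k] for k in sorted(cfg)},
           "sim_config": dataclasses.asdict(sim_config),
           "scenario": {"ppm_2015": scn.ppm_2015,
                        "ppm_2050_unmitigated": scn.ppm_2050_unmitigated,
                        "fraction_rise_prevented": scn.fraction_rise_prevented},
           "strategies": strategy_names,
           "n_countries": len(world)}
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))

    return {"burden_by_country": burden_df, "burden_by_region": region_df,
            "mitigation": mitigation_df, "sensitivity": sensitivity_df,
            "run_log": log}
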
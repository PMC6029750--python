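"""Synthetic country profiles with the statistical structure the model assumes.

Profiles are generated from three archetypes (``high_burden``, ``middle``,
``low_burden``) that differ in how much of dietary energy comes from C3
staples, how far the mean intake sits above the deficiency cut-point (in
intake-SD units), and how intense background disease rates are.  The
archetype margins are calibrated so baseline zinc deficiency prevalences
bracket the realistic regional range (roughly 4%-32%).

All demography, background mortality, life expectancy, secular-trend and
population-size values here are synthetic defaults, not sourced data; the
Nigeria fixture embeds the published example input values and documents
which fields those are.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np

from .deficiency import FAMILIES, build_intake_distribution, deficiency_prevalence
from .errors import ValidationError
from .exposure import CO2Scenario, FoodRecord, per_capita_supply

WHO_REGIONS = ("AFR", "AMR", "SEAR", "EUR", "EMR", "WPR")
AGE_BANDS = ("0-4", "5-14", "15-49", "50+")
SEXES = ("female", "male")
DISEASES = ("malaria", "pneumonia", "diarrhea", "ida")

#: age band -> (lowest age, highest age) for within-band draws
AGE_BAND_RANGES: Dict[str, Tuple[int, int]] = {
    "0-4": (0, 4),
    "5-14": (5, 14),
    "15-49": (15, 49),
    "50+": (50, 79),
}


@dataclass(frozen=True)
class DiseaseEpi:
    """GBD-style epidemiology for one modeled disease."""

    disease: str
    prevalence_2015: float
    prevalence_apc: float
    mortality_2015: float
    mortality_apc: float
    disability_weight: float
    rr_given_zinc_deficient: float = 1.0
    applies_to_under5_only: bool = False

    def __post_init__(self) -> None:
        if self.disease not in DISEASES:
            raise ValidationError(
                f"DiseaseEpi.disease must be one of {DISEASES}, got {self.disease!r}"
            )
        if not 0.0 <= self.prevalence_2015 <= 1.0:
            raise ValidationError(
                f"DiseaseEpi.prevalence_2015 must be in [0, 1] for {self.disease}"
            )
        if not 0.0 <= self.disability_weight <= 1.0:
            raise ValidationError(
                f"DiseaseEpi.disability_weight must be in [0, 1] for {self.disease}"
            )
        if self.mortality_2015 < 0:
            raise ValidationError(
                f"DiseaseEpi.mortality_2015 must be >= 0 for {self.disease}"
            )
        if self.rr_given_zinc_deficient < 1.0:
            raise ValidationError(
                f"DiseaseEpi.rr_given_zinc_deficient must be >= 1 for {self.disease}"
            )
        for fld in ("prevalence_apc", "mortality_apc"):
            if getattr(self, fld) <= -1.0:
                raise ValidationError(
                    f"DiseaseEpi.{fld} must be > -1 for {self.disease}"
                )


@dataclass(frozen=True)
class CountryProfile:
    """Everything needed to simulate one country."""

    country_id: str
    who_region: str
    population_2015: float
    demographic_weights: Mapping[Tuple[str, str], float]
    crude_birth_rate: float
    background_mortality: Mapping[str, float]
    life_expectancy_at_death: Mapping[str, float]
    foods: Tuple[FoodRecord, ...]
    wtdear_zinc: float
    wtdear_iron: float
    disease_epi: Mapping[str, DiseaseEpi]
    intake_cv_zinc: float = 0.25
    intake_cv_iron: float = 0.25
    iron_family: str = "normal"

    def __post_init__(self) -> None:
        if self.who_region not in WHO_REGIONS:
            raise ValidationError(
                f"CountryProfile.who_region must be one of {WHO_REGIONS}, "
                f"got {self.who_region!r} (country {self.country_id})"
            )
        if self.population_2015 <= 0:
            raise ValidationError("CountryProfile.population_2015 must be > 0")
        if self.crude_birth_rate < 0:
            raise ValidationError("CountryProfile.crude_birth_rate must be >= 0")
        total = sum(self.demographic_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"CountryProfile.demographic_weights must sum to 1 +/- 1e-9, got {total}"
            )
        for cell, w in self.demographic_weights.items():
            band, sex = cell
            if band not in AGE_BANDS or sex not in SEXES:
                raise ValidationError(
                    f"CountryProfile.demographic_weights has unknown cell {cell!r}"
                )
            if w < 0:
                raise ValidationError(
                    f"CountryProfile.demographic_weights[{cell!r}] must be >= 0"
                )
        for mapping, name in (
            (self.background_mortality, "background_mortality"),
            (self.life_expectancy_at_death, "life_expectancy_at_death"),
        ):
            missing = set(AGE_BANDS) - set(mapping)
            if missing:
                raise ValidationError(
                    f"CountryProfile.{name} missing age bands {sorted(missing)}"
                )
            if any(v < 0 for v in mapping.values()):
                raise ValidationError(f"CountryProfile.{name} must be >= 0")
        if not self.foods:
            raise ValidationError("CountryProfile.foods must be non-empty")
        for fld in ("wtdear_zinc", "wtdear_iron"):
            if getattr(self, fld) <= 0:
                raise ValidationError(f"CountryProfile.{fld} must be > 0")
        for fld in ("intake_cv_zinc", "intake_cv_iron"):
            if not 0.0 < getattr(self, fld) < 1.0:
                raise ValidationError(f"CountryProfile.{fld} must be in (0, 1)")
        if self.iron_family not in FAMILIES:
            raise ValidationError(
                f"CountryProfile.iron_family must be one of {FAMILIES}"
            )
        if set(self.disease_epi) != set(DISEASES):
            raise ValidationError(
                "CountryProfile.disease_epi must contain exactly one entry per "
                f"disease in {DISEASES}, got {sorted(self.disease_epi)}"
            )
        for name, epi in self.disease_epi.items():
            if epi.disease != name:
                raise ValidationError(
                    f"CountryProfile.disease_epi key {name!r} does not match "
                    f"entry disease {epi.disease!r}"
                )

    # -- convenience accessors used throughout the pipeline ----------------

    def wtdear(self, nutrient: str) -> float:
        return self.wtdear_zinc if nutrient == "zinc" else self.wtdear_iron

    def intake_cv(self, nutrient: str) -> float:
        return self.intake_cv_zinc if nutrient == "zinc" else self.intake_cv_iron

    def intake_family(self, nutrient: str) -> str:
        return "normal" if nutrient == "zinc" else self.iron_family

    @property
    def under5_fraction(self) -> float:
        return sum(
            w for (band, _sex), w in self.demographic_weights.items() if band == "0-4"
        )

    def intake_distribution(self, nutrient: str, year: int, scn: CO2Scenario):
        """Scenario-specific intake distribution for ``year``.

        The mean is the per-capita supply; the CV is held fixed.
        """
        mean = per_capita_supply(self, nutrient, year, scn)
        return build_intake_distribution(
            mean, self.intake_cv(nutrient), self.intake_family(nutrient)
        )

    def analytic_deficiency_prevalence(self, nutrient: str) -> float:
        """Closed-form 2015 deficiency prevalence (scenario-independent)."""
        dist = self.intake_distribution(nutrient, 2015, CO2Scenario())
        return deficiency_prevalence(dist, self.wtdear(nutrient))


@dataclass(frozen=True)
class ArchetypeSpec:
    """Knobs describing one synthetic country archetype."""

    name: str
    c3_energy_share: float
    margin_to_cutpoint: float
    disease_intensity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.c3_energy_share <= 1.0:
            raise ValidationError(
                f"ArchetypeSpec.c3_energy_share must be in [0, 1], got {self.c3_energy_share}"
            )
        if self.disease_intensity <= 0:
            raise ValidationError(
                f"ArchetypeSpec.disease_intensity must be > 0, got {self.disease_intensity}"
            )


ARCHETYPES: Dict[str, ArchetypeSpec] = {
    "high_burden": ArchetypeSpec("high_burden", c3_energy_share=0.75,
                                 margin_to_cutpoint=0.47, disease_intensity=1.5),
    "middle": ArchetypeSpec("middle", c3_energy_share=0.55,
                            margin_to_cutpoint=1.00, disease_intensity=1.0),
    "low_burden": ArchetypeSpec("low_burden", c3_energy_share=0.35,
                                margin_to_cutpoint=1.79, disease_intensity=0.25),
}

# category, is_c3, within-group kcal share, kcal/100 g, mg Zn/100 g, mg Fe/100 g
_BASE_FOODS = (
    ("c3_staple_grain", True, 0.70, 360.0, 1.20, 1.60),
    ("c3_legume", True, 0.15, 340.0, 2.50, 5.00),
    ("roots", True, 0.10, 90.0, 0.30, 0.60),
    ("vegetables", True, 0.05, 35.0, 0.30, 0.80),
    ("maize", False, 0.30, 365.0, 1.80, 2.70),
    ("bovine_meat", False, 0.15, 250.0, 4.80, 2.60),
    ("other_meat", False, 0.10, 200.0, 2.00, 1.00),
    ("dairy", False, 0.15, 65.0, 0.40, 0.05),
    ("fish", False, 0.10, 120.0, 0.60, 0.90),
    ("other", False, 0.20, 150.0, 0.50, 0.70),
)

# Synthetic demographic defaults per archetype (not sourced values):
# weights per age band, crude birth rate, background mortality and remaining
# life expectancy per band.
_DEMOGRAPHY = {
    "high_burden": {
        "band_weights": {"0-4": 0.165, "5-14": 0.26, "15-49": 0.465, "50+": 0.11},
        "crude_birth_rate": 0.038,
        "background_mortality": {"0-4": 0.010, "5-14": 0.002, "15-49": 0.004, "50+": 0.035},
        "life_expectancy": {"0-4": 63.0, "5-14": 58.0, "15-49": 35.0, "50+": 18.0},
        "population": 9.0e7,
    },
    "middle": {
        "band_weights": {"0-4": 0.09, "5-14": 0.17, "15-49": 0.52, "50+": 0.22},
        "crude_birth_rate": 0.018,
        "background_mortality": {"0-4": 0.004, "5-14": 0.001, "15-49": 0.002, "50+": 0.030},
        "life_expectancy": {"0-4": 72.0, "5-14": 66.0, "15-49": 42.0, "50+": 24.0},
        "population": 5.0e7,
    },
    "low_burden": {
        "band_weights": {"0-4": 0.05, "5-14": 0.10, "15-49": 0.47, "50+": 0.38},
        "crude_birth_rate": 0.010,
        "background_mortality": {"0-4": 0.003, "5-14": 0.0005, "15-49": 0.0015, "50+": 0.028},
        "life_expectancy": {"0-4": 78.0, "5-14": 72.0, "15-49": 46.0, "50+": 28.0},
        "population": 2.0e7,
    },
}

# Baseline epidemiology before disease_intensity scaling.  Prevalences,
# disability weights and RRs for the three childhood diseases follow the
# published Nigeria example inputs; mortality levels and all APCs are
# synthetic defaults.
_EPI_DEFAULTS = {
    "malaria": dict(prevalence_2015=0.038, prevalence_apc=-0.020,
                    mortality_2015=1.0e-3, mortality_apc=-0.020,
                    disability_weight=0.191, rr_given_zinc_deficient=1.56,
                    applies_to_under5_only=True),
    "pneumonia": dict(prevalence_2015=7.42e-4, prevalence_apc=-0.010,
                      mortality_2015=1.2e-3, mortality_apc=-0.020,
                      disability_weight=0.279, rr_given_zinc_deficient=1.52,
                      applies_to_under5_only=True),
    "diarrhea": dict(prevalence_2015=0.055, prevalence_apc=-0.015,
                     mortality_2015=8.0e-4, mortality_apc=-0.025,
                     disability_weight=0.105, rr_given_zinc_deficient=1.28,
                     applies_to_under5_only=True),
    "ida": dict(prevalence_2015=0.25, prevalence_apc=-0.005,
                mortality_2015=1.0e-4, mortality_apc=-0.010,
                disability_weight=0.0312, rr_given_zinc_deficient=1.0,
                applies_to_under5_only=False),
}

_DEFAULT_WTDEAR_ZINC = 10.33
_DEFAULT_WTDEAR_IRON = 18.91


def _build_foods(rng: np.random.Generator, c3_energy_share: float,
                 total_kcal: float) -> List[FoodRecord]:
    foods = []
    for category, is_c3, share, energy_density, zn, fe in _BASE_FOODS:
        group_budget = c3_energy_share if is_c3 else (1.0 - c3_energy_share)
        kcal = total_kcal * group_budget * share
        if is_c3:
            zn_decline = rng.uniform(0.05, 0.10)
            fe_decline = rng.uniform(0.05, 0.10)
        else:
            zn_decline = fe_decline = 0.0
        foods.append(FoodRecord(
            category=category, supply_kcal=kcal, energy_density=energy_density,
            zinc_conc_2015=zn, iron_conc_2015=fe,
            zinc_decline_2050=zn_decline, iron_decline_2050=fe_decline,
        ))
    return foods


def _scale_concentrations(foods: List[FoodRecord], nutrient: str,
                          target_supply: float) -> List[FoodRecord]:
    """Uniformly rescale one nutrient's concentrations to hit a 2015 supply."""
    base = sum(f.supply_kcal / f.energy_density * f.conc_2015(nutrient) for f in foods)
    factor = target_supply / base
    key = f"{nutrient}_conc_2015"
    return [
        dataclasses.replace(f, **{key: getattr(f, key) * factor}) for f in foods
    ]


def make_country(spec: ArchetypeSpec, seed: int, *, country_id: str | None = None,
                 who_region: str = "AFR") -> CountryProfile:
    """Generate one synthetic country from an archetype.

    Deterministic for fixed ``(spec, seed)``.  The 2015 mean intake of each
    nutrient is placed ``margin_to_cutpoint`` intake-SDs above the WtdEAR,
    so the analytic 2015 deficiency prevalence is Phi(-margin) for the
    normal family.  C3 staple categories contribute ``c3_energy_share`` of
    total energy and carry nonzero concentration declines in [0.05, 0.10].
    """
    if not isinstance(spec, ArchetypeSpec):
        raise ValidationError("make_country: spec must be an ArchetypeSpec")
    if seed < 0:
        raise ValidationError(f"make_country: seed must be >= 0, got {seed}")
    rng = np.random.default_rng(seed)

    total_kcal = 2400.0 * (0.95 + 0.10 * rng.random())
    foods = _build_foods(rng, spec.c3_energy_share, total_kcal)

    cv_zn, cv_fe = 0.25, 0.25
    m = spec.margin_to_cutpoint
    # mean = wtdear / (1 - margin * cv)  <=>  (wtdear - mean) / sd = -margin
    if m * cv_zn >= 1.0 or m * cv_fe >= 1.0:
        raise ValidationError(
            "make_country: margin_to_cutpoint too large for CV "
            f"(margin * cv must be < 1, got margin={m})"
        )
    target_zn = _DEFAULT_WTDEAR_ZINC / (1.0 - m * cv_zn)
    target_fe = _DEFAULT_WTDEAR_IRON / (1.0 - m * cv_fe)
    foods = _scale_concentrations(foods, "zinc", target_zn)
    foods = _scale_concentrations(foods, "iron", target_fe)

    demo = _DEMOGRAPHY[spec.name] if spec.name in _DEMOGRAPHY else _DEMOGRAPHY["middle"]
    weights = {
        (band, sex): w / 2.0
        for band, w in demo["band_weights"].items()
        for sex in SEXES
    }

    epi = {}
    for disease, params in _EPI_DEFAULTS.items():
        params = dict(params)
        params["prevalence_2015"] = min(
            params["prevalence_2015"] * spec.disease_intensity, 1.0
        )
        params["mortality_2015"] *= spec.disease_intensity
        epi[disease] = DiseaseEpi(disease=disease, **params)

    population = demo["population"] * (0.8 + 0.4 * rng.random())

    return CountryProfile(
        country_id=country_id or f"SYN-{spec.name}-{seed}",
        who_region=who_region,
        population_2015=population,
        demographic_weights=weights,
        crude_birth_rate=demo["crude_birth_rate"],
        background_mortality=dict(demo["background_mortality"]),
        life_expectancy_at_death=dict(demo["life_expectancy"]),
        foods=tuple(foods),
        wtdear_zinc=_DEFAULT_WTDEAR_ZINC,
        wtdear_iron=_DEFAULT_WTDEAR_IRON,
        disease_epi=epi,
        intake_cv_zinc=cv_zn,
        intake_cv_iron=cv_fe,
    )


def make_world(n_countries: int, seed: int) -> List[CountryProfile]:
    """Generate ``n_countries`` profiles cycling archetypes and WHO regions."""
    if n_countries < 1:
        raise ValidationError(
            f"make_world: n_countries must be >= 1, got {n_countries}"
        )
    names = list(ARCHETYPES)
    profiles = []
    for i in range(n_countries):
        spec = ARCHETYPES[names[i % len(names)]]
        profiles.append(make_country(
            spec,
            seed * 100003 + i,
            country_id=f"C{i:03d}",
            who_region=WHO_REGIONS[i % len(WHO_REGIONS)],
        ))
    return profiles


def nigeria_fixture() -> CountryProfile:
    """A profile embedding the published Nigeria example input values.

    Exact published cells: both WtdEARs, the three childhood-disease
    prevalences, all four disability weights, and the three zinc RRs (IDA
    carries RR 1.0: it is the iron pathway).  Every other field —
    demography, background mortality, life expectancy, mortality levels,
    all APCs, the food list and the population size — is a documented
    synthetic default and must not be read as published data.
    """
    base = make_country(
        ARCHETYPES["high_burden"], seed=2015, country_id="NGA", who_region="AFR"
    )
    table = {
        "malaria": dict(prevalence_2015=0.038, disability_weight=0.191,
                        rr_given_zinc_deficient=1.56),
        "pneumonia": dict(prevalence_2015=7.42e-4, disability_weight=0.279,
                          rr_given_zinc_deficient=1.52),
        "diarrhea": dict(prevalence_2015=0.055, disability_weight=0.105,
                         rr_given_zinc_deficient=1.28),
        "ida": dict(disability_weight=0.0312, rr_given_zinc_deficient=1.0),
    }
    epi = {
        d: dataclasses.replace(base.disease_epi[d], **table[d]) for d in DISEASES
    }
    return dataclasses.replace(
        base, disease_epi=epi, wtdear_zinc=10.33, wtdear_iron=18.91
    )
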
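"""Exposure model: CO2 trajectory, crop nutrient concentrations, dietary supply.

Atmospheric CO2 rises linearly from its 2015 level to the (possibly
mitigated) 2050 endpoint.  Each food category loses a fixed fraction of its
2015 zinc/iron concentration by 2050 under the unmitigated rise; mitigation
scales that loss proportionally to the fraction of the CO2 rise prevented
(linear dose-response by default, overridable via
:attr:`CO2Scenario.decline_scaling`).  Per-capita nutrient supply is the sum
over food categories of mass consumed times concentration, with caloric
consumption patterns held fixed over time and across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from .errors import RangeError, ValidationError

NUTRIENTS = ("zinc", "iron")

START_YEAR = 2015
END_YEAR = 2050
SPAN_YEARS = END_YEAR - START_YEAR  # 35


@dataclass(frozen=True)
class FoodRecord:
    """One aggregate food category in a country's diet.

    Parameters
    ----------
    category : str
        Category label, e.g. ``"c3_staple_grain"``.
    supply_kcal : float
        Consumption, kcal/capita/day.  Held constant over the horizon.
    energy_density : float
        kcal per 100 g of the food.
    zinc_conc_2015, iron_conc_2015 : float
        Baseline nutrient concentration, mg per 100 g.
    zinc_decline_2050, iron_decline_2050 : float
        Fraction of the 2015 concentration lost by 2050 under the full
        (unmitigated) CO2 rise; in [0, 1).  Zero for foods unaffected by
        CO2 (animal products, C4 crops).
    """

    category: str
    supply_kcal: float
    energy_density: float
    zinc_conc_2015: float
    iron_conc_2015: float
    zinc_decline_2050: float = 0.0
    iron_decline_2050: float = 0.0

    def __post_init__(self) -> None:
        if not self.category:
            raise ValidationError("FoodRecord.category must be non-empty")
        if self.energy_density <= 0:
            raise ValidationError(
                f"FoodRecord.energy_density must be > 0 for {self.category!r}, "
                f"got {self.energy_density}"
            )
        if self.supply_kcal < 0:
            raise ValidationError(
                f"FoodRecord.supply_kcal must be >= 0 for {self.category!r}, "
                f"got {self.supply_kcal}"
            )
        for fld in ("zinc_conc_2015", "iron_conc_2015"):
            if getattr(self, fld) < 0:
                raise ValidationError(
                    f"FoodRecord.{fld} must be >= 0 for {self.category!r}"
                )
        for fld in ("zinc_decline_2050", "iron_decline_2050"):
            val = getattr(self, fld)
            if not 0.0 <= val < 1.0:
                raise ValidationError(
                    f"FoodRecord.{fld} must be in [0, 1) for {self.category!r}, "
                    f"got {val}"
                )

    def decline_2050(self, nutrient: str) -> float:
        _check_nutrient(nutrient)
        return self.zinc_decline_2050 if nutrient == "zinc" else self.iron_decline_2050

    def conc_2015(self, nutrient: str) -> float:
        _check_nutrient(nutrient)
        return self.zinc_conc_2015 if nutrient == "zinc" else self.iron_conc_2015


@dataclass(frozen=True)
class CO2Scenario:
    """Atmospheric CO2 path from 2015 to 2050.

    ``fraction_rise_prevented = 0`` is business-as-usual (400 -> 550 ppm by
    default); ``0.47`` approximates a Paris-Agreement trajectory; ``1``
    freezes CO2 (and hence crop nutrient concentrations) at 2015 levels.

    ``decline_scaling`` optionally maps ``fraction_rise_prevented`` to the
    multiplier applied to each food's 2050 concentration decline.  The
    default is the linear dose-response ``1 - fraction_rise_prevented``.
    """

    ppm_2015: float = 400.0
    ppm_2050_unmitigated: float = 550.0
    fraction_rise_prevented: float = 0.0
    decline_scaling: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.ppm_2050_unmitigated < self.ppm_2015:
            raise ValidationError(
                "CO2Scenario.ppm_2050_unmitigated must be >= ppm_2015, got "
                f"{self.ppm_2050_unmitigated} < {self.ppm_2015}"
            )
        if not 0.0 <= self.fraction_rise_prevented <= 1.0:
            raise ValidationError(
                "CO2Scenario.fraction_rise_prevented must be in [0, 1], got "
                f"{self.fraction_rise_prevented}"
            )

    @property
    def decline_multiplier(self) -> float:
        """Multiplier on each food's full-rise 2050 decline."""
        if self.decline_scaling is not None:
            return float(self.decline_scaling(self.fraction_rise_prevented))
        return 1.0 - self.fraction_rise_prevented


def _check_nutrient(nutrient: str) -> None:
    if nutrient not in NUTRIENTS:
        raise ValidationError(
            f"unknown nutrient {nutrient!r}; expected one of {NUTRIENTS}"
        )


def _check_year(year: int) -> None:
    if not START_YEAR <= year <= END_YEAR:
        raise RangeError(
            f"year must be in [{START_YEAR}, {END_YEAR}], got {year}"
        )


def co2_at_year(scn: CO2Scenario, year: int) -> float:
    """CO2 concentration (ppm) in ``year`` under scenario ``scn``.

    Linear interpolation from the 2015 level to the mitigated 2050
    endpoint ``ppm_2015 + (1 - fraction_rise_prevented) * rise``.
    """
    _check_year(year)
    mitigated_rise = (1.0 - scn.fraction_rise_prevented) * (
        scn.ppm_2050_unmitigated - scn.ppm_2015
    )
    return scn.ppm_2015 + mitigated_rise * (year - START_YEAR) / SPAN_YEARS


def nutrient_concentration(
    food: FoodRecord, nutrient: str, year: int, scn: CO2Scenario
) -> float:
    """Concentration (mg/100 g) of ``nutrient`` in ``food`` at ``year``.

    The 2015 concentration declines linearly, reaching
    ``conc_2015 * (1 - decline_2050 * decline_multiplier)`` in 2050.
    Floored at zero (unreachable for declines < 1).
    """
    _check_nutrient(nutrient)
    _check_year(year)
    effective = food.decline_2050(nutrient) * scn.decline_multiplier
    frac_elapsed = (year - START_YEAR) / SPAN_YEARS
    conc = food.conc_2015(nutrient) * (1.0 - effective * frac_elapsed)
    return max(conc, 0.0)


def supply_from_foods(
    foods: Iterable[FoodRecord], nutrient: str, year: int, scn: CO2Scenario
) -> float:
    """Per-capita nutrient supply (mg/capita/day) from a list of foods.

    Each food contributes (kcal consumed / energy density) units of 100 g
    times its year- and scenario-specific concentration.
    """
    foods = list(foods)
    if not foods:
        raise ValidationError("food list is empty; cannot compute supply")
    return sum(
        (f.supply_kcal / f.energy_density)
        * nutrient_concentration(f, nutrient, year, scn)
        for f in foods
    )


def per_capita_supply(profile, nutrient: str, year: int, scn: CO2Scenario) -> float:
    """Per-capita supply (mg/capita/day) for a country profile.

    Total kcal per category is held fixed across years and scenarios; only
    concentrations change.
    """
    return supply_from_foods(profile.foods, nutrient, year, scn)
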
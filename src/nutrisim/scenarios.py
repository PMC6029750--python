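"""The six mitigation strategies and averted-burden arithmetic.

Strategies:

* ``paris`` — climate mitigation preventing 47% of the 2015-2050 CO2 rise,
  scaling every crop concentration decline proportionally.
* ``zinc_supplement`` — daily zinc for 80% of children under 5 (random
  selection, fixed over the simulation).
* ``iron_supplement`` — weekly iron for 80% of females over 5.
* ``malaria_control`` / ``pneumonia_control`` / ``diarrhea_control`` —
  intervention portfolios at 80% coverage (vaccine components at 90%,
  folded into the single effective efficacy) that scale the target
  disease's prevalence and mortality in *both* simulation arms.
* ``combined_public_health`` — all five of the above at once.

Supplementation is modeled as deficiency removal for covered individuals;
an intake-increment alternative (``supplement_mg_per_day``) is available.
The portfolio efficacies are placeholder defaults (the literature
portfolios are not parameterised here) and are plain fields, so callers
can override them.

``PUBLISHED_AVERTED_PCT`` records the published global averted-burden
percentages; it exists for comparison/reporting only and is never used by
the simulation itself.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .errors import ValidationError

STRATEGY_NAMES = (
    "none",
    "paris",
    "zinc_supplement",
    "iron_supplement",
    "malaria_control",
    "pneumonia_control",
    "diarrhea_control",
    "combined_public_health",
)

TARGETS = ("children_under5", "females_over5", "whole_population", "not_applicable")

PARIS_FRACTION_PREVENTED = 0.47
DEFAULT_COVERAGE = 0.80
#: placeholder portfolio efficacy (fractional reduction at full coverage)
DEFAULT_CONTROL_EFFICACY = 0.50

#: Published global averted-burden percentages (reference values for
#: comparison machinery only; model outputs are computed, never read from
#: this table).
PUBLISHED_AVERTED_PCT = {
    "paris": 48.2,
    "combined_public_health": 26.6,
    "zinc_supplement": 5.5,
    "iron_supplement": 15.7,
    "malaria_control": 3.2,
    "pneumonia_control": 1.6,
    "diarrhea_control": 0.5,
}


@dataclass(frozen=True)
class MitigationStrategy:
    """Declarative description of one intervention.

    A strategy either prevents part of the CO2 rise (``paris``), removes a
    nutrient deficiency for covered individuals in a target group
    (supplementation), scales one disease's rates (disease control), or
    composes other strategies (``components``).
    """

    name: str
    coverage: float = 0.0
    target: str = "not_applicable"
    supplement_nutrient: Optional[str] = None
    disease: Optional[str] = None
    efficacy_prevalence: float = 0.0
    efficacy_mortality: float = 0.0
    fraction_rise_prevented: float = 0.0
    supplement_mg_per_day: Optional[float] = None
    components: Tuple["MitigationStrategy", ...] = ()

    def __post_init__(self) -> None:
        for fld in ("coverage", "efficacy_prevalence", "efficacy_mortality",
                    "fraction_rise_prevented"):
            val = getattr(self, fld)
            if not 0.0 <= val <= 1.0:
                raise ValidationError(
                    f"MitigationStrategy.{fld} must be in [0, 1], got {val}"
                )
        if self.target not in TARGETS:
            raise ValidationError(
                f"MitigationStrategy.target must be one of {TARGETS}, "
                f"got {self.target!r}"
            )
        if self.supplement_nutrient not in (None, "zinc", "iron"):
            raise ValidationError(
                "MitigationStrategy.supplement_nutrient must be 'zinc', 'iron' "
                f"or None, got {self.supplement_nutrient!r}"
            )

    def leaves(self) -> List["MitigationStrategy"]:
        """Flatten portfolio strategies into their atomic components."""
        if self.components:
            out: List[MitigationStrategy] = []
            for c in self.components:
                out.extend(c.leaves())
            return out
        return [self]

    def supplementation_for(self, nutrient: str) -> Optional["MitigationStrategy"]:
        for leaf in self.leaves():
            if leaf.supplement_nutrient == nutrient and leaf.coverage > 0:
                return leaf
        return None

    def controls_for(self, disease: str) -> List["MitigationStrategy"]:
        return [leaf for leaf in self.leaves() if leaf.disease == disease]

    @property
    def total_fraction_rise_prevented(self) -> float:
        return max((leaf.fraction_rise_prevented for leaf in self.leaves()),
                   default=0.0)


def builtin_strategies() -> List[MitigationStrategy]:
    """The named strategies with their stated coverages.

    Coverages are 0.80 throughout (vaccine components inside the disease
    portfolios run at 0.90, absorbed into the single effective efficacy);
    the Paris strategy prevents 47% of the CO2 rise.  Portfolio efficacies
    are configurable placeholders.
    """
    zinc = MitigationStrategy(
        name="zinc_supplement", coverage=DEFAULT_COVERAGE,
        target="children_under5", supplement_nutrient="zinc",
    )
    iron = MitigationStrategy(
        name="iron_supplement", coverage=DEFAULT_COVERAGE,
        target="females_over5", supplement_nutrient="iron",
    )
    controls = [
        MitigationStrategy(
            name=f"{d}_control", coverage=DEFAULT_COVERAGE,
            target="children_under5", disease=d,
            efficacy_prevalence=DEFAULT_CONTROL_EFFICACY,
            efficacy_mortality=DEFAULT_CONTROL_EFFICACY,
        )
        for d in ("malaria", "pneumonia", "diarrhea")
    ]
    combined = MitigationStrategy(
        name="combined_public_health",
        components=(zinc, iron, *controls),
    )
    return [
        MitigationStrategy(name="none"),
        MitigationStrategy(
            name="paris", target="whole_population",
            fraction_rise_prevented=PARIS_FRACTION_PREVENTED,
        ),
        zinc, iron, *controls, combined,
    ]


def get_strategy(name: str) -> MitigationStrategy:
    for s in builtin_strategies():
        if s.name == name:
            return s
    raise ValidationError(
        f"unknown strategy {name!r}; expected one of {STRATEGY_NAMES}"
    )


def apply_supplementation(individual_covered, deficient_raw):
    """Effective deficiency status after supplementation.

    Covered individuals are never classified deficient for the
    supplemented nutrient; uncovered individuals are unchanged.
    Vectorised over boolean arrays.
    """
    return np.logical_and(deficient_raw, np.logical_not(individual_covered))


def apply_disease_control(rate: float, strategy: MitigationStrategy,
                          which: str, disease: str) -> float:
    """Scale a disease rate by every matching control in ``strategy``.

    Each control multiplies the rate by ``1 - coverage * efficacy``;
    applied identically in both simulation arms.
    """
    if which not in ("prevalence", "mortality"):
        raise ValidationError(
            f"apply_disease_control: which must be 'prevalence' or 'mortality', "
            f"got {which!r}"
        )
    out = rate
    for leaf in strategy.controls_for(disease):
        eff = (leaf.efficacy_prevalence if which == "prevalence"
               else leaf.efficacy_mortality)
        out *= 1.0 - leaf.coverage * eff
    return out


def averted_fraction(burden_no_strategy: float, burden_with_strategy: float) -> float:
    """Fraction of CO2-attributable burden averted by a strategy."""
    if burden_no_strategy <= 0:
        raise ValidationError(
            "averted_fraction undefined: burden_no_strategy must be > 0, "
            f"got {burden_no_strategy}"
        )
    return (burden_no_strategy - burden_with_strategy) / burden_no_strategy
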
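"""Intake distributions and EAR cut-point deficiency classification.

A population's yearly nutrient intake is summarised by a parametric
distribution (normal with CV 25% by default; lognormal with CV 40% as the
iron sensitivity alternative).  A person is deficient when their average
annual intake falls strictly below the population-weighted estimated
average requirement (WtdEAR); population prevalence is therefore the intake
CDF evaluated at the WtdEAR.

The CO2-induced supply decline is applied multiplicatively to the
distribution mean with CV held fixed, so the whole distribution shifts and
a person's *rank* (their persistent quantile ``u``) is preserved across
years and scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import RangeError, ValidationError

FAMILIES = ("normal", "lognormal")


@dataclass(frozen=True)
class IntakeDistribution:
    """Parametric yearly intake distribution.

    ``normal``: SD = cv * mean, quantiles clamped at 0 (the sub-zero mass is
    negligible at CV 25%; clamped individuals remain deficient for any
    positive cut-point).  ``lognormal``: parameters moment-matched so the
    arithmetic mean and CV equal the inputs, i.e. sigma^2 = ln(1 + cv^2),
    mu = ln(mean) - sigma^2 / 2.
    """

    family: str
    mean: float
    cv: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(
                f"unknown intake family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.mean <= 0:
            raise ValidationError(f"IntakeDistribution.mean must be > 0, got {self.mean}")
        if not 0.0 < self.cv < 1.0:
            raise ValidationError(f"IntakeDistribution.cv must be in (0, 1), got {self.cv}")

    @property
    def sd(self) -> float:
        return self.cv * self.mean

    def _frozen(self):
        if self.family == "normal":
            return stats.norm(loc=self.mean, scale=self.sd)
        sigma2 = math.log1p(self.cv**2)
        sigma = math.sqrt(sigma2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return stats.lognorm(s=sigma, scale=math.exp(mu))

    def quantile(self, u):
        """Inverse CDF at ``u`` in (0, 1); vectorised; never negative."""
        u_arr = np.asarray(u, dtype=float)
        if np.any((u_arr <= 0.0) | (u_arr >= 1.0)):
            raise RangeError("quantile argument u must lie strictly in (0, 1)")
        q = self._frozen().ppf(u_arr)
        q = np.maximum(q, 0.0)
        return float(q) if np.isscalar(u) or q.ndim == 0 else q

    def cdf(self, x):
        """CDF at intake ``x`` (mg/day); vectorised."""
        c = self._frozen().cdf(x)
        return float(c) if np.ndim(c) == 0 else c


@dataclass(frozen=True)
class WtdEARSpec:
    """Per-demographic-group requirements and population weights.

    Keys of both mappings are (age band, sex) cells and must coincide;
    weights sum to 1.
    """

    group_requirements: Mapping = field(default_factory=dict)
    group_weights: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        req_keys = set(self.group_requirements)
        w_keys = set(self.group_weights)
        if req_keys != w_keys:
            raise ValidationError(
                "WtdEARSpec cells mismatch between group_requirements and "
                f"group_weights: {sorted(map(str, req_keys ^ w_keys))}"
            )
        if not req_keys:
            raise ValidationError("WtdEARSpec must contain at least one cell")
        if any(r <= 0 for r in self.group_requirements.values()):
            raise ValidationError("WtdEARSpec.group_requirements must all be > 0")
        total = sum(self.group_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"WtdEARSpec.group_weights must sum to 1 +/- 1e-9, got {total}"
            )


def build_intake_distribution(mean: float, cv: float, family: str = "normal") -> IntakeDistribution:
    """Construct an :class:`IntakeDistribution`, validating all inputs."""
    return IntakeDistribution(family=family, mean=mean, cv=cv)


def compute_wtdear(spec: WtdEARSpec) -> float:
    """Population-weighted estimated average requirement (mg/day).

    Sum over demographic cells of requirement times population fraction.
    """
    return sum(
        spec.group_requirements[cell] * spec.group_weights[cell]
        for cell in spec.group_requirements
    )


def deficiency_prevalence(dist: IntakeDistribution, wtdear: float) -> float:
    """Analytic deficiency prevalence: the intake CDF at the cut-point."""
    if wtdear <= 0:
        raise ValidationError(f"wtdear must be > 0, got {wtdear}")
    return dist.cdf(wtdear)


def is_deficient(u, dist: IntakeDistribution, wtdear: float):
    """Deficiency status for persistent quantile(s) ``u``.

    True iff ``quantile(dist, u) < wtdear`` (strict: a tie at the cut-point
    counts as non-deficient).  Vectorised over ``u``.
    """
    if wtdear <= 0:
        raise ValidationError(f"wtdear must be > 0, got {wtdear}")
    q = dist.quantile(u)
    out = np.asarray(q) < wtdear
    return bool(out) if out.ndim == 0 else out
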
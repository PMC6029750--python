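"""One-way (+/-10%) and probabilistic sensitivity analysis.

One-way analysis perturbs one input at a time by fixed multipliers (0.9 and
1.1 by default), reruns the paired microsimulation with the *same* seeds for
the low and high runs (common random numbers isolate the parameter effect),
and ranks parameters by outcome spread (tornado order).

Probabilistic analysis jointly samples a multiplier for every listed input
from independent normal distributions (relative SD 10% by default, truncated
to each input's natural bounds), reruns the model once per draw, and
summarises the outcome draws with an empirical mean/SD and percentile
credible interval.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .exposure import CO2Scenario
from .microsim import DEFAULT_CONFIG, SimConfig, run_paired
from .scenarios import MitigationStrategy
from .synthetic_data import CountryProfile, DISEASES


@dataclass(frozen=True)
class ParamPerturbation:
    """A multiplicative perturbation of one dotted profile parameter."""

    parameter_path: str
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValidationError(
                f"ParamPerturbation.multiplier must be > 0, got {self.multiplier}"
            )


@dataclass(frozen=True)
class UncertaintySummary:
    """Empirical summary of Monte Carlo outcome draws."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_draws: int

    @staticmethod
    def from_draws(draws: Sequence[float], level: float = 0.95) -> "UncertaintySummary":
        arr = np.asarray(draws, dtype=float)
        lo, hi = credible_interval(arr, level)
        return UncertaintySummary(
            mean=float(arr.mean()), sd=float(arr.std(ddof=1)),
            ci_low=lo, ci_high=hi, n_draws=len(arr),
        )


# natural bounds by (suffix of) field name; perturbed values are clamped here
_FIELD_BOUNDS = {
    "prevalence_2015": (0.0, 1.0),
    "disability_weight": (0.0, 1.0),
    "intake_cv_zinc": (1e-6, 0.999999),
    "intake_cv_iron": (1e-6, 0.999999),
    "zinc_decline_2050": (0.0, 0.999999),
    "iron_decline_2050": (0.0, 0.999999),
    "rr_given_zinc_deficient": (1.0, np.inf),
    "prevalence_apc": (-0.999, np.inf),
    "mortality_apc": (-0.999, np.inf),
}


def _natural_bounds(field_name: str) -> Tuple[float, float]:
    return _FIELD_BOUNDS.get(field_name, (0.0, np.inf))


def get_parameter(profile: CountryProfile, path: str) -> float:
    """Resolve a dotted parameter path to its current value."""
    parts = path.split(".")
    try:
        if len(parts) == 1:
            return float(getattr(profile, parts[0]))
        if parts[0] == "disease_epi" and len(parts) == 3:
            return float(getattr(profile.disease_epi[parts[1]], parts[2]))
        if parts[0] == "foods" and len(parts) == 3:
            food = next(f for f in profile.foods if f.category == parts[1])
            return float(getattr(food, parts[2]))
    except (AttributeError, KeyError, StopIteration, TypeError) as exc:
        raise ValidationError(f"parameter path {path!r} does not resolve") from exc
    raise ValidationError(f"parameter path {path!r} does not resolve")


def perturb_profile(profile: CountryProfile, path: str,
                    multiplier: float) -> Tuple[CountryProfile, bool]:
    """Return a copy with one parameter multiplied, clamped to natural bounds.

    The second element reports whether clamping was applied.
    """
    if multiplier <= 0:
        raise ValidationError(f"multiplier must be > 0, got {multiplier}")
    parts = path.split(".")
    current = get_parameter(profile, path)
    lo, hi = _natural_bounds(parts[-1])
    new = current * multiplier
    clamped = not (lo <= new <= hi)
    new = float(np.clip(new, lo, hi))

    if len(parts) == 1:
        return dataclasses.replace(profile, **{parts[0]: new}), clamped
    if parts[0] == "disease_epi":
        epi = dict(profile.disease_epi)
        epi[parts[1]] = dataclasses.replace(epi[parts[1]], **{parts[2]: new})
        return dataclasses.replace(profile, disease_epi=epi), clamped
    # foods.<category>.<field>
    foods = tuple(
        dataclasses.replace(f, **{parts[2]: new}) if f.category == parts[1] else f
        for f in profile.foods
    )
    return dataclasses.replace(profile, foods=foods), clamped


def default_parameter_paths(profile: CountryProfile) -> List[str]:
    """A representative input list for sensitivity runs."""
    paths = ["wtdear_zinc", "wtdear_iron", "intake_cv_zinc", "intake_cv_iron",
             "crude_birth_rate"]
    for d in DISEASES:
        paths += [f"disease_epi.{d}.prevalence_2015",
                  f"disease_epi.{d}.mortality_2015",
                  f"disease_epi.{d}.disability_weight"]
    for f in profile.foods:
        if f.zinc_decline_2050 > 0:
            paths += [f"foods.{f.category}.zinc_conc_2015",
                      f"foods.{f.category}.iron_conc_2015"]
    return paths


def _mean_outcome(profile: CountryProfile, scn: CO2Scenario,
                  strategy: MitigationStrategy, n: int, reps: int, seed: int,
                  config: SimConfig) -> float:
    vals = [
        run_paired(profile, scn, strategy, n=n, seed=seed + r,
                   config=config).attributable_dalys_per_1000
        for r in range(reps)
    ]
    return float(np.mean(vals))


def one_way(profile: CountryProfile, scn: CO2Scenario,
            strategy: MitigationStrategy, parameters: Sequence[str],
            n: int = 2000, reps: int = 3, seed: int = 0,
            low: float = 0.9, high: float = 1.1,
            config: SimConfig = DEFAULT_CONFIG) -> List[Dict]:
    """Perturb each parameter alone by ``low``/``high``; rank by spread.

    Returns one record per parameter with the low/high outcomes (mean
    attributable DALYs per 1,000 over ``reps`` seeds, common random numbers
    within the pair), sorted by ``|high - low|`` descending.
    """
    if reps < 1:
        raise ValidationError(f"one_way: reps must be >= 1, got {reps}")
    records = []
    for path in parameters:
        get_parameter(profile, path)  # fail fast on bad paths
        p_low, cl_low = perturb_profile(profile, path, low)
        p_high, cl_high = perturb_profile(profile, path, high)
        out_low = _mean_outcome(p_low, scn, strategy, n, reps, seed, config)
        out_high = _mean_outcome(p_high, scn, strategy, n, reps, seed, config)
        records.append({
            "parameter": path,
            "low": out_low,
            "high": out_high,
            "spread": abs(out_high - out_low),
            "clamped": cl_low or cl_high,
        })
    records.sort(key=lambda r: (-r["spread"], r["parameter"]))
    return records


def probabilistic(profile: CountryProfile, scn: CO2Scenario,
                  strategy: MitigationStrategy,
                  parameters: Optional[Sequence[str]] = None,
                  n_draws: int = 100, seed: int = 0, n: int = 2000,
                  rel_sd: float = 0.10,
                  distributions: Optional[Dict[str, float]] = None,
                  outcome: str = "attributable_dalys_per_1000",
                  config: SimConfig = DEFAULT_CONFIG
                  ) -> Tuple[UncertaintySummary, np.ndarray]:
    """Monte Carlo over jointly sampled inputs; returns (summary, draws).

    ``distributions`` optionally maps a parameter path to its relative SD
    (overriding ``rel_sd``); all multipliers are sampled independently from
    normal(1, rel_sd), floored at 0.01, and parameter values are clamped to
    natural bounds.  ``outcome`` is either the attributable burden per
    1,000 or ``"averted_fraction"`` relative to a no-strategy run with the
    same draw.
    """
    if n_draws < 2:
        raise ValidationError(f"probabilistic: n_draws must be >= 2, got {n_draws}")
    if outcome not in ("attributable_dalys_per_1000", "averted_fraction"):
        raise ValidationError(f"unknown outcome {outcome!r}")
    if parameters is None:
        parameters = default_parameter_paths(profile)
    distributions = distributions or {}
    for path, sd in distributions.items():
        if sd < 0:
            raise ValidationError(
                f"distribution SD for {path!r} must be >= 0, got {sd}"
            )

    rng = np.random.default_rng([seed, 7])
    none_strategy = MitigationStrategy(name="none")
    draws = np.empty(n_draws)
    for k in range(n_draws):
        perturbed = profile
        for path in parameters:
            sd = distributions.get(path, rel_sd)
            mult = max(rng.normal(1.0, sd), 0.01) if sd > 0 else 1.0
            perturbed, _ = perturb_profile(perturbed, path, mult)
        # fixed sim seed across draws: common random numbers isolate input
        # uncertainty, and zero input SDs yield an exactly degenerate summary
        sim_seed = seed + 1000
        res = run_paired(perturbed, scn, strategy, n=n, seed=sim_seed,
                         config=config)
        if outcome == "attributable_dalys_per_1000":
            draws[k] = res.attributable_dalys_per_1000
        else:
            base = run_paired(perturbed, scn, none_strategy, n=n,
                              seed=sim_seed, config=config)
            b0 = base.attributable_dalys_per_1000
            draws[k] = np.nan if b0 <= 0 else 1.0 - res.attributable_dalys_per_1000 / b0
    draws = draws[~np.isnan(draws)]
    return UncertaintySummary.from_draws(draws), draws


def credible_interval(draws: Sequence[float], level: float = 0.95
                      ) -> Tuple[float, float]:
    """Empirical percentile interval with linear interpolation."""
    arr = np.asarray(draws, dtype=float)
    if arr.size < 2:
        raise ValidationError(
            f"credible_interval needs at least 2 draws, got {arr.size}"
        )
    if not 0.0 < level < 1.0:
        raise ValidationError(f"credible_interval level must be in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(arr, [100 * alpha, 100 * (1 - alpha)], method="linear")
    return float(lo), float(hi)
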
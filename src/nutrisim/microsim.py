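"""Paired-arm microsimulation with common random numbers and DALY accounting.

Two identical population samples are initialised from the same seed.  The
exposed arm experiences CO2-induced declines in crop zinc/iron
concentrations; the counterfactual arm keeps 2015 concentrations.  Each
individual carries persistent intake quantiles (``u_zinc``, ``u_iron``), so
the arms differ only through the intake distributions; the per-year death
draws and newborn attributes come from seed-derived streams shared between
arms.  With zero declines the arms are bit-identical and the attributable
burden is exactly zero.

Annual time step: each simulated year, deficiency status is evaluated from
that year's scenario-specific intake distribution, disease person-time is
accrued deterministically at the individual's (possibly RR-elevated)
prevalence, at most one death per individual is sampled (modeled diseases
first, then background mortality), survivors age one year, and births keep
the cohort open at the crude birth rate.

Disease rates are partitioned so the population-average rate reproduces the
GBD-style input: the non-deficient stratum faces
``avg / (1 + f * (rr - 1))`` and the deficient stratum ``rr`` times that,
where ``f`` is the analytic 2015 deficiency prevalence of the relevant risk
group in the no-CO2 arm (the calibration anchor, held fixed over time).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .deficiency import build_intake_distribution, deficiency_prevalence
from .errors import RangeError, ValidationError
from .exposure import CO2Scenario, END_YEAR, START_YEAR, per_capita_supply
from .scenarios import MitigationStrategy, apply_disease_control, apply_supplementation
from .synthetic_data import AGE_BANDS, CountryProfile, DISEASES

CAUSES = DISEASES  # ("malaria", "pneumonia", "diarrhea", "ida")
UNDER5_DISEASES = ("malaria", "pneumonia", "diarrhea")

YEARS = tuple(range(START_YEAR, END_YEAR + 1))


@dataclass(frozen=True)
class SimConfig:
    """Switches for the documented implementation choices."""

    constant_prevalence: bool = False        # hold disease prevalence at 2015
    iron_lognormal: bool = False             # lognormal iron intake, CV 40%
    iron_lognormal_cv: float = 0.40
    independent_intakes: bool = False        # default: u_iron == u_zinc
    rr_ida: Optional[float] = None           # None: all IDA mortality in deficient stratum


DEFAULT_CONFIG = SimConfig()


@dataclass
class Individual:
    """Scalar view of one simulated person (arrays are the source of truth)."""

    age: int
    sex: str
    u_zinc: float
    u_iron: float
    alive: bool = True


class Population:
    """Array-backed cohort of simulated persons.

    Paired arms constructed from the same ``(profile, n, seed)`` are
    identical at initialisation and consume identical seed-derived random
    streams while stepping.
    """

    def __init__(self, country_id: str, rng_seed: int, age: np.ndarray,
                 sex: np.ndarray, u_zinc: np.ndarray, u_iron: np.ndarray,
                 u_cov: np.ndarray):
        self.country_id = country_id
        self.rng_seed = rng_seed
        self.age = age
        self.sex = sex            # 0 = female, 1 = male
        self.u_zinc = u_zinc
        self.u_iron = u_iron
        self.u_cov = u_cov        # persistent coverage-selection quantile
        self.alive = np.ones(len(age), dtype=bool)
        self.n_initial = len(age)

    def __len__(self) -> int:
        return len(self.age)

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    @property
    def individuals(self) -> List[Individual]:
        return [
            Individual(age=int(a), sex="female" if s == 0 else "male",
                       u_zinc=float(uz), u_iron=float(ui), alive=bool(al))
            for a, s, uz, ui, al in zip(self.age, self.sex, self.u_zinc,
                                        self.u_iron, self.alive)
        ]

    def age_band(self) -> np.ndarray:
        """Index into AGE_BANDS for every individual."""
        return np.select(
            [self.age < 5, self.age < 15, self.age < 50],
            [0, 1, 2],
            default=3,
        )

    def append(self, age, sex, u_zinc, u_iron, u_cov) -> None:
        self.age = np.concatenate([self.age, age])
        self.sex = np.concatenate([self.sex, sex])
        self.u_zinc = np.concatenate([self.u_zinc, u_zinc])
        self.u_iron = np.concatenate([self.u_iron, u_iron])
        self.u_cov = np.concatenate([self.u_cov, u_cov])
        self.alive = np.concatenate([self.alive, np.ones(len(age), dtype=bool)])


@dataclass
class YearSlice:
    """Burden accrued in a single simulated year."""

    year: int
    yll: np.ndarray          # (4,) by cause
    yld: np.ndarray          # (4,)
    deaths: np.ndarray       # (4,)
    background_deaths: float
    zinc_deficiency_prev: float
    iron_deficiency_prev: float
    person_years: float
    births: float = 0.0

    @property
    def dalys(self) -> np.ndarray:
        return self.yll + self.yld


@dataclass
class BurdenResult:
    """Per-year, per-cause burden for one simulation arm."""

    years: np.ndarray        # (T,)
    causes: Tuple[str, ...]  # (4,)
    yll: np.ndarray          # (T, 4)
    yld: np.ndarray          # (T, 4)
    deaths: np.ndarray       # (T, 4)
    zinc_deficiency_prev: np.ndarray   # (T,)
    iron_deficiency_prev: np.ndarray   # (T,)
    person_years: np.ndarray           # (T,)
    n_initial: int

    @property
    def dalys(self) -> np.ndarray:
        """(T, 4) DALYs; YLL + YLD exactly, by construction."""
        return self.yll + self.yld

    def cumulative_dalys(self, cause: Optional[str] = None) -> float:
        if cause is None:
            return float(self.dalys.sum())
        return float(self.dalys[:, self.causes.index(cause)].sum())

    def cumulative_dalys_per_1000(self, cause: Optional[str] = None) -> float:
        return self.cumulative_dalys(cause) / self.n_initial * 1000.0

    @staticmethod
    def from_slices(slices: List[YearSlice], n_initial: int) -> "BurdenResult":
        return BurdenResult(
            years=np.array([s.year for s in slices]),
            causes=CAUSES,
            yll=np.vstack([s.yll for s in slices]),
            yld=np.vstack([s.yld for s in slices]),
            deaths=np.vstack([s.deaths for s in slices]),
            zinc_deficiency_prev=np.array([s.zinc_deficiency_prev for s in slices]),
            iron_deficiency_prev=np.array([s.iron_deficiency_prev for s in slices]),
            person_years=np.array([s.person_years for s in slices]),
            n_initial=n_initial,
        )


@dataclass
class PairedResult:
    """Exposed and counterfactual arms plus the attributable difference."""

    exposed: BurdenResult
    counterfactual: BurdenResult

    @property
    def n_initial(self) -> int:
        return self.exposed.n_initial

    def attributable_dalys(self, cause: Optional[str] = None) -> float:
        return (self.exposed.cumulative_dalys(cause)
                - self.counterfactual.cumulative_dalys(cause))

    @property
    def attributable_dalys_per_1000(self) -> float:
        return self.attributable_dalys() / self.n_initial * 1000.0

    def attributable_by_cause(self) -> Dict[str, float]:
        return {c: self.attributable_dalys(c) for c in CAUSES}


# ---------------------------------------------------------------------------
# rate algebra


def project_rate(rate_2015: float, apc: float, year: int) -> float:
    """Continue an annual proportional trend: rate_2015 * (1 + apc)^(y - 2015)."""
    if apc <= -1.0:
        raise ValidationError(f"project_rate: apc must be > -1, got {apc}")
    if year < START_YEAR:
        raise RangeError(f"project_rate: year must be >= {START_YEAR}, got {year}")
    if rate_2015 < 0:
        raise ValidationError(f"project_rate: rate_2015 must be >= 0, got {rate_2015}")
    return max(rate_2015 * (1.0 + apc) ** (year - START_YEAR), 0.0)


def partition_rate_by_deficiency(avg_rate: float, deficient_fraction: float,
                                 rr: float) -> Tuple[float, float]:
    """Split a population-average rate into (non-deficient, deficient) rates.

    The weighted mean recovers ``avg_rate`` exactly:
    ``(1 - f) * nd + f * rr * nd == avg_rate``.
    """
    if avg_rate < 0:
        raise ValidationError("partition: avg_rate must be >= 0")
    if not 0.0 <= deficient_fraction <= 1.0:
        raise ValidationError("partition: deficient_fraction must be in [0, 1]")
    if rr < 1.0:
        raise ValidationError("partition: rr must be >= 1")
    nondeficient = avg_rate / (1.0 + deficient_fraction * (rr - 1.0))
    return nondeficient, rr * nondeficient


# ---------------------------------------------------------------------------
# population initialisation and stepping


def init_population(profile: CountryProfile, n: int, seed: int,
                    config: SimConfig = DEFAULT_CONFIG) -> Population:
    """Draw ``n`` individuals from the profile's demographic weights.

    Deterministic for fixed arguments; persistent intake quantiles are
    perfectly rank-correlated between zinc and iron unless
    ``config.independent_intakes`` is set.
    """
    if n < 1:
        raise ValidationError(f"init_population: n must be >= 1, got {n}")
    rng = np.random.default_rng([seed, 0])
    cells = [(band, sex) for band in AGE_BANDS for sex in ("female", "male")]
    probs = np.array([profile.demographic_weights.get(c, 0.0) for c in cells])
    probs = probs / probs.sum()
    cell_idx = rng.choice(len(cells), size=n, p=probs)

    from .synthetic_data import AGE_BAND_RANGES
    lows = np.array([AGE_BAND_RANGES[band][0] for band, _ in cells])
    highs = np.array([AGE_BAND_RANGES[band][1] for band, _ in cells])
    age = rng.integers(lows[cell_idx], highs[cell_idx] + 1)
    sex = np.array([1 if cells[i][1] == "male" else 0 for i in cell_idx],
                   dtype=np.int8)
    u_zinc = rng.uniform(size=n)
    u_iron = rng.uniform(size=n) if config.independent_intakes else u_zinc.copy()
    u_cov = rng.uniform(size=n)
    return Population(profile.country_id, seed, age, sex, u_zinc, u_iron, u_cov)


def _iron_distribution(profile: CountryProfile, year: int, scn: CO2Scenario,
                       config: SimConfig):
    mean = per_capita_supply(profile, "iron", year, scn)
    if config.iron_lognormal:
        return build_intake_distribution(mean, config.iron_lognormal_cv, "lognormal")
    return build_intake_distribution(mean, profile.intake_cv_iron,
                                     profile.iron_family)


def _zinc_distribution(profile: CountryProfile, year: int, scn: CO2Scenario):
    mean = per_capita_supply(profile, "zinc", year, scn)
    return build_intake_distribution(mean, profile.intake_cv_zinc, "normal")


def rr_group_anchors(profile: CountryProfile,
                     config: SimConfig = DEFAULT_CONFIG) -> Dict[str, float]:
    """Analytic 2015 fractions of the population in each RR-elevated group.

    Under-5 diseases: under-5 population share times the analytic zinc
    deficiency prevalence (the RR group is deficient under-5s).  IDA: the
    analytic iron deficiency prevalence.  Evaluated in the no-decline arm,
    these anchors keep the partitioned rates consistent with the
    population-average inputs.
    """
    no_co2 = CO2Scenario(fraction_rise_prevented=1.0)
    zn = deficiency_prevalence(_zinc_distribution(profile, START_YEAR, no_co2),
                               profile.wtdear_zinc)
    fe = deficiency_prevalence(_iron_distribution(profile, START_YEAR, no_co2, config),
                               profile.wtdear_iron)
    u5 = profile.under5_fraction
    return {
        "malaria": u5 * zn,
        "pneumonia": u5 * zn,
        "diarrhea": u5 * zn,
        "ida": fe,
    }


def _birth_schedule(profile: CountryProfile, n_initial: int, year: int) -> int:
    """Deterministic births for ``year``: crude birth rate times the
    deterministically projected population.

    The projection uses the profile's crude growth rate (births minus
    population-weighted background mortality) rather than the arm's
    realised alive count, so paired arms append identical newborn slots and
    their shared random streams stay aligned for the whole horizon.
    """
    bar_mu = sum(
        w * profile.background_mortality[band]
        for (band, _sex), w in profile.demographic_weights.items()
    )
    growth = profile.crude_birth_rate - bar_mu
    expected_alive = n_initial * (1.0 + growth) ** (year - START_YEAR)
    return int(round(profile.crude_birth_rate * expected_alive))


def _target_mask(pop: Population, target: str) -> np.ndarray:
    if target == "children_under5":
        return pop.age < 5
    if target == "females_over5":
        return (pop.sex == 0) & (pop.age >= 5)
    if target == "whole_population":
        return np.ones(len(pop), dtype=bool)
    return np.zeros(len(pop), dtype=bool)


def _effective_deficiency(pop: Population, dist, wtdear: float,
                          strategy: MitigationStrategy, nutrient: str,
                          u: np.ndarray) -> np.ndarray:
    """Raw cut-point deficiency, then supplementation overrides."""
    supp = strategy.supplementation_for(nutrient)
    if supp is not None and supp.supplement_mg_per_day is not None:
        covered = (pop.u_cov < supp.coverage) & _target_mask(pop, supp.target)
        intake = dist.quantile(u)
        intake = np.where(covered, intake + supp.supplement_mg_per_day, intake)
        return intake < wtdear
    # strict tie rule: quantile(u) < wtdear  <=>  u < CDF(wtdear)
    raw = u < dist.cdf(wtdear)
    if supp is None:
        return raw
    covered = (pop.u_cov < supp.coverage) & _target_mask(pop, supp.target)
    return apply_supplementation(covered, raw)


def simulate_year(pop: Population, profile: CountryProfile, year: int,
                  scn: CO2Scenario, strategy: MitigationStrategy,
                  config: SimConfig = DEFAULT_CONFIG,
                  anchors: Optional[Dict[str, float]] = None) -> YearSlice:
    """Step the population through one year, mutating it in place.

    Returns the burden accrued during the year.  All stochastic draws come
    from streams derived from ``(pop.rng_seed, year)``, so paired arms see
    identical randomness.
    """
    if not START_YEAR <= year <= END_YEAR:
        raise RangeError(f"simulate_year: year must be in [{START_YEAR}, {END_YEAR}]")
    for leaf in strategy.leaves():
        if leaf.disease is not None and leaf.disease not in DISEASES:
            raise ValidationError(
                f"strategy {strategy.name!r} targets unknown disease {leaf.disease!r}"
            )
    if anchors is None:
        anchors = rr_group_anchors(profile, config)

    n = len(pop)
    alive = pop.alive
    n_alive = int(alive.sum())
    if n_alive == 0:
        zero = np.zeros(len(CAUSES))
        return YearSlice(year, zero, zero.copy(), zero.copy(), 0.0,
                         0.0, 0.0, 0.0)

    dist_zn = _zinc_distribution(profile, year, scn)
    dist_fe = _iron_distribution(profile, year, scn, config)
    def_zn = _effective_deficiency(pop, dist_zn, profile.wtdear_zinc,
                                   strategy, "zinc", pop.u_zinc)
    def_fe = _effective_deficiency(pop, dist_fe, profile.wtdear_iron,
                                   strategy, "iron", pop.u_iron)

    under5 = pop.age < 5
    yll = np.zeros(len(CAUSES))
    yld = np.zeros(len(CAUSES))
    deaths = np.zeros(len(CAUSES))
    mortality = np.zeros((n, len(CAUSES)))

    for ci, disease in enumerate(CAUSES):
        epi = profile.disease_epi[disease]
        prev_apc = 0.0 if config.constant_prevalence else epi.prevalence_apc
        prev = project_rate(epi.prevalence_2015, prev_apc, year)
        mort = project_rate(epi.mortality_2015, epi.mortality_apc, year)
        prev = apply_disease_control(prev, strategy, "prevalence", disease)
        mort = apply_disease_control(mort, strategy, "mortality", disease)
        f = anchors[disease]

        if disease == "ida":
            # YLD: every iron-deficient person-year carries the IDA weight.
            ida_mask = def_fe & alive
            yld[ci] = epi.disability_weight * ida_mask.sum()
            if config.rr_ida is None:
                # all IDA mortality borne by the deficient stratum
                if f > 0:
                    mortality[:, ci] = np.where(ida_mask, mort / f, 0.0)
                else:
                    mortality[:, ci] = np.where(alive, mort, 0.0)
            else:
                m_nd, m_d = partition_rate_by_deficiency(mort, f, config.rr_ida)
                mortality[:, ci] = np.where(ida_mask, m_d, m_nd)
        else:
            rr = epi.rr_given_zinc_deficient
            p_nd, p_d = partition_rate_by_deficiency(prev, f, rr)
            m_nd, m_d = partition_rate_by_deficiency(mort, f, rr)
            rr_mask = def_zn & under5 & alive
            prev_i = np.where(rr_mask, p_d, p_nd)
            yld[ci] = epi.disability_weight * prev_i[alive].sum()
            mortality[:, ci] = np.where(rr_mask, m_d, m_nd)
        mortality[~alive, ci] = 0.0

    # At most one death per individual per year: one shared uniform per
    # cause (modeled diseases in fixed order, background mortality last),
    # first triggered cause wins.  Per-cause uniforms keep a cause's death
    # draws identical across paired arms whenever its rates are identical,
    # so attributable burden flows only through genuinely different rates.
    background = np.array(
        [profile.background_mortality[AGE_BANDS[b]] for b in pop.age_band()]
    )
    probs = np.concatenate([mortality, background[:, None]], axis=1)
    rng_event = np.random.default_rng([pop.rng_seed, year, 1])
    u_event = rng_event.uniform(size=(n, len(CAUSES) + 1))
    triggered = u_event < np.clip(probs, 0.0, 1.0)
    died_any = triggered.any(axis=1)
    first_cause = triggered.argmax(axis=1)
    survived = len(CAUSES) + 1
    cause_idx = np.where(alive & died_any, first_cause, survived)

    life_exp = np.array(
        [profile.life_expectancy_at_death[AGE_BANDS[b]] for b in pop.age_band()]
    )
    for ci in range(len(CAUSES)):
        died_c = cause_idx == ci
        deaths[ci] = died_c.sum()
        yll[ci] = life_exp[died_c].sum()
    background_deaths = float((cause_idx == len(CAUSES)).sum())

    zinc_prev = float(def_zn[alive].mean())
    iron_prev = float(def_fe[alive].mean())
    person_years = float(n_alive)

    # transitions: deaths, aging, births
    pop.alive = alive & (cause_idx == survived)
    pop.age[pop.alive] += 1

    n_births = _birth_schedule(profile, pop.n_initial, year)
    if n_births > 0:
        rng_birth = np.random.default_rng([pop.rng_seed, year, 2])
        draws = rng_birth.uniform(size=(n_births, 4))
        b_sex = (draws[:, 0] < 0.5).astype(np.int8)  # 1 = male
        b_uz = draws[:, 1]
        b_ui = draws[:, 2] if config.independent_intakes else b_uz.copy()
        b_cov = draws[:, 3]
        pop.append(np.zeros(n_births, dtype=pop.age.dtype), b_sex, b_uz, b_ui, b_cov)

    return YearSlice(year, yll, yld, deaths, background_deaths,
                     zinc_prev, iron_prev, person_years, births=float(n_births))


def run_arm(profile: CountryProfile, scn: CO2Scenario,
            strategy: MitigationStrategy, n: int, seed: int,
            config: SimConfig = DEFAULT_CONFIG) -> BurdenResult:
    """Simulate one arm over the full 2015-2050 horizon."""
    pop = init_population(profile, n, seed, config)
    anchors = rr_group_anchors(profile, config)
    slices = [simulate_year(pop, profile, year, scn, strategy, config, anchors)
              for year in YEARS]
    return BurdenResult.from_slices(slices, n)


def run_paired(profile: CountryProfile, scn: Optional[CO2Scenario] = None,
               strategy: Optional[MitigationStrategy] = None,
               n: int = 10_000, seed: int = 0,
               config: SimConfig = DEFAULT_CONFIG) -> PairedResult:
    """Run the exposed and counterfactual arms with common random numbers.

    The counterfactual arm keeps 2015 nutrient concentrations
    (``fraction_rise_prevented = 1``); the exposed arm follows ``scn``,
    additionally mitigated if the strategy prevents part of the CO2 rise.
    Any supplementation or disease-control strategy acts identically in
    both arms.
    """
    if n < 1:
        raise ValidationError(f"run_paired: n must be >= 1, got {n}")
    scn = scn if scn is not None else CO2Scenario()
    strategy = strategy if strategy is not None else MitigationStrategy(name="none")

    frp = max(scn.fraction_rise_prevented, strategy.total_fraction_rise_prevented)
    exposed_scn = dataclasses.replace(scn, fraction_rise_prevented=frp)
    cf_scn = dataclasses.replace(scn, fraction_rise_prevented=1.0)

    exposed = run_arm(profile, exposed_scn, strategy, n, seed, config)
    counterfactual = run_arm(profile, cf_scn, strategy, n, seed, config)
    return PairedResult(exposed=exposed, counterfactual=counterfactual)
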
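import dataclasses
import math

import numpy as np
import pytest

import nutrisim as ns
from nutrisim.errors import RangeError, ValidationError
from nutrisim.microsim import (CAUSES, SimConfig, rr_group_anchors, run_arm,
                               simulate_year)


def _no_decline_scenario():
    return ns.CO2Scenario(fraction_rise_prevented=1.0)


def _zero_disease_profile(profile):
    # IDA YLD is deficiency-driven (disability weight per deficient
    # person-year), so silencing the IDA pathway requires zeroing its
    # disability weight, not just its prevalence
    epi = {
        d: dataclasses.replace(e, prevalence_2015=0.0, mortality_2015=0.0,
                               disability_weight=0.0 if d == "ida"
                               else e.disability_weight)
        for d, e in profile.disease_epi.items()
    }
    return dataclasses.replace(profile, disease_epi=epi)


class TestProjectRate:
    def test_flat_trend(self):
        assert ns.project_rate(0.05, 0.0, 2040) == pytest.approx(0.05)

    def test_one_step(self):
        assert ns.project_rate(0.05, -0.02, 2016) == pytest.approx(0.049)

    def test_35_year_hand_value(self):
        # oracle: iterated multiplication
        expected = 0.038
        for _ in range(35):
            expected *= 0.98
        assert ns.project_rate(0.038, -0.02, 2050) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.01873, abs=1e-5)

    def test_closed_form_to_1e12(self):
        for apc in (-0.03, 0.0, 0.015):
            for year in (2015, 2030, 2050):
                got = ns.project_rate(0.2, apc, year)
                oracle = 0.2
                for _ in range(year - 2015):
                    oracle *= 1.0 + apc
                assert got == pytest.approx(oracle, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValidationError):
            ns.project_rate(0.05, -1.0, 2020)
        with pytest.raises(RangeError):
            ns.project_rate(0.05, 0.0, 2014)
        with pytest.raises(ValidationError):
            ns.project_rate(-0.05, 0.0, 2020)


class TestPartition:
    def test_null_rr(self):
        nd, d = ns.partition_rate_by_deficiency(0.07, 0.3, 1.0)
        assert nd == pytest.approx(0.07)
        assert d == pytest.approx(0.07)

    def test_hand_value(self):
        nd, d = ns.partition_rate_by_deficiency(0.10, 0.5, 1.5)
        assert (nd, d) == (pytest.approx(0.08), pytest.approx(0.12))
        assert 0.5 * nd + 0.5 * d == pytest.approx(0.10)

    def test_zero_deficient_fraction(self):
        nd, d = ns.partition_rate_by_deficiency(0.10, 0.0, 2.0)
        assert nd == pytest.approx(0.10)

    @pytest.mark.parametrize("avg,f,rr", [(0.05, 0.2, 1.56), (0.3, 0.9, 3.0),
                                          (0.0, 0.5, 1.2)])
    def test_mean_preserved_exactly(self, avg, f, rr):
        nd, d = ns.partition_rate_by_deficiency(avg, f, rr)
        assert (1 - f) * nd + f * d == pytest.approx(avg, abs=1e-15)

    def test_validation(self):
        with pytest.raises(ValidationError):
            ns.partition_rate_by_deficiency(-0.1, 0.5, 1.5)
        with pytest.raises(ValidationError):
            ns.partition_rate_by_deficiency(0.1, 1.5, 1.5)
        with pytest.raises(ValidationError):
            ns.partition_rate_by_deficiency(0.1, 0.5, 0.9)


class TestInitPopulation:
    def test_deterministic(self, high_profile):
        a = ns.init_population(high_profile, 5000, seed=5)
        b = ns.init_population(high_profile, 5000, seed=5)
        for attr in ("age", "sex", "u_zinc", "u_iron", "u_cov", "alive"):
            np.testing.assert_array_equal(getattr(a, attr), getattr(b, attr))

    def test_under5_fraction_within_3se(self, high_profile):
        n = 100_000
        pop = ns.init_population(high_profile, n, seed=9)
        w = high_profile.under5_fraction
        se = math.sqrt(w * (1 - w) / n)
        assert abs((pop.age < 5).mean() - w) < 3 * se

    def test_single_individual(self, high_profile):
        pop = ns.init_population(high_profile, 1, seed=0)
        ind = pop.individuals[0]
        assert ind.alive and ind.age >= 0
        assert 0.0 < ind.u_zinc < 1.0
        assert ind.sex in ("female", "male")

    def test_rank_correlated_intakes_by_default(self, high_profile):
        pop = ns.init_population(high_profile, 1000, seed=1)
        np.testing.assert_array_equal(pop.u_zinc, pop.u_iron)

    def test_independent_intakes_switch(self, high_profile):
        pop = ns.init_population(high_profile, 1000, seed=1,
                                 config=SimConfig(independent_intakes=True))
        assert not np.array_equal(pop.u_zinc, pop.u_iron)

    def test_rejects_nonpositive_n(self, high_profile):
        with pytest.raises(ValidationError):
            ns.init_population(high_profile, 0, seed=0)


class TestSimulateYear:
    def test_zero_disease_zero_burden(self, high_profile, none_strategy):
        profile = _zero_disease_profile(high_profile)
        pop = ns.init_population(profile, 2000, seed=0)
        s = simulate_year(pop, profile, 2015, ns.CO2Scenario(), none_strategy)
        assert s.yll.sum() == 0 and s.yld.sum() == 0 and s.deaths.sum() == 0

    def test_person_year_conservation(self, high_profile, none_strategy):
        pop = ns.init_population(high_profile, 5000, seed=3)
        anchors = rr_group_anchors(high_profile)
        for year in range(2015, 2020):
            before = pop.n_alive
            s = simulate_year(pop, high_profile, year, ns.CO2Scenario(),
                              none_strategy, anchors=anchors)
            after = pop.n_alive
            assert after == before - (s.deaths.sum() + s.background_deaths) \
                + s.births
            assert s.deaths.sum() + s.background_deaths <= before

    def test_population_mean_prevalence_matches_input(self, high_profile,
                                                      none_strategy):
        # partition identity: implied average malaria prevalence in the
        # no-CO2 arm equals the projected input within 3 binomial SEs
        n = 100_000
        profile = high_profile
        pop = ns.init_population(profile, n, seed=4)
        s = simulate_year(pop, profile, 2015, _no_decline_scenario(),
                          none_strategy)
        epi = profile.disease_epi["malaria"]
        implied = s.yld[CAUSES.index("malaria")] / (
            epi.disability_weight * s.person_years)
        f = rr_group_anchors(profile)["malaria"]
        nd, d = ns.partition_rate_by_deficiency(
            epi.prevalence_2015, f, epi.rr_given_zinc_deficient)
        se = (d - nd) * math.sqrt(f * (1 - f) / n)
        assert abs(implied - epi.prevalence_2015) < 3 * se

    def test_mortality_bernoulli_matches_input(self, high_profile,
                                               none_strategy):
        n = 100_000
        pop = ns.init_population(high_profile, n, seed=8)
        s = simulate_year(pop, high_profile, 2015, _no_decline_scenario(),
                          none_strategy)
        epi = high_profile.disease_epi["malaria"]
        expected = epi.mortality_2015 * n
        assert abs(s.deaths[CAUSES.index("malaria")] - expected) \
            < 3 * math.sqrt(expected)

    def test_unknown_strategy_disease(self, high_profile):
        bad = ns.MitigationStrategy(name="x_control", coverage=0.5,
                                    disease="cholera", efficacy_mortality=0.5)
        pop = ns.init_population(high_profile, 100, seed=0)
        with pytest.raises(ValidationError, match="cholera"):
            simulate_year(pop, high_profile, 2015, ns.CO2Scenario(), bad)

    def test_year_out_of_range(self, high_profile, none_strategy):
        pop = ns.init_population(high_profile, 100, seed=0)
        with pytest.raises(RangeError):
            simulate_year(pop, high_profile, 2051, ns.CO2Scenario(),
                          none_strategy)


class TestRunPaired:
    def test_null_when_declines_prevented(self, high_profile):
        res = ns.run_paired(high_profile, _no_decline_scenario(),
                            n=2000, seed=11)
        assert res.attributable_dalys() == 0.0
        np.testing.assert_array_equal(res.exposed.yll, res.counterfactual.yll)
        np.testing.assert_array_equal(res.exposed.yld, res.counterfactual.yld)

    def test_null_with_zero_decline_foods(self, high_profile):
        foods = tuple(dataclasses.replace(f, zinc_decline_2050=0.0,
                                          iron_decline_2050=0.0)
                      for f in high_profile.foods)
        profile = dataclasses.replace(high_profile, foods=foods)
        res = ns.run_paired(profile, n=2000, seed=13)
        assert res.attributable_dalys() == 0.0

    def test_reproducibility(self, high_profile):
        a = ns.run_paired(high_profile, n=1500, seed=21)
        b = ns.run_paired(high_profile, n=1500, seed=21)
        np.testing.assert_array_equal(a.exposed.yll, b.exposed.yll)
        np.testing.assert_array_equal(a.exposed.deaths, b.exposed.deaths)
        assert a.attributable_dalys() == b.attributable_dalys()

    def test_daly_is_yll_plus_yld_exactly(self, high_profile):
        res = ns.run_paired(high_profile, n=1500, seed=2)
        for arm in (res.exposed, res.counterfactual):
            np.testing.assert_array_equal(arm.dalys, arm.yll + arm.yld)

    def test_attributable_positive_in_expectation(self, high_profile):
        vals = [ns.run_paired(high_profile, n=4000, seed=s)
                .attributable_dalys_per_1000 for s in range(5)]
        assert np.mean(vals) > 0

    def test_deficiency_prevalence_rises_in_exposed_arm(self, high_profile):
        res = ns.run_paired(high_profile, n=8000, seed=1)
        # by 2050 the exposed arm must show materially more zinc deficiency
        assert res.exposed.zinc_deficiency_prev[-1] \
            > res.counterfactual.zinc_deficiency_prev[-1] + 0.02
        # at baseline the arms coincide
        assert res.exposed.zinc_deficiency_prev[0] \
            == res.counterfactual.zinc_deficiency_prev[0]

    def test_constant_prevalence_switch(self, high_profile):
        cfg = SimConfig(constant_prevalence=True)
        arm = run_arm(high_profile, _no_decline_scenario(),
                      ns.get_strategy("none"), n=20_000, seed=3, config=cfg)
        epi = high_profile.disease_epi["diarrhea"]
        ci = CAUSES.index("diarrhea")
        implied_2015 = arm.yld[0, ci] / (epi.disability_weight
                                         * arm.person_years[0])
        implied_2050 = arm.yld[-1, ci] / (epi.disability_weight
                                          * arm.person_years[-1])
        # prevalence held at the 2015 level instead of trending down
        assert implied_2050 == pytest.approx(implied_2015, rel=0.15)

    def test_iron_lognormal_switch_changes_burden(self, high_profile):
        a = ns.run_paired(high_profile, n=2000, seed=5)
        b = ns.run_paired(high_profile, n=2000, seed=5,
                          config=SimConfig(iron_lognormal=True))
        assert a.attributable_dalys("ida") != b.attributable_dalys("ida")
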
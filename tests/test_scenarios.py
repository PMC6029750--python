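import numpy as np
import pytest

import nutrisim as ns
from nutrisim.errors import ValidationError


class TestBuiltinStrategies:
    def test_all_names_present(self):
        names = {s.name for s in ns.builtin_strategies()}
        assert names == {"none", "paris", "zinc_supplement", "iron_supplement",
                         "malaria_control", "pneumonia_control",
                         "diarrhea_control", "combined_public_health"}

    def test_paris_prevents_47_percent(self):
        assert ns.get_strategy("paris").fraction_rise_prevented == 0.47

    def test_zinc_supplement_coverage_and_target(self):
        s = ns.get_strategy("zinc_supplement")
        assert s.coverage == 0.80
        assert s.target == "children_under5"
        assert s.supplement_nutrient == "zinc"

    def test_iron_supplement_targets_females_over5(self):
        s = ns.get_strategy("iron_supplement")
        assert s.coverage == 0.80
        assert s.target == "females_over5"

    def test_none_is_identity(self):
        s = ns.get_strategy("none")
        assert s.coverage == 0.0
        assert s.fraction_rise_prevented == 0.0
        assert not s.components

    def test_combined_has_five_components(self):
        s = ns.get_strategy("combined_public_health")
        assert len(s.leaves()) == 5

    def test_unknown_strategy(self):
        with pytest.raises(ValidationError):
            ns.get_strategy("magic")


class TestApplySupplementation:
    @pytest.mark.parametrize("covered,raw,expected", [
        (True, True, False), (False, True, True),
        (True, False, False), (False, False, False),
    ])
    def test_truth_table(self, covered, raw, expected):
        assert bool(ns.apply_supplementation(covered, raw)) is expected

    def test_vectorised(self):
        covered = np.array([True, False, True, False])
        raw = np.array([True, True, False, False])
        np.testing.assert_array_equal(
            ns.apply_supplementation(covered, raw),
            np.array([False, True, False, False]))


class TestApplyDiseaseControl:
    def test_hand_value(self):
        s = ns.MitigationStrategy(name="malaria_control", coverage=0.8,
                                  disease="malaria", efficacy_prevalence=0.5,
                                  efficacy_mortality=0.5)
        assert ns.apply_disease_control(0.10, s, "prevalence", "malaria") \
            == pytest.approx(0.06)

    def test_zero_efficacy_no_change(self):
        s = ns.MitigationStrategy(name="malaria_control", coverage=0.8,
                                  disease="malaria")
        assert ns.apply_disease_control(0.10, s, "prevalence", "malaria") \
            == pytest.approx(0.10)

    def test_full_coverage_full_efficacy(self):
        s = ns.MitigationStrategy(name="malaria_control", coverage=1.0,
                                  disease="malaria", efficacy_prevalence=1.0,
                                  efficacy_mortality=1.0)
        assert ns.apply_disease_control(0.10, s, "mortality", "malaria") == 0.0

    def test_untargeted_disease_unchanged(self):
        s = ns.get_strategy("malaria_control")
        assert ns.apply_disease_control(0.10, s, "prevalence", "diarrhea") \
            == pytest.approx(0.10)

    def test_bad_which(self):
        with pytest.raises(ValidationError):
            ns.apply_disease_control(0.1, ns.get_strategy("none"), "cost",
                                     "malaria")


class TestAvertedFraction:
    def test_no_change(self):
        assert ns.averted_fraction(100.0, 100.0) == 0.0

    def test_everything_averted(self):
        assert ns.averted_fraction(100.0, 0.0) == 1.0

    def test_undefined_for_zero_baseline(self):
        with pytest.raises(ValidationError):
            ns.averted_fraction(0.0, 1.0)


class TestStrategyEffectsInSimulation:
    def test_paris_full_prevention_averts_everything(self, high_profile):
        full = ns.MitigationStrategy(name="paris", target="whole_population",
                                     fraction_rise_prevented=1.0)
        res = ns.run_paired(high_profile, strategy=full, n=1500, seed=3)
        assert res.attributable_dalys() == 0.0

    def test_full_coverage_zinc_kills_childhood_pathway(self, high_profile):
        # whole-population full-coverage zinc supplementation equalises zinc
        # deficiency (none) across arms -> childhood pathways exactly null
        strat = ns.MitigationStrategy(name="zinc_supplement", coverage=1.0,
                                      target="whole_population",
                                      supplement_nutrient="zinc")
        res = ns.run_paired(high_profile, strategy=strat, n=3000, seed=7)
        base = ns.run_paired(high_profile, n=3000, seed=7)
        childhood = sum(res.attributable_dalys(c)
                        for c in ("malaria", "pneumonia", "diarrhea"))
        childhood_base = sum(base.attributable_dalys(c)
                             for c in ("malaria", "pneumonia", "diarrhea"))
        # only survivorship interaction with the iron pathway remains
        assert abs(childhood) < 0.05 * abs(childhood_base)
        # the iron pathway is untouched
        assert res.attributable_dalys("ida") != 0.0

    def test_full_coverage_iron_kills_ida_pathway(self, high_profile):
        strat = ns.MitigationStrategy(name="iron_supplement", coverage=1.0,
                                      target="whole_population",
                                      supplement_nutrient="iron")
        res = ns.run_paired(high_profile, strategy=strat, n=3000, seed=7)
        assert res.attributable_dalys("ida") == 0.0

    def test_disease_control_leaves_deficiency_unchanged(self, high_profile):
        a = ns.run_paired(high_profile, strategy=ns.get_strategy("none"),
                          n=3000, seed=9)
        b = ns.run_paired(high_profile,
                          strategy=ns.get_strategy("malaria_control"),
                          n=3000, seed=9)
        # identical individuals at baseline: prevalence matches exactly
        assert a.exposed.zinc_deficiency_prev[0] \
            == b.exposed.zinc_deficiency_prev[0]
        assert a.exposed.iron_deficiency_prev[0] \
            == b.exposed.iron_deficiency_prev[0]
        # later years may differ microscopically through survivorship only
        np.testing.assert_allclose(a.exposed.zinc_deficiency_prev,
                                   b.exposed.zinc_deficiency_prev, atol=0.01)

    def test_supplementation_lowers_recorded_deficiency(self, high_profile):
        res = ns.run_paired(high_profile,
                            strategy=ns.get_strategy("iron_supplement"),
                            n=3000, seed=9)
        base = ns.run_paired(high_profile, n=3000, seed=9)
        assert res.exposed.iron_deficiency_prev[0] \
            < base.exposed.iron_deficiency_prev[0]

    def test_intake_increment_mode(self, high_profile):
        # +30 mg/day for everyone clears iron deficiency entirely
        strat = ns.MitigationStrategy(name="iron_supplement", coverage=1.0,
                                      target="whole_population",
                                      supplement_nutrient="iron",
                                      supplement_mg_per_day=30.0)
        res = ns.run_paired(high_profile, strategy=strat, n=1000, seed=1)
        assert res.exposed.iron_deficiency_prev[0] == 0.0
        assert res.attributable_dalys("ida") == 0.0
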
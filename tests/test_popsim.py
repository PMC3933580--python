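import numpy as np
import pytest

from sotalolpbpk import ontogeny, physiology, popsim
from sotalolpbpk.popsim import (
    AdultStudyArm,
    ChildRecord,
    VariabilitySpec,
    alternative_variability,
    fixed_variability,
    sample_variability,
    simulate_adult_population,
    simulate_virtual_twins,
)


class TestVariabilitySampling:
    def test_uniform_get_bounds_and_mean(self):
        _, get, _ = sample_variability(10_000, VariabilitySpec(), seed=1)
        assert get.min() >= 0.2 and get.max() <= 1.9
        assert get.mean() == pytest.approx(1.05, rel=0.02)

    def test_lognormal_cl_geometric_sd(self):
        cl, _, _ = sample_variability(10_000, VariabilitySpec(), seed=2)
        gsd = np.exp(np.std(np.log(cl)))
        assert gsd == pytest.approx(1.3, rel=0.03)

    def test_fixed_spec_has_zero_variance(self):
        cl, get, sitt = sample_variability(100, fixed_variability(), seed=3)
        assert np.ptp(cl) == 0 and np.ptp(get) == 0 and np.ptp(sitt) == 0

    def test_pediatric_get_bounds_apply(self):
        _, get, _ = sample_variability(5000, VariabilitySpec(), seed=4,
                                       pediatric=True)
        assert get.max() <= 2.1
        assert get.max() > 1.9  # wider child range actually used

    def test_sitt_truncated_positive(self):
        _, _, sitt = sample_variability(10_000, VariabilitySpec(), seed=5)
        assert sitt.min() > 0
        assert sitt.mean() == pytest.approx(4.0, rel=0.03)

    def test_alternative_set_weibull_mean(self):
        from math import gamma

        _, _, sitt = sample_variability(20_000, alternative_variability(), seed=6)
        expected = 4.04 * gamma(1 + 1 / 2.92)
        assert sitt.mean() == pytest.approx(expected, rel=0.03)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            VariabilitySpec(get_distribution=("uniform", 2.0, 1.0))
        with pytest.raises(ValueError):
            VariabilitySpec(cl_distribution=("mystery", 1.0))


class TestAdultPopulation:
    def test_seed_determinism(self, sotalol_a, calibrated_absorption):
        arm = AdultStudyArm(dose_mg=160.0, route="oral")
        kw = dict(n=6, drug=sotalol_a,
                  absorption_settings=calibrated_absorption, seed=11)
        a = simulate_adult_population(arm, **kw)
        b = simulate_adult_population(arm, **kw)
        np.testing.assert_array_equal(a.summary_mean, b.summary_mean)

    def test_zero_variability_collapses(self, sotalol_a, calibrated_absorption):
        arm = AdultStudyArm(dose_mg=75.0, route="iv", female_fraction=0.0)
        pop = simulate_adult_population(
            arm, n=5, spec=fixed_variability(), drug=sotalol_a,
            absorption_settings=calibrated_absorption, seed=1,
            resample_anthropometrics=False)
        for i in range(pop.n_subjects):
            np.testing.assert_allclose(pop.per_subject[i], pop.summary_mean,
                                       rtol=1e-9)
        np.testing.assert_allclose(pop.summary_mean, pop.summary_median,
                                   rtol=1e-12)

    def test_population_size_insensitivity(self, sotalol_a, calibrated_absorption):
        # mean exposure from 100 vs 1000 virtual subjects agrees within 5%
        arm = AdultStudyArm(dose_mg=160.0, route="oral", female_fraction=0.2)
        small = simulate_adult_population(
            arm, n=100, drug=sotalol_a,
            absorption_settings=calibrated_absorption, seed=21)
        large = simulate_adult_population(
            arm, n=1000, drug=sotalol_a,
            absorption_settings=calibrated_absorption, seed=22)
        auc_small = np.trapezoid(small.summary_mean, small.times)
        auc_large = np.trapezoid(large.summary_mean, large.times)
        assert auc_small == pytest.approx(auc_large, rel=0.05)

    def test_percentile_ordering(self, sotalol_a, calibrated_absorption):
        arm = AdultStudyArm(dose_mg=80.0, route="oral")
        pop = simulate_adult_population(
            arm, n=20, drug=sotalol_a,
            absorption_settings=calibrated_absorption, seed=31)
        assert np.all(pop.percentile_5 <= pop.summary_median + 1e-12)
        assert np.all(pop.summary_median <= pop.percentile_95 + 1e-12)
        assert pop.comparator == "mean"


@pytest.fixture(scope="module")
def neonate():
    return ChildRecord(subject_id="n1", age=11 / 365.25, sex="male",
                       body_weight=3.8, height=52.0,
                       dose_mg_per_kg_day=3.0)


class TestVirtualTwins:
    def test_median_is_the_comparator(self, neonate, sotalol_a,
                                      calibrated_absorption):
        twins = simulate_virtual_twins(
            neonate, n=5, drug=sotalol_a,
            absorption_settings=calibrated_absorption, seed=41)
        assert twins.comparator == "median"
        np.testing.assert_array_equal(twins.comparator_curve,
                                      twins.summary_median)

    def test_twins_inherit_neonatal_maturation(self, neonate):
        # every resampled twin's per-kg clearance sits below the adult value
        rng = np.random.default_rng(3)
        for _ in range(50):
            demo = physiology.sample_demographics(neonate.age, neonate.sex, rng)
            prof = physiology.scale_profile_to_age(demo)
            cl = ontogeny.scale_clearance(
                ontogeny.DEFAULT_CLEARANCE_MODEL, demo, prof)
            assert cl / demo.body_weight < 0.1125

    def test_zero_variability_twins_collapse_to_child(self, neonate, sotalol_a,
                                                      calibrated_absorption):
        twins = simulate_virtual_twins(
            neonate, n=3, spec=fixed_variability(), drug=sotalol_a,
            absorption_settings=calibrated_absorption, seed=42,
            resample_anthropometrics=False)
        times, conc = popsim.steady_state_oral_curve(
            neonate.demographics, neonate.daily_dose_mg, sotalol_a,
            calibrated_absorption)
        np.testing.assert_allclose(twins.summary_median, conc, rtol=1e-9)

    def test_steady_state_accumulation(self, sotalol_a, calibrated_absorption):
        # repeated q12h dosing accumulates relative to a single dose
        child = ChildRecord(subject_id="c", age=8.0, sex="female",
                            body_weight=26.0, height=128.0,
                            dose_mg_per_kg_day=4.0)
        times, ss = popsim.steady_state_oral_curve(
            child.demographics, child.daily_dose_mg, sotalol_a,
            calibrated_absorption)
        from sotalolpbpk import distribution
        from sotalolpbpk.pbpk_core import DoseEvent, build_model, simulate

        prof = physiology.scale_profile_to_age(child.demographics)
        kp = distribution.compute_kp_set(sotalol_a, prof)
        cl = ontogeny.scale_clearance(
            ontogeny.DEFAULT_CLEARANCE_MODEL, child.demographics, prof)
        single = simulate(
            build_model(prof, kp, sotalol_a, cl, calibrated_absorption),
            [DoseEvent("oral", child.daily_dose_mg / 2)], 12.0)
        auc_ss = np.trapezoid(ss, times)
        auc_single = np.trapezoid(single.plasma_concentration, single.times)
        assert auc_ss > auc_single * 1.05
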
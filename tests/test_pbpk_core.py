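import numpy as np
import pytest

from sotalolpbpk import distribution, ontogeny, physiology
from sotalolpbpk.distribution import KpSet
from sotalolpbpk.pbpk_core import (
    DoseEvent,
    auc_to_infinity,
    build_model,
    simulate,
)
from sotalolpbpk.physiology import ORGANS


@pytest.fixture(scope="module")
def neonate_setup(sotalol_a):
    demo = physiology.Demographics(age=11 / 365.25, sex="male",
                                   body_weight=3.8, height=52.0)
    prof = physiology.scale_profile_to_age(demo)
    kp = distribution.compute_kp_set(sotalol_a, prof)
    cl = ontogeny.scale_clearance(ontogeny.DEFAULT_CLEARANCE_MODEL, demo, prof)
    return prof, kp, cl


class TestModelConstruction:
    def test_constructor_contract(self, adult_male, kpset_a, sotalol_a,
                                  calibrated_absorption):
        m = build_model(adult_male, kpset_a, sotalol_a, 7.875,
                        calibrated_absorption)
        labels = m.state_labels
        for organ in ORGANS:
            assert organ in labels
        assert "arterial" in labels and "venous" in labels
        assert "stomach" in labels and "gut_lumen_1" in labels

    def test_zero_clearance_conserves_dose(self, adult_male, kpset_a, sotalol_a):
        m = build_model(adult_male, kpset_a, sotalol_a, 0.0)
        res = simulate(m, [DoseEvent("iv", 75.0)], 48.0)
        body = sum(a[-1] for a in res.compartment_amounts.values())
        assert body == pytest.approx(75.0, rel=1e-9)

    def test_negative_clearance_rejected(self, adult_male, kpset_a, sotalol_a):
        with pytest.raises(ValueError):
            build_model(adult_male, kpset_a, sotalol_a, -1.0)

    def test_missing_organ_named(self, adult_male, sotalol_a, kpset_a):
        kp = dict(kpset_a.kp)
        kp.pop("spleen")
        broken = KpSet(kp=kp, kp_blood_cells=kpset_a.kp_blood_cells,
                       acidic_phospholipid_affinity=0.0)
        with pytest.raises(ValueError, match="spleen"):
            build_model(adult_male, broken, sotalol_a, 7.875)


class TestSimulation:
    def test_iv_clearance_recovery(self, adult_male, kpset_a, sotalol_a):
        m = build_model(adult_male, kpset_a, sotalol_a, 7.875)
        res = simulate(m, [DoseEvent("iv", 75.0)], 120.0, output_step=0.1)
        cl_per_kg = 75.0 / auc_to_infinity(res) / 70.0
        assert cl_per_kg == pytest.approx(0.1125, rel=0.02)

    def test_integrators_agree(self, adult_male, kpset_a, sotalol_a,
                               calibrated_absorption):
        m = build_model(adult_male, kpset_a, sotalol_a, 7.875,
                        calibrated_absorption)
        doses = [DoseEvent("oral", 160.0)]
        a = simulate(m, doses, 24.0, method="expm")
        b = simulate(m, doses, 24.0, method="lsoda")
        scale = a.plasma_concentration.max()
        assert np.max(np.abs(a.plasma_concentration
                             - b.plasma_concentration)) / scale < 1e-6

    def test_tolerance_refinement_stable(self, adult_male, kpset_a, sotalol_a):
        m = build_model(adult_male, kpset_a, sotalol_a, 7.875)
        doses = [DoseEvent("iv", 75.0)]
        coarse = simulate(m, doses, 24.0, method="lsoda", rtol=1e-6, atol=1e-8)
        fine = simulate(m, doses, 24.0, method="lsoda", rtol=5e-7, atol=5e-9)
        auc_c = np.trapezoid(coarse.plasma_concentration, coarse.times)
        auc_f = np.trapezoid(fine.plasma_concentration, fine.times)
        assert abs(auc_c - auc_f) / auc_f < 1e-3

    def test_closed_system_equilibrium(self, adult_male, sotalol_a):
        # all Kp = 1, B/P forced to 1, no clearance: the system relaxes to a
        # uniform concentration dose / (total distribution volume)
        import dataclasses

        drug = dataclasses.replace(sotalol_a, blood_plasma_ratio=1.0)
        kp = KpSet(kp={o: 1.0 for o in ORGANS}, kp_blood_cells=1.0,
                   acidic_phospholipid_affinity=0.0)
        m = build_model(adult_male, kp, drug, 0.0)
        res = simulate(m, [DoseEvent("iv", 70.0)], 200.0, output_step=0.5)
        v_total = sum(adult_male.organ_volumes.values()) + adult_male.blood_volume
        tail = res.plasma_concentration[-20:]
        assert tail[-1] == pytest.approx(70.0 / v_total, rel=1e-6)
        assert np.ptp(tail) / tail[-1] < 1e-9  # flat

    def test_infusion_mass_balance_and_shape(self, adult_male, kpset_a, sotalol_a):
        m = build_model(adult_male, kpset_a, sotalol_a, 7.875)
        res = simulate(m, [DoseEvent("iv", 75.0, infusion_duration=1.0)], 24.0)
        assert res.mass_balance_error() < 1e-6
        cmax_t = res.times[np.argmax(res.plasma_concentration)]
        assert cmax_t == pytest.approx(1.0, abs=0.1)  # peak at end of infusion

    def test_t_end_validation(self, adult_male, kpset_a, sotalol_a):
        m = build_model(adult_male, kpset_a, sotalol_a, 7.875)
        with pytest.raises(ValueError):
            simulate(m, [DoseEvent("iv", 75.0, start_time=30.0)], 24.0)

    def test_oral_requires_absorption(self, adult_male, kpset_a, sotalol_a):
        m = build_model(adult_male, kpset_a, sotalol_a, 7.875)
        with pytest.raises(ValueError, match="absorption"):
            simulate(m, [DoseEvent("oral", 80.0)], 24.0)


class TestConservationLaws:
    def test_mass_balance_across_scenarios(self, adult_male, kpset_a, sotalol_a,
                                           calibrated_absorption, neonate_setup):
        runs = []
        m_iv = build_model(adult_male, kpset_a, sotalol_a, 7.875)
        runs.append(simulate(m_iv, [DoseEvent("iv", 75.0)], 48.0))
        m_oral = build_model(adult_male, kpset_a, sotalol_a, 7.875,
                             calibrated_absorption)
        runs.append(simulate(m_oral, [DoseEvent("oral", 160.0)], 48.0))
        prof, kp, cl = neonate_setup
        m_neo = build_model(prof, kp, sotalol_a, cl, calibrated_absorption)
        runs.append(simulate(m_neo, [DoseEvent("oral", 7.6)], 48.0))
        for res in runs:
            assert res.mass_balance_error() <= 1e-6

    def test_dose_linearity(self, adult_male, kpset_a, sotalol_a,
                            calibrated_absorption):
        m = build_model(adult_male, kpset_a, sotalol_a, 7.875,
                        calibrated_absorption)
        lo = simulate(m, [DoseEvent("oral", 80.0)], 24.0)
        hi = simulate(m, [DoseEvent("oral", 160.0)], 24.0)
        scale = hi.plasma_concentration.max()
        dev = np.abs(2.0 * lo.plasma_concentration - hi.plasma_concentration)
        assert np.max(dev) / scale < 1e-6

    def test_superposition(self, adult_male, kpset_a, sotalol_a,
                           calibrated_absorption):
        m = build_model(adult_male, kpset_a, sotalol_a, 7.875,
                        calibrated_absorption)
        two = simulate(m, [DoseEvent("oral", 80.0, 0.0),
                           DoseEvent("oral", 80.0, 12.0)], 36.0)
        one = simulate(m, [DoseEvent("oral", 80.0, 0.0)], 36.0)
        shifted = np.interp(two.times - 12.0, one.times,
                            one.plasma_concentration, left=0.0)
        summed = np.interp(two.times, one.times, one.plasma_concentration) + shifted
        scale = two.plasma_concentration.max()
        assert np.max(np.abs(summed - two.plasma_concentration)) / scale < 1e-6
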
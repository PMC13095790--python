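"""Compartmental Monte Carlo blood dosimetry: closed forms and invariants."""

import numpy as np
import pytest

import lymphodose as ld
from lymphodose.errors import ValidationError


@pytest.fixture(scope="module")
def two_comp_flow():
    return ld.BloodFlowModel((
        ld.Compartment("a", 0.3, 5.0),
        ld.Compartment("b", 0.7, 5.0),
    ))


UNIT_DVH = ld.DifferentialDVH([1.0], [1.0])


class TestFlowModel:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            ld.BloodFlowModel((ld.Compartment("a", 0.5, 1.0),))

    def test_stationary_occupancy_weights_by_transit(self):
        flow = ld.BloodFlowModel((
            ld.Compartment("fast", 0.5, 1.0),
            ld.Compartment("slow", 0.5, 3.0),
        ))
        np.testing.assert_allclose(flow.stationary_occupancy(), [0.25, 0.75])

    def test_packaged_thoracic_model_is_valid(self):
        flow = ld.default_flow_model()
        assert "remainder" in flow.names
        assert flow.blood_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert flow.transit_times.sum() == pytest.approx(60.0)


class TestClosedForms:
    def test_zero_dose_everywhere_gives_point_mass_at_zero(self, two_comp_flow):
        res = ld.simulate_blood_dvh({}, two_comp_flow,
                                    ld.DeliverySchedule(3, 60.0),
                                    n_particles=200, seed=0)
        assert res.mean_blood_dose == 0.0
        np.testing.assert_allclose(res.blood_dvh.doses, [0.0])
        np.testing.assert_allclose(res.blood_dvh.fractions, [1.0])

    def test_single_compartment_uniform_dose_exact(self):
        # particle never leaves: dose = n_fractions * d exactly, zero variance
        flow = ld.BloodFlowModel((ld.Compartment("lungs", 1.0, 10.0),))
        res = ld.simulate_blood_dvh({"lungs": ld.DifferentialDVH([2.0], [1.0])},
                                    flow, ld.DeliverySchedule(5, 100.0),
                                    n_particles=1000, seed=3)
        np.testing.assert_allclose(res.particle_doses, 10.0, rtol=1e-12)

    def test_stationary_occupancy_two_compartments(self, two_comp_flow):
        # unit dose in compartment a: mean dose estimates time share in a
        n = 50_000
        res = ld.simulate_blood_dvh({"a": UNIT_DVH}, two_comp_flow,
                                    ld.DeliverySchedule(1, 500.0),
                                    n_particles=n, seed=7)
        mc_se = res.particle_doses.std() / np.sqrt(n)
        assert abs(res.mean_blood_dose - 0.3) < 3 * mc_se

    def test_mean_matches_occupancy_closed_form_three_compartments(self):
        flow = ld.BloodFlowModel((
            ld.Compartment("a", 0.2, 2.0),
            ld.Compartment("b", 0.3, 6.0),
            ld.Compartment("c", 0.5, 4.0),
        ))
        organ_dvhs = {"a": ld.DifferentialDVH([1.0], [1.0]),
                      "b": ld.DifferentialDVH([0.5, 1.5], [0.5, 0.5])}
        schedule = ld.DeliverySchedule(2, 400.0)
        n = 40_000
        res = ld.simulate_blood_dvh(organ_dvhs, flow, schedule,
                                    n_particles=n, seed=11)
        occ = flow.stationary_occupancy()
        expected = schedule.n_fractions * (occ[0] * 1.0 + occ[1] * 1.0)
        mc_se = res.particle_doses.std() / np.sqrt(n)
        assert abs(res.mean_blood_dose - expected) < 3 * mc_se


class TestInvariants:
    def test_volume_conservation(self, two_comp_flow):
        res = ld.simulate_blood_dvh({"a": UNIT_DVH}, two_comp_flow,
                                    ld.DeliverySchedule(3, 60.0),
                                    n_particles=2000, seed=1)
        assert res.blood_dvh.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mean_dose_consistent_with_dvh(self, two_comp_flow):
        res = ld.simulate_blood_dvh({"a": UNIT_DVH}, two_comp_flow,
                                    ld.DeliverySchedule(5, 120.0),
                                    n_particles=5000, seed=2, bin_width=0.01)
        assert ld.mean_dose(res.blood_dvh) == pytest.approx(
            res.mean_blood_dose, abs=0.01)

    def test_mean_dose_monotone_in_fractions(self, two_comp_flow):
        means = [
            ld.simulate_blood_dvh({"a": UNIT_DVH}, two_comp_flow,
                                  ld.DeliverySchedule(f, 60.0),
                                  n_particles=3000, seed=5).mean_blood_dose
            for f in (1, 3, 6)
        ]
        assert means[0] < means[1] < means[2]

    def test_dose_scaling_exact(self, two_comp_flow):
        sched = ld.DeliverySchedule(2, 50.0)
        base = ld.simulate_blood_dvh({"a": UNIT_DVH}, two_comp_flow, sched,
                                     n_particles=500, seed=11)
        doubled = ld.simulate_blood_dvh({"a": UNIT_DVH.scaled(2.0)},
                                        two_comp_flow, sched,
                                        n_particles=500, seed=11)
        # power-of-two scale: bit-identical; general scale: 1-ulp float noise
        assert np.array_equal(doubled.particle_doses, 2 * base.particle_doses)
        tripled = ld.simulate_blood_dvh({"a": UNIT_DVH.scaled(3.0)},
                                        two_comp_flow, sched,
                                        n_particles=500, seed=11)
        np.testing.assert_allclose(tripled.particle_doses,
                                   3 * base.particle_doses, rtol=1e-12)

    def test_seed_reproducibility(self, two_comp_flow):
        kw = dict(n_particles=800, seed=13)
        r1 = ld.simulate_blood_dvh({"a": UNIT_DVH}, two_comp_flow,
                                   ld.DeliverySchedule(2, 50.0), **kw)
        r2 = ld.simulate_blood_dvh({"a": UNIT_DVH}, two_comp_flow,
                                   ld.DeliverySchedule(2, 50.0), **kw)
        assert np.array_equal(r1.particle_doses, r2.particle_doses)

    def test_unknown_organ_rejected(self, two_comp_flow):
        with pytest.raises(ValidationError):
            ld.simulate_blood_dvh({"nope": UNIT_DVH}, two_comp_flow,
                                  ld.DeliverySchedule(1, 10.0),
                                  n_particles=10, seed=0)

    @pytest.mark.parametrize("bad", [
        dict(n_particles=0), dict(time_step=0.0), dict(bin_width=-1.0),
    ])
    def test_nonpositive_settings_rejected(self, two_comp_flow, bad):
        kw = dict(n_particles=10, time_step=0.1, bin_width=0.05, seed=0)
        kw.update(bad)
        with pytest.raises(ValidationError):
            ld.simulate_blood_dvh({"a": UNIT_DVH}, two_comp_flow,
                                  ld.DeliverySchedule(1, 10.0), **kw)


class TestBloodMetrics:
    def test_point_mass_metrics(self):
        flow = ld.BloodFlowModel((ld.Compartment("lungs", 1.0, 10.0),))
        res = ld.simulate_blood_dvh({"lungs": ld.DifferentialDVH([2.0], [1.0])},
                                    flow, ld.DeliverySchedule(2, 100.0),
                                    n_particles=500, seed=3)
        m = ld.blood_metrics(res, a=8.0)
        for n_pct in m["d_percent_gy"]:
            assert m["d_percent_gy"][n_pct] == pytest.approx(4.0, abs=0.05)
        assert m["v_gy_percent"][3.0] == pytest.approx(100.0)
        assert m["v_gy_percent"][3.5] == pytest.approx(100.0)

    def test_zero_dose_metrics_all_zero(self, two_comp_flow):
        res = ld.simulate_blood_dvh({}, two_comp_flow,
                                    ld.DeliverySchedule(1, 10.0),
                                    n_particles=100, seed=0)
        m = ld.blood_metrics(res, a=2.0)
        assert m["mean_gy"] == 0.0 and m["geud_gy"] == 0.0
        assert all(v == 0.0 for v in m["v_gy_percent"].values())

    def test_metrics_match_bruteforce_histogram(self, two_comp_flow):
        res = ld.simulate_blood_dvh({"a": UNIT_DVH.scaled(4.0)}, two_comp_flow,
                                    ld.DeliverySchedule(4, 80.0),
                                    n_particles=4000, seed=9, bin_width=0.02)
        m = ld.blood_metrics(res, a=2.0)
        doses = res.particle_doses
        # recompute V_2Gy straight from the raw particle doses (one bin slack)
        brute_v2 = 100.0 * np.mean(doses > 2.0)
        assert m["v_gy_percent"][2.0] == pytest.approx(brute_v2, abs=1.5)
        brute_d50 = np.quantile(doses, 0.5)
        assert m["d_percent_gy"][50] == pytest.approx(brute_d50, abs=0.05)
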
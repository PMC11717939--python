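"""Herd demography: transitions, conservation, decay, weights, production."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mclsim.herd import (DemographyParams, HerdClass, HerdState, N_CLASSES,
                         class_transition_rate, manure_nitrogen,
                         meat_production, methane_emission, milk_production,
                         projection_matrix, step_demography,
                         update_live_weights)

ZERO_RATES = DemographyParams(
    parturition_annual=0.0, base_mortality_annual=(0.0,) * 6,
    starvation_mortality_max_annual=(0.0,) * 6,
    survival_for_gamma=(1e-12,) * 4, offtake_annual=(0.0,) * 6)


class TestTransitionRate:
    @pytest.mark.parametrize("duration,survival,expected", [
        (1, 1.0, 1.0),
        (365, 1.0, 1.0 / 365),
        (730, 0.9, 0.9 / 730),
    ])
    def test_gamma_values(self, duration, survival, expected):
        assert class_transition_rate(duration, survival) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            class_transition_rate(0, 0.9)
        with pytest.raises(ValueError):
            class_transition_rate(365, 0.0)


class TestStepDemography:
    def test_all_rates_zero_is_identity(self):
        herd = HerdState(np.full(N_CLASSES, 10.0))
        out, flows = step_demography(herd, ZERO_RATES, 1.0)
        np.testing.assert_allclose(out.count, herd.count, atol=1e-9)
        for f in (flows.births, flows.deaths, flows.offtake):
            assert f.sum() == pytest.approx(0.0, abs=1e-9)

    def test_birth_arithmetic(self):
        counts = np.zeros(N_CLASSES)
        counts[HerdClass.ADULTS_FEMALE] = 50.0
        params = DemographyParams(
            parturition_annual=0.73, prolification=1.0, sex_ratio_male=0.5,
            base_mortality_annual=(0.0,) * 6,
            starvation_mortality_max_annual=(0.0,) * 6,
            survival_for_gamma=(1e-12,) * 4, offtake_annual=(0.0,) * 6)
        _, flows = step_demography(HerdState(counts), params, 1.0)
        assert flows.births[HerdClass.JUVENILES_MALE] == pytest.approx(0.05)
        assert flows.births[HerdClass.JUVENILES_FEMALE] == pytest.approx(0.05)

    def test_constant_mortality_geometric_decay(self):
        """A single class under 0.365 yr-1 mortality: N = N0 (1 - 0.001)^t."""
        counts = np.zeros(N_CLASSES)
        counts[HerdClass.ADULTS_MALE] = 100.0
        params = DemographyParams(
            parturition_annual=0.0,
            base_mortality_annual=(0.365,) * 6,
            starvation_mortality_max_annual=(0.0,) * 6,
            survival_for_gamma=(1e-12,) * 4, offtake_annual=(0.0,) * 6)
        herd = HerdState(counts)
        herd2, _ = step_demography(herd, params, 1.0)
        assert herd2.count[HerdClass.ADULTS_MALE] == pytest.approx(99.9, abs=1e-9)
        for _ in range(364):
            herd2, _ = step_demography(herd2, params, 1.0)
        expected = 100.0 * (1 - 0.001) ** 365
        assert herd2.count[HerdClass.ADULTS_MALE] == pytest.approx(
            expected, abs=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
    def test_bookkeeping_closes_each_day(self, seed, stress):
        rng = np.random.default_rng(seed)
        params = DemographyParams(
            parturition_annual=float(rng.uniform(0, 1.5)),
            prolification=float(rng.uniform(0.8, 2.0)),
            base_mortality_annual=tuple(rng.uniform(0, 0.4, 6)),
            starvation_mortality_max_annual=tuple(rng.uniform(0, 0.8, 6)),
            survival_for_gamma=tuple(rng.uniform(0.5, 1.0, 4)),
            offtake_annual=tuple(rng.uniform(0, 0.3, 6)),
            intake_annual=tuple(rng.uniform(0, 0.1, 6)))
        herd = HerdState(rng.uniform(0, 50, N_CLASSES))
        for _ in range(30):
            herd2, flows = step_demography(herd, params, stress)
            delta = (flows.births - flows.deaths + flows.promotions_in
                     - flows.promotions_out - flows.offtake + flows.intake)
            np.testing.assert_allclose(herd2.count - herd.count, delta,
                                       atol=1e-9)
            assert (herd2.count >= 0).all()
            herd = herd2

    def test_overdraw_empties_class_to_zero(self):
        counts = np.zeros(N_CLASSES)
        counts[HerdClass.ADULTS_MALE] = 5.0
        params = DemographyParams(
            parturition_annual=0.0,
            base_mortality_annual=(400.0,) * 6,  # > 365: daily rate > 1
            starvation_mortality_max_annual=(0.0,) * 6,
            survival_for_gamma=(1e-12,) * 4, offtake_annual=(0.0,) * 6)
        herd2, flows = step_demography(HerdState(counts), params, 1.0)
        assert herd2.count[HerdClass.ADULTS_MALE] == 0.0
        assert flows.deaths[HerdClass.ADULTS_MALE] == pytest.approx(5.0)


class TestStationarity:
    def test_proportions_converge_to_dominant_eigenvector(self):
        """Simulated class proportions match matrix-power stationary structure."""
        params = DemographyParams()
        a = projection_matrix(params, energy_stress=1.0)
        power = np.linalg.matrix_power(a, 8000)
        v = power @ np.full(N_CLASSES, 1.0)
        v_prop = v / v.sum()

        herd = HerdState(np.full(N_CLASSES, 10.0))
        for _ in range(8000):
            herd, _ = step_demography(herd, params, 1.0)
        sim_prop = herd.count / herd.count.sum()
        assert np.max(np.abs(sim_prop - v_prop)) < 1e-6

    def test_projection_matrix_matches_one_step(self):
        params = DemographyParams()
        herd = HerdState(np.array([3.0, 7.0, 2.0, 9.0, 4.0, 11.0]))
        out, _ = step_demography(herd, params, 0.7)
        expected = projection_matrix(params, 0.7) @ herd.count
        np.testing.assert_allclose(out.count, expected, atol=1e-12)


class TestWeightsAndProduction:
    def test_weight_update_limits_and_blend(self):
        params = DemographyParams(weight_gain_max=(0.2,) * 6,
                                  weight_loss_max=(0.4,) * 6)
        herd = HerdState(np.ones(N_CLASSES))
        up = update_live_weights(herd, params, 1.0)
        np.testing.assert_allclose(up.mean_weight, herd.mean_weight + 0.2)
        down = update_live_weights(herd, params, 0.0)
        np.testing.assert_allclose(down.mean_weight, herd.mean_weight - 0.4)
        mid = update_live_weights(herd, params, 0.5)
        np.testing.assert_allclose(mid.mean_weight, herd.mean_weight - 0.1)

    def test_weight_floor(self):
        params = DemographyParams(weight_loss_max=(500.0,) * 6)
        herd = HerdState(np.ones(N_CLASSES))
        out = update_live_weights(herd, params, 0.0)
        np.testing.assert_allclose(out.mean_weight,
                                   np.asarray(params.min_viable_weight))

    def test_total_live_weight_identity(self):
        herd = HerdState(np.array([1.0, 2, 3, 4, 5, 6]))
        assert herd.total_live_weight == pytest.approx(
            float((herd.count * herd.mean_weight).sum()))

    def test_meat_production(self):
        assert meat_production(0.0, 0.5) == 0.0
        assert meat_production(2000.0, 0.5) == 1000.0
        assert meat_production(1.5 * 300.0, 0.5) == pytest.approx(225.0)
        with pytest.raises(ValueError):
            meat_production(100.0, 1.5)

    def test_milk_production(self):
        counts = np.zeros(N_CLASSES)
        counts[HerdClass.ADULTS_FEMALE] = 10.0
        params = DemographyParams(lactating_fraction=0.5, milk_yield_potential=2.0)
        herd = HerdState(counts)
        assert milk_production(herd, params, 1.0) == pytest.approx(10.0)
        assert milk_production(herd, params, 0.0) == 0.0
        assert milk_production(HerdState(np.zeros(N_CLASSES)), params, 1.0) == 0.0

    def test_methane_linear(self):
        assert methane_emission(0.0, 0.021) == 0.0
        assert methane_emission(10.0, 0.021) == pytest.approx(0.21)
        assert methane_emission(20.0, 0.021) == pytest.approx(
            2 * methane_emission(10.0, 0.021))

    def test_manure_routing(self):
        crop_n, grass_n = manure_nitrogen(0.1, 0.8, cropland_share=1.0)
        assert crop_n == pytest.approx(0.08) and grass_n == 0.0
        crop_n, grass_n = manure_nitrogen(0.1, 0.8, cropland_share=0.25)
        assert crop_n + grass_n == pytest.approx(0.08)
        assert manure_nitrogen(0.0, 0.8) == (0.0, 0.0)
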
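import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wfcrop import soil_water as sw
from wfcrop.soil_water import (BLUE_CR, BLUE_I, GREEN, OverfillError,
                               SoilProfile, SoilState, capillary_rise,
                               curve_number_runoff, drain,
                               extract_evapotranspiration,
                               interpolate_monthly_to_daily, mix_inflow,
                               root_weights, root_zone_depletion,
                               step_water_balance)

# pinned before the build: S = 254*(100/75-1), runoff = (40-0.2S)^2/(40+0.8S)
PINNED_RUNOFF_CN75_P40 = 4.93877887788779


class TestCurveNumberRunoff:
    def test_pinned_hand_evaluation(self):
        assert curve_number_runoff(40.0, 75.0) == pytest.approx(
            PINNED_RUNOFF_CN75_P40, abs=1e-9)

    def test_no_rain_no_runoff(self):
        assert curve_number_runoff(0.0, 75.0) == 0.0

    def test_zero_below_initial_abstraction(self):
        s = 254.0 * (100.0 / 75.0 - 1.0)
        assert curve_number_runoff(0.2 * s, 75.0) == 0.0
        assert curve_number_runoff(0.2 * s - 0.01, 75.0) == 0.0

    def test_rice_bund_suppresses_runoff(self):
        # 300 mm bunds: 100 mm ponded + 50 mm rain stays in the paddy
        assert curve_number_runoff(50.0, 85.0, bund_height_mm=300.0,
                                   ponded_mm=100.0) == 0.0

    def test_bund_spills_only_excess(self):
        assert curve_number_runoff(80.0, 85.0, bund_height_mm=300.0,
                                   ponded_mm=280.0) == pytest.approx(60.0)

    def test_invalid_curve_number(self):
        with pytest.raises(ValueError):
            curve_number_runoff(10.0, 0.0)
        with pytest.raises(ValueError):
            curve_number_runoff(10.0, 100.0)

    @given(st.floats(0.0, 500.0), st.floats(30.0, 95.0))
    def test_runoff_below_precip(self, p, cn):
        r = curve_number_runoff(p, cn)
        assert 0.0 <= r <= p + 1e-12


class TestMixInflow:
    def test_single_source_into_empty(self, deep_profile, loam):
        state = SoilState(w=np.zeros(deep_profile.n),
                          frac=np.zeros((deep_profile.n, 3)))
        out = mix_inflow(state, 0, 10.0, GREEN)
        assert out.w[0] == 10.0
        assert out.frac[0].tolist() == [1.0, 0.0, 0.0]

    def test_two_source_mass_balance(self, deep_profile):
        state = SoilState(w=np.zeros(deep_profile.n),
                          frac=np.zeros((deep_profile.n, 3)))
        state = mix_inflow(state, 2, 50.0, GREEN)
        state = mix_inflow(state, 2, 50.0, BLUE_I)
        assert state.w[2] == 100.0
        assert state.frac[2, GREEN] == pytest.approx(0.5)
        assert state.frac[2, BLUE_I] == pytest.approx(0.5)

    def test_zero_inflow_is_identity(self, fc_state):
        out = mix_inflow(fc_state, 3, 0.0, BLUE_CR)
        np.testing.assert_array_equal(out.w, fc_state.w)
        np.testing.assert_array_equal(out.frac, fc_state.frac)

    def test_overfill_signalled_not_clipped(self, deep_profile, loam):
        state = SoilState.at_content(deep_profile, loam,
                                     theta=loam.theta_sat)
        cap = deep_profile.capacity_mm(loam.theta_sat)[0]
        with pytest.raises(OverfillError) as err:
            mix_inflow(state, 0, 25.0, GREEN, capacity_mm=cap)
        assert err.value.excess_mm == pytest.approx(25.0)

    @given(st.floats(0.0, 200.0), st.sampled_from([GREEN, BLUE_I, BLUE_CR]))
    def test_fractions_stay_normalised(self, amount, colour):
        profile = SoilProfile.deep()
        state = SoilState(w=np.full(profile.n, 30.0),
                          frac=np.tile([0.5, 0.3, 0.2], (profile.n, 1)))
        out = mix_inflow(state, 4, amount, colour)
        assert out.frac[4].sum() == pytest.approx(1.0, abs=1e-12)
        assert out.w[4] == pytest.approx(30.0 + amount)


class TestDrain:
    def test_at_field_capacity_no_drainage(self, fc_state, loam, deep_profile):
        out, dp = drain(fc_state, loam, deep_profile)
        np.testing.assert_allclose(out.w, fc_state.w)
        assert dp.sum() == 0.0

    def test_single_excess_drains_at_tau(self, deep_profile, loam):
        state = SoilState.at_content(deep_profile, loam)
        state.w[2] += 10.0  # 10 mm above field capacity, tau = 0.5
        out, dp = drain(state, loam, deep_profile)
        fc2 = deep_profile.capacity_mm(loam.theta_fc)[2]
        assert out.w[2] == pytest.approx(fc2 + 5.0)
        assert out.w[3] == pytest.approx(
            deep_profile.capacity_mm(loam.theta_fc)[3] + 5.0 * (1 - loam.tau))

    def test_colour_conservation(self, deep_profile, loam):
        state = SoilState.at_content(deep_profile, loam)
        state.w += 15.0
        state.frac[:] = [0.2, 0.5, 0.3]
        before = state.colour_storage()
        out, dp = drain(state, loam, deep_profile)
        np.testing.assert_allclose(out.colour_storage() + dp, before,
                                   atol=1e-9)

    def test_never_exceeds_saturation(self, deep_profile, loam):
        state = SoilState.at_content(deep_profile, loam,
                                     theta=loam.theta_sat)
        out, _ = drain(state, loam, deep_profile)
        sat = deep_profile.capacity_mm(loam.theta_sat)
        assert np.all(out.w <= sat + 1e-9)


class TestCapillaryRise:
    def test_irrigated_non_rice_gets_nothing(self, deep_profile, loam):
        dry = SoilState.at_content(deep_profile, loam, theta=loam.theta_wp)
        _, flux = capillary_rise(dry, 1.0, "irrigated", False, loam,
                                 deep_profile)
        assert flux == 0.0

    def test_zero_below_cutoff_depth(self, deep_profile, loam):
        dry = SoilState.at_content(deep_profile, loam, theta=loam.theta_wp)
        _, flux = capillary_rise(dry, 5.0, "rainfed", False, loam,
                                 deep_profile)
        assert flux == 0.0

    def test_surfacing_water_table_drained_to_1m(self, deep_profile, loam):
        dry = SoilState.at_content(deep_profile, loam, theta=loam.theta_wp)
        _, flux0 = capillary_rise(dry, 0.0, "rainfed", False, loam,
                                  deep_profile)
        _, flux1 = capillary_rise(dry, 1.0, "rainfed", False, loam,
                                  deep_profile)
        assert flux0 == pytest.approx(flux1)
        assert flux0 > 0.0

    def test_flux_decreases_with_depth(self, deep_profile, loam):
        dry = SoilState.at_content(deep_profile, loam, theta=loam.theta_wp)
        fluxes = [capillary_rise(dry, d, "rainfed", False, loam,
                                 deep_profile)[1] for d in (1.0, 2.0, 3.0, 3.9)]
        assert np.all(np.diff(fluxes) < 0)

    def test_wet_bottom_gates_flux(self, fc_state, loam, deep_profile):
        _, flux = capillary_rise(fc_state, 1.0, "rainfed", False, loam,
                                 deep_profile)
        assert flux == 0.0

    def test_irrigated_rice_allowed(self, deep_profile, loam):
        dry = SoilState.at_content(deep_profile, loam, theta=loam.theta_wp)
        _, flux = capillary_rise(dry, 1.5, "irrigated", True, loam,
                                 deep_profile)
        assert flux > 0.0

    def test_negative_depth_rejected(self, fc_state, loam, deep_profile):
        with pytest.raises(ValueError):
            capillary_rise(fc_state, -1.0, "rainfed", False, loam,
                           deep_profile)


class TestExtraction:
    def test_all_green_state_yields_no_blue_et(self, fc_state, loam,
                                               deep_profile):
        w = root_weights(deep_profile, 1.0)
        _, evap, transp, _ = extract_evapotranspiration(
            fc_state, 3.0, 4.0, w, loam, deep_profile)
        assert evap[BLUE_I] == evap[BLUE_CR] == 0.0
        assert transp[BLUE_I] == transp[BLUE_CR] == 0.0
        assert evap[GREEN] + transp[GREEN] > 0.0

    def test_wilting_point_limits_evaporation(self, deep_profile, loam):
        state = SoilState.at_content(deep_profile, loam,
                                     theta=0.5 * loam.theta_wp)
        w = root_weights(deep_profile, 1.0)
        out, evap, transp, unmet = extract_evapotranspiration(
            state, 5.0, 5.0, w, loam, deep_profile)
        assert evap.sum() == pytest.approx(0.0, abs=1e-12)
        assert transp.sum() == pytest.approx(0.0, abs=1e-12)
        assert unmet == pytest.approx(10.0)

    def test_blue_fraction_of_transpiration(self, deep_profile, loam):
        state = SoilState.at_content(deep_profile, loam)
        state.frac[:] = [0.7, 0.3, 0.0]  # 30 % irrigation water everywhere
        w = root_weights(deep_profile, 2.0)
        _, _, transp, _ = extract_evapotranspiration(
            state, 0.0, 10.0, w, loam, deep_profile)
        assert transp.sum() == pytest.approx(10.0)
        assert transp[BLUE_I] == pytest.approx(3.0, abs=1e-9)

    def test_two_stage_evaporation_slows_down(self, deep_profile, loam):
        state = SoilState.at_content(deep_profile, loam)
        w = np.zeros(deep_profile.n)
        day_totals = []
        for _ in range(8):
            state, evap, _, _ = extract_evapotranspiration(
                state, 6.0, 0.0, w, loam, deep_profile)
            day_totals.append(evap.sum())
        assert day_totals[0] == pytest.approx(6.0)  # energy-limited at first
        assert day_totals[-1] < day_totals[0]  # falling-rate stage reached
        assert all(np.diff(day_totals) <= 1e-12)


class TestStepWaterBalance:
    def test_quiescent_day_all_fluxes_zero(self, deep_profile, loam):
        state = SoilState.at_content(deep_profile, loam,
                                     theta=loam.theta_wp)
        out, fx = step_water_balance(state, 0.0, 4.0, 0.0, 0.0, 0.0, 10.0,
                                     loam, deep_profile)
        assert fx.inflow().sum() == 0.0
        assert fx.runoff_out.sum() == 0.0
        assert fx.transpiration_out.sum() == 0.0

    def test_colour_closure_random_days(self, deep_profile, loam):
        rng = np.random.default_rng(42)
        state = SoilState.at_content(deep_profile, loam)
        state.frac[:] = [0.6, 0.25, 0.15]
        for _ in range(60):
            before = state.colour_storage()
            state, fx = step_water_balance(
                state, float(rng.gamma(1.0, 8.0) * (rng.random() < 0.4)),
                float(rng.uniform(1.0, 7.0)), float(rng.uniform(0.0, 0.9)),
                float(rng.uniform(0.2, 2.5)),
                float(rng.choice([0.0, 25.0])), float(rng.uniform(0.5, 8.0)),
                loam, deep_profile, system="irrigated")
            after = state.colour_storage()
            np.testing.assert_allclose(
                before + fx.inflow() - fx.outflow(), after, atol=1e-6)

    def test_rainfed_deep_water_table_stays_green(self, deep_profile, loam):
        state = SoilState.at_content(deep_profile, loam)
        for precip in (0.0, 12.0, 0.0, 30.0, 0.0, 0.0):
            state, fx = step_water_balance(state, precip, 4.0, 0.5, 1.0,
                                           0.0, 10.0, loam, deep_profile)
            assert fx.capillary_in.sum() == 0.0
            assert fx.evaporation_out[BLUE_I] == 0.0
            assert fx.transpiration_out[BLUE_CR] == 0.0
        np.testing.assert_array_equal(state.colour_storage()[1:], [0.0, 0.0])

    def test_rice_ponding_builds_behind_bund(self, deep_profile, loam):
        state = SoilState.at_content(deep_profile, loam)
        out, fx = step_water_balance(state, 40.0, 4.0, 0.8, 0.5, 30.0, 10.0,
                                     loam, deep_profile, system="irrigated",
                                     crop_is_rice=True, bund_height_mm=300.0)
        assert fx.runoff_out.sum() == 0.0
        assert out.ponding > 0.0


class TestParcelOracleEquivalence:
    def test_fractional_tracing_matches_parcel_ledger(self, deep_profile,
                                                      loam):
        """Two years of daily forcing: the fractional implementation and a
        brute-force per-parcel ledger agree on colour storages and
        cumulative colour-split ET to 1e-6 mm."""
        from _parcel_oracle import ParcelColumn

        theta0 = loam.theta_wp + 0.5 * (loam.theta_fc - loam.theta_wp)
        state = SoilState.at_content(deep_profile, loam, theta=theta0)
        oracle = ParcelColumn(deep_profile.thicknesses, loam.theta_sat,
                              loam.theta_fc, loam.theta_wp, loam.tau,
                              loam.curve_number, loam.rew, theta0)
        rng = np.random.default_rng(3)
        cum_et = np.zeros(3)
        for d in range(730):
            precip = float(rng.gamma(0.8, 10.0)) if rng.random() < 0.35 else 0.0
            et0 = float(rng.uniform(2.0, 6.0))
            cc = 0.5 + 0.3 * np.sin(2 * np.pi * d / 365.0)
            irr = 20.0 if d % 17 == 0 else 0.0
            wt = 2.0 + 1.5 * np.sin(2 * np.pi * d / 365.0)
            state, fx = step_water_balance(state, precip, et0, cc, 1.2, irr,
                                           wt, loam, deep_profile,
                                           system="rainfed")
            cum_et += fx.evaporation_out + fx.transpiration_out
            oracle.step(precip, et0, cc, 1.2, irr, wt, system="rainfed")
        np.testing.assert_allclose(state.colour_storage(),
                                   oracle.storage_by_colour(), atol=1e-6)
        np.testing.assert_allclose(cum_et, oracle.cum_et, atol=1e-6)


class TestProfilesAndHelpers:
    def test_default_profiles_match_design(self):
        deep = SoilProfile.deep()
        assert deep.n == 8 and deep.depth == pytest.approx(3.0)
        assert np.all(deep.thicknesses >= 0.1) and np.all(deep.thicknesses <= 0.7)
        shallow = SoilProfile.shallow()
        assert shallow.n == 7 and shallow.depth == pytest.approx(2.0)

    def test_monthly_interpolation_hits_midpoints(self):
        monthly = np.arange(1.0, 13.0)
        assert interpolate_monthly_to_daily(monthly, 16) == pytest.approx(
            monthly[0], abs=0.2)
        mid_june = interpolate_monthly_to_daily(monthly, 166)
        assert mid_june == pytest.approx(6.0, abs=0.01)

    def test_root_weights_cover_root_zone_only(self, deep_profile):
        w = root_weights(deep_profile, 0.5)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w[deep_profile.tops >= 0.5] == 0.0)

    def test_depletion_zero_at_fc_full_at_wp(self, deep_profile, loam):
        fc = SoilState.at_content(deep_profile, loam)
        dr, taw = root_zone_depletion(fc, loam, deep_profile, 1.0)
        assert dr == pytest.approx(0.0, abs=1e-9)
        wp = SoilState.at_content(deep_profile, loam, theta=loam.theta_wp)
        dr2, taw2 = root_zone_depletion(wp, loam, deep_profile, 1.0)
        assert dr2 == pytest.approx(taw2)
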
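import numpy as np
import pytest

from wfcrop.crop_growth import (CO2_REFERENCE_PPM, CropCalendar,
                                NonViableCellError, StageRequirements,
                                adjust_calendar, biomass_increment,
                                calibrate_heat_units, canopy_step,
                                co2_factor, daily_gdd, rooting_depth,
                                water_stress_coefficients, yield_at_harvest)
from wfcrop.parameters import load_crop_parameters

CROPS = load_crop_parameters()


class TestDailyGDD:
    def test_plain_arithmetic(self):
        assert daily_gdd(28.0, 12.0, 8.0, 30.0) == pytest.approx(12.0)

    def test_base_temperature_identity(self):
        assert daily_gdd(8.0, 8.0, 8.0, 30.0) == 0.0

    def test_upper_cap(self):
        assert daily_gdd(40.0, 20.0, 8.0, 30.0) == pytest.approx(17.0)

    def test_cold_tmin_raised_to_base(self):
        # tmin below Tbase is clamped up before averaging
        assert daily_gdd(20.0, -5.0, 8.0, 30.0) == pytest.approx(
            (20.0 + 8.0) / 2.0 - 8.0)

    def test_never_negative(self):
        assert daily_gdd(2.0, -10.0, 8.0, 30.0) == 0.0


class TestCanopy:
    def setup_method(self):
        self.p = CROPS["maize"]
        self.reqs = self.p.stage_requirements(1500.0)

    def test_zero_before_emergence(self):
        assert canopy_step(0.0, 10.0, 5.0, self.p, self.reqs) == 0.0

    def test_starts_at_cc0_at_emergence(self):
        cc = canopy_step(0.0, self.reqs.emergence, 0.0, self.p, self.reqs)
        assert cc == pytest.approx(self.p.cc0)

    def test_unstressed_growth_matches_closed_form(self):
        # stepwise exponential growth equals CC0*exp(CGC*t) while CC<=CCx/2
        cc = self.p.cc0
        cum = self.reqs.emergence
        total = 0.0
        rng = np.random.default_rng(0)
        while True:
            d = float(rng.uniform(5.0, 15.0))
            nxt = canopy_step(cc, cum + d, d, self.p, self.reqs)
            if nxt > self.p.ccx / 2.0:
                break
            cc, cum, total = nxt, cum + d, total + d
        assert cc == pytest.approx(self.p.cc0 * np.exp(self.p.cgc * total),
                                   rel=1e-12)

    def test_never_exceeds_ccx(self):
        cc, cum = self.p.cc0, self.reqs.emergence
        for _ in range(200):
            cum += 10.0
            cc = canopy_step(cc, cum, 10.0, self.p, self.reqs)
            assert cc <= self.p.ccx + 1e-12

    def test_senescence_declines(self):
        cc = self.p.ccx
        out = canopy_step(cc, self.reqs.senescence + 10.0, 10.0, self.p,
                          self.reqs)
        assert out < cc

    def test_water_stress_slows_growth(self):
        cc0 = self.p.cc0
        cum = self.reqs.emergence + 10.0
        full = canopy_step(cc0, cum, 10.0, self.p, self.reqs, 1.0)
        stressed = canopy_step(cc0, cum, 10.0, self.p, self.reqs, 0.3)
        assert stressed < full

    def test_evergreen_holds_ccx(self):
        p = CROPS["citrus"]
        assert canopy_step(0.1, 0.0, 5.0, p, p.stage_requirements()) == p.ccx

    def test_deciduous_leafless_minimum(self):
        p = CROPS["grape"]
        reqs = p.stage_requirements()
        assert canopy_step(p.cc_min_leafless, 0.0, 5.0, p, reqs) \
            == p.cc_min_leafless

    def test_rooting_depth_grows_to_zmax(self):
        reqs = self.p.stage_requirements(1500.0)
        assert rooting_depth(0.0, self.p, reqs) == self.p.zmin
        assert rooting_depth(reqs.max_canopy, self.p, reqs) == self.p.zmax
        mid = rooting_depth(reqs.max_canopy / 2.0, self.p, reqs)
        assert self.p.zmin < mid < self.p.zmax


class TestWaterStress:
    def test_no_depletion_no_stress(self):
        ks = water_stress_coefficients(0.0, 100.0, 0.5)
        assert ks.expansion == ks.stomatal == 1.0

    def test_full_depletion_full_stress(self):
        ks = water_stress_coefficients(100.0, 100.0, 0.5)
        assert ks.expansion == ks.stomatal == 0.0

    def test_linear_interpolation_by_hand(self):
        # p_up 0.5, Dr = 0.75 TAW: stomatal Ks = (1-0.75)/(1-0.5) = 0.5
        ks = water_stress_coefficients(75.0, 100.0, 0.5)
        assert ks.stomatal == pytest.approx(0.5)

    def test_expansion_engages_before_stomatal(self):
        ks = water_stress_coefficients(45.0, 100.0, 0.5)
        assert ks.expansion < 1.0
        assert ks.stomatal == 1.0

    def test_invalid_taw(self):
        with pytest.raises(ValueError):
            water_stress_coefficients(10.0, 0.0, 0.5)


class TestBiomass:
    def test_no_transpiration_no_growth(self):
        assert biomass_increment(0.0, 5.0, 0.32) == 0.0

    def test_reference_co2_factor_is_one(self):
        assert co2_factor(CO2_REFERENCE_PPM, 0.158) == 1.0

    def test_elevated_co2_boosts_c3_more_than_c4(self):
        c3 = co2_factor(CO2_REFERENCE_PPM + 200.0, CROPS["wheat"].co2_response)
        c4 = co2_factor(CO2_REFERENCE_PPM + 200.0, CROPS["maize"].co2_response)
        assert c3 > c4 > 1.0
        assert c3 == pytest.approx(1.10, abs=0.02)
        assert c4 == pytest.approx(1.02, abs=0.01)

    def test_season_sum_identity(self):
        # summing daily increments equals WP* f_CO2 sum(Tr/ET0) exactly
        rng = np.random.default_rng(1)
        tr = rng.uniform(0.0, 5.0, 120)
        et0 = rng.uniform(2.0, 7.0, 120)
        total = sum(biomass_increment(t, e, 0.32, 400.0, 0.032)
                    for t, e in zip(tr, et0))
        expected = 0.32 * co2_factor(400.0, 0.032) * np.sum(tr / et0)
        assert total == pytest.approx(expected, rel=1e-12)


class TestYield:
    def test_unstressed_identity(self):
        p = CROPS["maize"]  # HI0 = 0.5
        assert yield_at_harvest(10.0, p) == pytest.approx(10.0 * p.hi0)

    def test_one_failed_flowering_day(self):
        p = CROPS["maize"]
        assert yield_at_harvest(10.0, p, heat_failure_days=1) == pytest.approx(
            10.0 * p.hi0 * 0.8)

    def test_total_flowering_failure_hits_floor(self):
        p = CROPS["maize"]
        y = yield_at_harvest(10.0, p, heat_failure_days=15)
        assert y == pytest.approx(10.0 * p.hi0 * 0.05)

    def test_removing_stress_never_decreases_yield(self):
        p = CROPS["wheat"]
        stressed = yield_at_harvest(8.0, p, 3, 5)
        assert yield_at_harvest(8.0, p, 0, 0) >= stressed


class _ConstWeather:
    """Sinusoidal mean-climate forcing for calibration tests."""

    def __init__(self, years=4, tmean=18.0, amp=8.0, offset=0.0):
        n = years * 365
        self.day_of_year = np.tile(np.arange(1, 366), years)
        self.year = np.repeat(np.arange(2000, 2000 + years), 365)
        t = tmean + offset + amp * np.cos(
            2 * np.pi * (self.day_of_year - 201) / 365.0)
        self.tmin = t - 5.0
        self.tmax = t + 5.0


class TestCalendarAndCalibration:
    def test_maturity_is_mean_seasonal_gdd(self):
        p = CROPS["maize"]
        cal = CropCalendar(120, 260)
        w = _ConstWeather()
        reqs = calibrate_heat_units(w, cal, p)
        gdd = daily_gdd(w.tmax, w.tmin, p.tbase, p.tupp)
        manual = gdd[119:119 + cal.season_length_days + 1].sum()
        assert reqs.maturity == pytest.approx(manual, rel=1e-9)

    def test_stage_requirements_partition_maturity(self):
        p = CROPS["maize"]
        reqs = calibrate_heat_units(_ConstWeather(), CropCalendar(120, 260), p)
        assert reqs.maturity >= reqs.senescence >= reqs.max_canopy \
            >= reqs.emergence > 0

    def test_too_cold_cell_is_non_viable(self):
        p = CROPS["maize"]  # Tbase 8 never reached
        with pytest.raises(NonViableCellError):
            calibrate_heat_units(_ConstWeather(tmean=-20.0, amp=2.0),
                                 CropCalendar(120, 260), p)

    def test_calibrated_harvest_on_reference_date(self):
        # closure: under the calibration climate the season ends on the
        # reference harvest date (within 3 days)
        p = CROPS["maize"]
        cal = CropCalendar(120, 260)
        w = _ConstWeather()
        reqs = calibrate_heat_units(w, cal, p)
        gdd = daily_gdd(w.tmax, w.tmin, p.tbase, p.tupp)
        moist = np.ones(len(gdd), dtype=bool)
        emergence, harvest, matured = adjust_calendar(119, gdd, moist, reqs, cal)
        assert matured
        assert emergence == 119
        assert abs((harvest - 119) - cal.season_length_days) <= 3

    def test_warm_year_shortens_season(self):
        p = CROPS["maize"]
        cal = CropCalendar(120, 260)
        reqs = calibrate_heat_units(_ConstWeather(), cal, p)
        moist = np.ones(4 * 365, dtype=bool)
        gdd_ref = daily_gdd(_ConstWeather().tmax, _ConstWeather().tmin,
                            p.tbase, p.tupp)
        gdd_warm = daily_gdd(_ConstWeather(offset=2.0).tmax,
                             _ConstWeather(offset=2.0).tmin, p.tbase, p.tupp)
        _, h_ref, _ = adjust_calendar(119, gdd_ref, moist, reqs, cal)
        _, h_warm, m_warm = adjust_calendar(119, gdd_warm, moist, reqs, cal)
        assert m_warm
        assert h_warm < h_ref

    def test_cold_year_capped_at_15_percent_extension(self):
        p = CROPS["maize"]
        cal = CropCalendar(120, 260)
        reqs = calibrate_heat_units(_ConstWeather(), cal, p)
        cold = _ConstWeather(offset=-4.0)
        gdd_cold = daily_gdd(cold.tmax, cold.tmin, p.tbase, p.tupp)
        moist = np.ones(4 * 365, dtype=bool)
        _, harvest, _ = adjust_calendar(119, gdd_cold, moist, reqs, cal)
        assert harvest - 119 <= int(np.ceil(1.15 * cal.season_length_days))

    def test_dry_seedbed_delays_emergence(self):
        p = CROPS["maize"]
        cal = CropCalendar(120, 260)
        w = _ConstWeather()
        reqs = calibrate_heat_units(w, cal, p)
        gdd = daily_gdd(w.tmax, w.tmin, p.tbase, p.tupp)
        moist = np.ones(len(gdd), dtype=bool)
        moist[119:129] = False  # dry for the first 10 days after planting
        emergence, harvest, _ = adjust_calendar(119, gdd, moist, reqs, cal)
        assert emergence == 129
        ref = adjust_calendar(119, gdd, np.ones_like(moist), reqs, cal)
        assert harvest > ref[1]
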
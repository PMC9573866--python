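"""δ18O thermometry: calibrations, inversions, monthly thermometers."""

import datetime

import numpy as np
import pytest

from otolife import (
    KO_SEAWATER_CALIBRATION,
    HydroObservation,
    SwCalibration,
    acid_fractionation_adjust,
    assign_interval_month,
    build_monthly_thermometer,
    fit_sw_salinity_regression,
    forward_otolith_d18o,
    invert_fixed_sw,
    invert_quadratic,
    sw_d18o_from_salinity,
    sw_variation_to_temp_error,
)

CALCOFI_CALIB = SwCalibration(slope=0.279, intercept=-9.63, provenance="fitted")


class TestAcidAdjustment:
    @pytest.mark.parametrize(
        "d18o,instrument,expected",
        [(1.00, "auto72C", 0.91), (1.00, "micro25C", 1.00), (-0.33, "auto72C", -0.42)],
    )
    def test_instrument_offsets(self, d18o, instrument, expected):
        assert acid_fractionation_adjust(d18o, instrument) == pytest.approx(expected)

    def test_unknown_instrument(self):
        with pytest.raises(ValueError, match="instrument"):
            acid_fractionation_adjust(1.0, "delta-x")


class TestSeawaterSalinityRegression:
    def test_exact_line_recovery(self):
        s = np.linspace(33.0, 33.6, 10)
        calib = fit_sw_salinity_regression(s, 0.279 * s - 9.63)
        assert calib.slope == pytest.approx(0.279, abs=1e-9)
        assert calib.intercept == pytest.approx(-9.63, abs=1e-9)
        assert calib.r_squared == pytest.approx(1.0)

    def test_duplicated_two_points(self):
        s = np.array([33.0, 33.5, 33.0, 33.5])
        d = np.array([0.1, 0.3, 0.1, 0.3])
        calib = fit_sw_salinity_regression(s, d)
        assert calib.slope == pytest.approx(0.4)
        assert calib.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(32, 35, 40)
        d = 0.5 * s - 17 + rng.normal(0, 0.05, 40)
        calib = fit_sw_salinity_regression(s, d)
        # closed-form OLS
        sx = s - s.mean()
        slope = float(sx @ (d - d.mean()) / (sx @ sx))
        intercept = float(d.mean() - slope * s.mean())
        assert calib.slope == pytest.approx(slope, abs=1e-9)
        assert calib.intercept == pytest.approx(intercept, abs=1e-9)

    def test_degenerate_salinity(self):
        with pytest.raises(ValueError):
            fit_sw_salinity_regression([33.0, 33.0, 33.0], [0.1, 0.2, 0.3])


class TestSeawaterPrediction:
    def test_california_bight_salinity_bounds(self):
        # the 95% salinity interval maps to the documented seawater d18O band
        assert round(sw_d18o_from_salinity(32.93, CALCOFI_CALIB), 2) == -0.44
        assert round(sw_d18o_from_salinity(33.69, CALCOFI_CALIB), 2) == -0.23

    def test_kuroshio_oyashio_relation(self):
        assert sw_d18o_from_salinity(34.0, KO_SEAWATER_CALIBRATION) == pytest.approx(-0.02)


class TestForwardInverse:
    def test_zero_temperature(self):
        assert forward_otolith_d18o(-0.5, 0.0) == pytest.approx(2.19)

    def test_hand_value(self):
        assert forward_otolith_d18o(-0.32, 15.0) == pytest.approx(-0.33)

    def test_slope_is_linear(self):
        t = np.linspace(0, 30, 31)
        d = forward_otolith_d18o(0.0, t)
        assert np.allclose(np.diff(d), -0.18)

    def test_fixed_sw_inversion_hand_value(self):
        assert float(invert_fixed_sw(-0.33, -0.32)) == pytest.approx(15.0)

    def test_round_trip_identity(self):
        t = np.linspace(0, 30, 301)
        back = invert_fixed_sw(forward_otolith_d18o(-0.32, t), -0.32)
        assert np.max(np.abs(back - t)) < 1e-12

    @pytest.mark.parametrize("offset,expected", [(0.12, 0.12 / 0.18), (0.0, 0.0), (0.18, 1.0)])
    def test_seawater_offset_to_temperature_error(self, offset, expected):
        assert sw_variation_to_temp_error(offset) == pytest.approx(expected)
        assert sw_variation_to_temp_error(0.12) < 0.7

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            sw_variation_to_temp_error(-0.1)


def _month_obs(temps, sals, month=4, year=2008):
    return [HydroObservation(year, month, float(t), float(s)) for t, s in zip(temps, sals)]


class TestMonthlyThermometer:
    def test_fixed_salinity_exactly_linear(self):
        temps = np.linspace(5, 25, 15)
        obs = _month_obs(temps, np.full(15, 34.0))
        th = build_monthly_thermometer(obs)
        assert th.rmse_c <= 1e-9
        d12 = forward_otolith_d18o(sw_d18o_from_salinity(34.0, KO_SEAWATER_CALIBRATION), 12.0)
        assert invert_quadratic(d12, th) == pytest.approx(12.0, abs=1e-6)

    def test_tight_ts_relation_low_rmse(self):
        rng = np.random.default_rng(4)
        sals = rng.uniform(33.0, 34.5, 300)
        temps = 8.0 * (sals - 33.0) + 8.0 + rng.normal(0, 0.2, 300)
        th = build_monthly_thermometer(_month_obs(temps, sals))
        assert th.rmse_c <= 0.5

    def test_coefficients_match_polyfit_oracle(self):
        rng = np.random.default_rng(9)
        sals = rng.uniform(33.0, 34.5, 100)
        temps = 8.0 * (sals - 33.0) + 8.0 + rng.normal(0, 0.5, 100)
        th = build_monthly_thermometer(_month_obs(temps, sals))
        d = forward_otolith_d18o(sw_d18o_from_salinity(sals, KO_SEAWATER_CALIBRATION), temps)
        oracle = np.polyfit(d, temps, 2)
        assert np.allclose(th.coefficients, oracle, atol=1e-8)

    def test_too_few_distinct_points(self):
        with pytest.raises(ValueError):
            build_monthly_thermometer(_month_obs([10.0, 10.0], [34.0, 34.0]))

    def test_extrapolation_margin_policy(self):
        temps = np.linspace(5, 25, 15)
        th = build_monthly_thermometer(_month_obs(temps, np.full(15, 34.0)))
        lo, hi = th.d18o_validity_range
        with pytest.warns(UserWarning, match="extrapolating"):
            invert_quadratic(hi + 0.4, th)
        with pytest.raises(ValueError, match="beyond validity"):
            invert_quadratic(hi + 0.6, th)


class TestIntervalMonthAssignment:
    @pytest.mark.parametrize(
        "hatch,interval,month",
        [
            (datetime.date(2008, 3, 1), (0, 30), 3),  # median day 15 -> 16 Mar
            (datetime.date(2008, 3, 1), (31, 60), 4),  # median day 45 -> 15 Apr
            (datetime.date(2008, 3, 20), (0, 30), 4),  # median day 15 -> 4 Apr
        ],
    )
    def test_median_date_month(self, hatch, interval, month):
        assert assign_interval_month(hatch, interval) == month

    def test_reversed_interval(self):
        with pytest.raises(ValueError):
            assign_interval_month(datetime.date(2008, 3, 1), (30, 0))
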
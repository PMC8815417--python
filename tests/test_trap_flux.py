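"""Funnel-trap reduction: calibration map, purge handling, error model."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from resflux import synthetic_data as sd
from resflux import trap_flux as tf


def _series(values, freq="5min", start="2018-06-01"):
    idx = pd.date_range(start, periods=len(values), freq=freq, tz="UTC")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


class TestVoltageToVolume:
    def test_root_of_linear_map_gives_zero_volume(self, calibration):
        volts = _series([-calibration.b / calibration.m])
        vol, neg = tf.voltage_to_volume(volts, calibration)
        assert vol.iloc[0] == pytest.approx(0.0, abs=1e-15)
        assert not neg.any()

    def test_direct_evaluation_oracle(self, calibration):
        # m=31, b=-15.81, V=0.61 V, d=0.10 m: height 3.10 cm, tube area
        # pi*25 cm^2 -> 243.47 cm^3
        vol, _ = tf.voltage_to_volume(_series([0.61]), calibration)
        assert vol.iloc[0] == pytest.approx(3.10 * math.pi * 25.0 * 1e-6, rel=1e-9)

    def test_negative_volumes_flagged_not_clipped(self, calibration):
        volts = _series([0.0])  # height = b < 0
        vol, neg = tf.voltage_to_volume(volts, calibration)
        assert vol.iloc[0] < 0
        assert neg.iloc[0]

    def test_missing_calibration_is_an_error(self):
        with pytest.raises(ValueError, match="calibration"):
            tf.voltage_to_volume(_series([0.5]), None)

    def test_study_calibration_constants(self, calibration):
        assert calibration.m == 31.0
        assert calibration.dm == pytest.approx(0.31)


class TestSmoothVolume:
    def test_constant_series_unchanged(self):
        smoothed = tf.smooth_volume(_series([4.0] * 50))
        np.testing.assert_allclose(smoothed.to_numpy(), 4.0)

    def test_single_spike_attenuated_to_height_over_window(self):
        values = np.zeros(50)
        values[25] = 12.0
        smoothed = tf.smooth_volume(_series(values))
        # every full window containing the spike averages it to h/12
        assert smoothed.iloc[25] == pytest.approx(1.0)

    def test_all_missing_window_stays_missing(self):
        s = _series([np.nan] * 30)
        assert tf.smooth_volume(s).isna().all()

    def test_short_series_warns(self):
        with pytest.warns(UserWarning, match="shrink"):
            tf.smooth_volume(_series([1.0] * 5))


class TestFilterPurges:
    def test_monotone_series_has_no_purges(self):
        clean, events = tf.filter_purges(_series(np.linspace(0, 1, 100)), threshold=0.05)
        assert events.empty
        np.testing.assert_allclose(clean.to_numpy(), np.linspace(0, 1, 100))

    def test_injected_purges_detected_at_known_times(self):
        rate = 1e-6
        n = 600
        vol = np.cumsum(np.full(n, rate))
        drops = [150, 300, 450]
        for d in drops:
            vol[d:] -= 5e-4
        series = _series(vol)
        smoothed = tf.smooth_volume(series)
        clean, events = tf.filter_purges(smoothed)
        assert len(events) == 3
        for got, want in zip(events["timestamp"], series.index[drops]):
            # the centered smoothing window smears the drop by up to half
            # a window (6 steps = 30 min) before the true drop time
            assert abs(got - want) <= pd.Timedelta("30min")

    def test_step_below_threshold_not_flagged(self):
        vol = np.cumsum(np.full(100, 1e-6))
        vol[50:] -= 0.5e-4
        _, events = tf.filter_purges(_series(vol), threshold=1e-4)
        assert events.empty

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            tf.filter_purges(_series([1.0, 2.0]), threshold=0.0)

    def test_mass_preserved_across_purges(self):
        # de-purged cumulative must end near the total injected volume
        rate = 1e-6
        vol = np.cumsum(np.full(600, rate))
        for d in (200, 400):
            vol[d:] -= 1.9e-4
        clean, events = tf.filter_purges(_series(vol))
        assert len(events) == 2
        assert clean.iloc[-1] == pytest.approx(600 * rate, rel=0.02)


class TestEbullitiveFlux:
    def test_zero_volume_change_zero_flux(self, bubble_gas, calibration):
        flux = tf.ebullitive_flux(_series([2e-4] * 100), bubble_gas, calibration)
        np.testing.assert_allclose(flux.dropna().to_numpy(), 0.0, atol=1e-12)

    def test_direct_evaluation_oracle(self, bubble_gas, calibration):
        # 6e-5 m3 over 2 h through 0.3 m2 at 4e5 mg/m3 -> 40 mg m-2 h-1
        n = 60
        ramp = np.linspace(0, 6e-5 * (n - 1) / 24.0, n)  # 6e-5 per 24 steps (2 h)
        flux = tf.ebullitive_flux(_series(ramp), bubble_gas, calibration, "2h")
        assert flux.dropna().iloc[0] == pytest.approx(40.0, rel=1e-9)

    def test_linear_ramp_flux_independent_of_bin_width(self, bubble_gas, calibration):
        ramp = np.linspace(0, 1e-3, 200)
        f1 = tf.ebullitive_flux(_series(ramp), bubble_gas, calibration, "1h").dropna()
        f2 = tf.ebullitive_flux(_series(ramp), bubble_gas, calibration, "2h").dropna()
        common = f1.index.intersection(f2.index)
        np.testing.assert_allclose(f1[common].to_numpy(), f2[common].to_numpy())

    def test_disallowed_bin_width_rejected(self, bubble_gas, calibration):
        with pytest.raises(ValueError, match="bin_width"):
            tf.ebullitive_flux(_series([0.0]), bubble_gas, calibration, "3h")

    def test_flux_invariant_to_affine_rezeroing(self, bubble_gas, calibration):
        rng = np.random.default_rng(0)
        volts = _series(np.cumsum(rng.uniform(0, 0.01, 100)) + 0.5)
        shifted_cal = dataclasses.replace(
            calibration, b=calibration.b - calibration.m * 0.2
        )
        base, _ = tf.voltage_to_volume(volts, calibration)
        shifted, _ = tf.voltage_to_volume(volts + 0.2, shifted_cal)
        fa = tf.ebullitive_flux(base, bubble_gas, calibration)
        fb = tf.ebullitive_flux(shifted, bubble_gas, shifted_cal)
        np.testing.assert_allclose(fa.dropna().to_numpy(), fb.dropna().to_numpy())


class TestErrorPropagation:
    def test_zero_error_terms_give_zero_flux_error(self):
        cal = tf.TrapCalibration(dm=0.0, dv_zero=0.0, dv_out=0.0, dead_volume=0.0)
        gas = tf.BubbleGas(ch4_conc=4e5, ch4_conc_sd=0.0)
        flux = _series([5.0] * 50, freq="2h")
        err, cum = tf.propagate_trap_error(flux, cal, gas, purge_count=3)
        np.testing.assert_allclose(err.to_numpy(), 0.0, atol=1e-15)
        assert cum == 0.0

    def test_larger_offset_sd_gives_larger_per_flux_error(self, bubble_gas):
        shallow = tf.TrapCalibration(dv_zero=0.071)
        deep = tf.TrapCalibration(dv_zero=0.045)
        flux = _series([5.0] * 50, freq="2h")
        err_sh, _ = tf.propagate_trap_error(flux, shallow, bubble_gas)
        err_dp, _ = tf.propagate_trap_error(flux, deep, bubble_gas)
        assert (err_sh > err_dp).all()

    @pytest.mark.parametrize("component", ["dm", "dv_zero", "dv_out", "dead_volume"])
    def test_error_monotone_in_every_component(self, bubble_gas, component):
        base = tf.TrapCalibration()
        bigger = dataclasses.replace(base, **{component: getattr(base, component) * 3})
        flux = _series([5.0] * 50, freq="2h")
        _, cum_a = tf.propagate_trap_error(flux, base, bubble_gas, purge_count=5)
        _, cum_b = tf.propagate_trap_error(flux, bigger, bubble_gas, purge_count=5)
        assert cum_b > cum_a


class TestPftFlux:
    def test_zero_volume_zero_flux(self, bubble_gas):
        assert tf.pft_flux(0.0, bubble_gas, 15.0) == 0.0

    def test_direct_evaluation_oracle(self, bubble_gas):
        # 1.8e-4 m3 over 15 h through 0.3 m2 at 4e5 mg/m3 -> 16 mg m-2 h-1
        assert tf.pft_flux(1.8e-4, bubble_gas, 15.0, 0.3) == pytest.approx(16.0)

    def test_doubling_deployment_halves_flux(self, bubble_gas):
        f15 = tf.pft_flux(1e-4, bubble_gas, 15.0)
        f30 = tf.pft_flux(1e-4, bubble_gas, 30.0)
        assert f15 == pytest.approx(2 * f30)

    def test_negative_volume_warns_and_returns_zero(self, bubble_gas):
        with pytest.warns(UserWarning, match="negative"):
            assert tf.pft_flux(-1e-5, bubble_gas, 15.0) == 0.0

    def test_nonpositive_deployment_rejected(self, bubble_gas):
        with pytest.raises(ValueError, match="deployment"):
            tf.pft_flux(1e-4, bubble_gas, 0.0)


class TestDailyAndCumulative:
    def test_constant_flux_ten_days(self):
        idx = pd.date_range("2018-06-01", periods=480, freq="30min", tz="UTC")
        flux = pd.Series(1.0, index=idx)
        _, cumulative, _ = tf.daily_and_cumulative(flux)
        assert cumulative == pytest.approx(0.24)  # 1 mg/m2/h * 240 h

    def test_short_gap_interpolated_between_equal_neighbors(self):
        idx = pd.date_range("2018-06-01", periods=48, freq="30min", tz="UTC")
        flux = pd.Series(2.0, index=idx)
        flux.iloc[20:24] = np.nan  # 2-h gap, below the 6-h limit
        table, cumulative, _ = tf.daily_and_cumulative(flux)
        assert cumulative == pytest.approx(2.0 * 24 / 1000)

    def test_long_gap_left_missing(self):
        idx = pd.date_range("2018-06-01", periods=480, freq="30min", tz="UTC")
        flux = pd.Series(1.0, index=idx)
        flux.iloc[100:200] = np.nan  # 50-h gap exceeds the 6-h limit
        table, _, _ = tf.daily_and_cumulative(flux)
        assert (table["n_obs"] < 48).any()


class TestEndToEnd:
    def test_zero_noise_reduction_recovers_injected_mass(
        self, zero_noise_truth, calibration
    ):
        cfg = zero_noise_truth.config
        sim = sd.gen_trap_voltage(zero_noise_truth, calibration, cfg)
        gas = tf.BubbleGas(ch4_conc=cfg.bubble_ch4_mg_m3)
        red = tf.reduce_trap_series(sim.voltage, calibration, gas)
        _, cumulative, _ = tf.daily_and_cumulative(red["flux"], red["flux_error"])
        true_g_m2 = (
            sim.total_injected_volume * cfg.bubble_ch4_mg_m3 / 1000.0 / calibration.a_f
        )
        assert cumulative == pytest.approx(true_g_m2, rel=0.01)

    def test_purge_count_matches_simulator(self, zero_noise_truth, calibration):
        cfg = zero_noise_truth.config
        sim = sd.gen_trap_voltage(zero_noise_truth, calibration, cfg)
        gas = tf.BubbleGas(ch4_conc=cfg.bubble_ch4_mg_m3)
        red = tf.reduce_trap_series(sim.voltage, calibration, gas)
        assert len(red["purges"]) == len(sim.purge_times)
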
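"""Generator contracts: determinism, conservation, gap structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from resflux import synthetic_data as sd
from resflux.chamber_flux import ChamberGeometry
from resflux.trap_flux import TrapCalibration


class TestSimConfig:
    def test_rejects_bad_gap_fraction(self):
        with pytest.raises(ValueError, match="gap_fraction"):
            sd.SimConfig(gap_fraction=1.5)

    def test_rejects_inverted_span(self):
        with pytest.raises(ValueError, match="end"):
            sd.SimConfig(start="2018-11-01", end="2018-04-01")

    def test_rejects_burst_outside_span(self):
        with pytest.raises(ValueError, match="burst_window"):
            sd.SimConfig(burst_window=("2019-05-24", "2019-06-04"))

    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError, match="noise"):
            sd.SimConfig(noise_sd={"ec": -1.0})


class TestDrivers:
    def test_zero_noise_sediment_temperature_is_deterministic_sinusoid(
        self, zero_noise_config
    ):
        drivers = sd.gen_drivers(zero_noise_config)
        expected = sd.sediment_temperature(drivers.index)
        np.testing.assert_allclose(drivers["sed_t"].to_numpy(), expected)

    def test_same_seed_reproduces_bit_identical_output(self, default_config):
        a = sd.gen_drivers(default_config)
        b = sd.gen_drivers(default_config)
        pd.testing.assert_frame_equal(a, b)

    def test_sediment_temperature_peaks_in_warm_season(self):
        cfg = sd.SimConfig(
            start="2018-01-01", end="2018-12-31", noise_sd=sd.zero_noise()
        )
        drivers = sd.gen_drivers(cfg)
        peak_month = drivers["sed_t"].idxmax().month
        assert 5 <= peak_month <= 9

    def test_drivers_fully_observed(self, default_config):
        assert not sd.gen_drivers(default_config).isna().any().any()


class TestTrueFlux:
    def test_flat_when_no_burst_and_q10_one(self, zero_noise_config):
        cfg = dataclasses.replace(
            zero_noise_config, burst_amplitude=0.0, q10_true=1.0
        )
        truth = sd.gen_true_flux(sd.gen_drivers(cfg), cfg)
        np.testing.assert_allclose(
            truth.flux["shallow_total"].to_numpy(), cfg.baseline_flux
        )

    def test_baseline_below_threshold(self, zero_noise_config):
        cfg = dataclasses.replace(zero_noise_config, burst_amplitude=0.0)
        truth = sd.gen_true_flux(sd.gen_drivers(cfg), cfg)
        cold = truth.drivers["sed_t"] < cfg.threshold_temp_true
        assert cold.any()
        np.testing.assert_allclose(
            truth.flux.loc[cold, "shallow_total"].to_numpy(), cfg.baseline_flux
        )

    def test_components_sum_to_total_everywhere(self, default_truth):
        flux = default_truth.flux
        for stratum in ("shallow", "deep"):
            np.testing.assert_allclose(
                flux[f"{stratum}_diffusive"] + flux[f"{stratum}_ebullitive"],
                flux[f"{stratum}_total"],
            )

    def test_log_slope_inverts_to_configured_q10(self):
        # F = F0 * 10**(b*(T-Tref)) with b = log10(10)/10 = 0.1 must yield
        # an estimated ecological Q10 of exactly 10 downstream
        from resflux.fluxstats import eco_q10

        cfg = sd.SimConfig(
            seed=5,
            noise_sd=sd.zero_noise(),
            gap_fraction=0.0,
            q10_true=10.0,
            threshold_temp_true=-50.0,
            burst_amplitude=0.0,
        )
        truth = sd.gen_true_flux(sd.gen_drivers(cfg), cfg)
        res = eco_q10(
            truth.drivers["sed_t"], truth.flux["shallow_total"], daily_means=False
        )
        assert res.eco_q10 == pytest.approx(10.0, rel=1e-9)


class TestEcObservations:
    def test_zero_noise_zero_gaps_equals_truth(self, zero_noise_config, zero_noise_truth):
        obs = sd.gen_ec_observations(zero_noise_truth, zero_noise_config)
        np.testing.assert_allclose(
            obs["fch4"].to_numpy(), zero_noise_truth.flux["shallow_total"].to_numpy()
        )

    @pytest.mark.parametrize("gap_fraction", [0.4, 0.6])
    def test_gap_fraction_achieved(self, default_truth, gap_fraction):
        cfg = dataclasses.replace(default_truth.config, gap_fraction=gap_fraction)
        obs = sd.gen_ec_observations(default_truth, cfg)
        achieved = obs["fch4"].isna().mean()
        assert achieved == pytest.approx(gap_fraction, abs=0.02)

    def test_noise_is_unbiased(self, default_truth):
        cfg = dataclasses.replace(default_truth.config, gap_fraction=0.0)
        obs = sd.gen_ec_observations(default_truth, cfg)
        resid = obs["fch4"] - default_truth.flux["shallow_total"]
        assert abs(resid.mean()) < 3 * cfg.noise_sd["ec"] / np.sqrt(len(resid))

    def test_all_gaps_is_an_error(self, default_truth):
        cfg = dataclasses.replace(default_truth.config, gap_fraction=1.0)
        with pytest.raises(ValueError, match="gap_fraction"):
            sd.gen_ec_observations(default_truth, cfg)


class TestTrapVoltage:
    def test_zero_bubble_rate_constant_voltage(self, zero_noise_truth, calibration):
        cfg = dataclasses.replace(zero_noise_truth.config, bubble_rate=0.0)
        sim = sd.gen_trap_voltage(zero_noise_truth, calibration, cfg)
        assert sim.voltage.nunique() == 1
        assert float(sim.true_flux.sum()) == 0.0

    def test_mass_conservation_before_noise(self, zero_noise_truth, calibration):
        sim = sd.gen_trap_voltage(zero_noise_truth, calibration, zero_noise_truth.config)
        # every injected volume appears as a positive voltage-implied
        # increment except those masked by a purge drop
        d_cm = calibration.aft_d * 100.0
        area = np.pi * (d_cm / 2) ** 2
        vol = (sim.voltage * calibration.m + calibration.b) * area * 1e-6
        steps = vol.diff().dropna()
        recovered = steps[steps > 0].sum() + vol.iloc[0]
        drop_positions = sim.injected_volume.index.get_indexer(sim.purge_times) + 1
        drop_positions = drop_positions[drop_positions < len(sim.injected_volume)]
        masked = sim.injected_volume.iloc[drop_positions].sum()
        assert recovered + masked == pytest.approx(sim.total_injected_volume, rel=1e-9)

    def test_small_capacity_triggers_purges(self, zero_noise_truth, calibration):
        cfg = dataclasses.replace(
            zero_noise_truth.config,
            trap_capacity=1e-3,
            bubble_volume_median=1e-5,
            bubble_rate=2.0,
        )
        sim = sd.gen_trap_voltage(zero_noise_truth, calibration, cfg)
        assert len(sim.purge_times) >= 1

    def test_capacity_below_bubble_volume_rejected(self, zero_noise_truth, calibration):
        cfg = dataclasses.replace(
            zero_noise_truth.config, trap_capacity=5e-7, bubble_volume_median=1e-6
        )
        with pytest.raises(ValueError, match="capacity"):
            sd.gen_trap_voltage(zero_noise_truth, calibration, cfg)


class TestChamberTrace:
    def test_zero_flux_flat_trace(self, zero_noise_config):
        dep = sd.gen_chamber_trace(0.0, ChamberGeometry(), zero_noise_config, chi0=2.0)
        np.testing.assert_allclose(dep.trace["ch4_ppm"].to_numpy(), 2.0)

    def test_linear_slope_matches_flux_inversion(self, zero_noise_config):
        # 3.6 mg m-2 h-1 in the reference geometry implies 0.01 ppm/s
        geom = ChamberGeometry(v=0.03, a=0.2, p=101325.0, t=293.15)
        dep = sd.gen_chamber_trace(3.6007307917818006, geom, zero_noise_config)
        slopes = np.diff(dep.trace["ch4_ppm"]) / np.diff(dep.trace["t_s"])
        np.testing.assert_allclose(slopes, 0.01, rtol=1e-9)

    def test_injected_spike_is_a_large_step(self, zero_noise_config):
        dep = sd.gen_chamber_trace(
            3.6, ChamberGeometry(), zero_noise_config, spike_at=20
        )
        steps = np.diff(dep.trace["ch4_ppm"])
        assert steps[19] > 5 * np.median(steps)

    def test_nonpositive_duration_rejected(self, zero_noise_config):
        with pytest.raises(ValueError, match="duration"):
            sd.gen_chamber_trace(1.0, ChamberGeometry(), zero_noise_config, duration_s=0)


class TestSurvey:
    def test_row_count_matches_site_count(self, default_truth):
        table = sd.gen_survey(default_truth, default_truth.config, "2018-07-10")
        assert len(table) == 15

    def test_depth_labels_consistent_with_cutoff(self, default_truth):
        table = sd.gen_survey(default_truth, default_truth.config, "2018-07-10")
        np.testing.assert_array_equal(
            table["is_deep"].to_numpy(),
            (table["depth_m"] >= default_truth.config.depth_cutoff).to_numpy(),
        )

    def test_zero_site_noise_weighted_mean_is_area_weighted_truth(
        self, zero_noise_truth
    ):
        cfg = zero_noise_truth.config
        table = sd.gen_survey(zero_noise_truth, cfg, "2018-07-10")
        w = table["weight"] / table["weight"].sum()
        got = float((w * table["total"]).sum())
        day = zero_noise_truth.flux.loc["2018-07-10"]
        frac_sh = cfg.depth_cutoff / cfg.max_depth
        want = frac_sh * day["shallow_total"].mean() + (1 - frac_sh) * day[
            "deep_total"
        ].mean()
        assert got == pytest.approx(want, rel=1e-9)


def test_write_streams_round_trip(tmp_path, default_truth, default_config):
    obs = sd.gen_ec_observations(default_truth, default_config)
    sd.write_streams(tmp_path, default_truth, obs, default_config)
    assert (tmp_path / "schema.md").exists()
    back = pd.read_csv(tmp_path / "drivers.csv", index_col=0, parse_dates=True)
    assert len(back) == len(default_truth.drivers)
    np.testing.assert_allclose(
        back["sed_t"].to_numpy(), default_truth.drivers["sed_t"].to_numpy(), rtol=1e-6
    )
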
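"""Tests of the growth-scenario generator and synthetic measurement runs."""

import numpy as np
import pandas as pd
import pytest

import dropvisc as dv
from dropvisc.synthetic import (
    GrowthScenario,
    OdParams,
    classify_regime,
    generate_calibration_set,
    generate_run,
    negative_control_run,
    od_curve,
    simulate_growth_traces,
    spatial_profile,
    viscosity_curve,
)


class TestOdCurve:
    def test_lag_phase_starts_near_od0(self):
        assert 0.05 <= od_curve(0.0) <= 0.06

    def test_logistic_midpoint_at_inflexion(self):
        assert od_curve(6.0) == pytest.approx((0.05 + 2.83) / 2, abs=1e-6)

    def test_death_phase_value_at_48h(self):
        # logistic saturated at 2.83, minus 36 h of linear decline
        assert od_curve(48.0) == pytest.approx(2.83 - 0.0064 * 36, abs=1e-3)

    def test_monotone_rise_then_decline(self):
        t = np.linspace(0, 48, 289)
        od = np.asarray(od_curve(t))
        i_stat = np.searchsorted(t, 12.2)
        assert np.all(np.diff(od[:i_stat]) >= 0) or np.all(
            np.diff(od[: np.searchsorted(t, 12.0)]) >= 0
        )
        assert od[-1] < od.max()

    def test_floored_at_od0(self):
        params = OdParams(death_slope=1.0)  # absurdly fast death
        assert od_curve(48.0, params) == params.od0


class TestViscosityCurve:
    def test_baseline_peak_and_final_values(self):
        assert viscosity_curve(0.0) == pytest.approx(1.83, abs=0.01)
        assert viscosity_curve(6.0) == pytest.approx(23.31, abs=1e-9)
        # 5.5 + 17.81·e⁻⁷
        assert viscosity_curve(48.0) == pytest.approx(5.5162, abs=1e-3)

    def test_continuous_at_peak(self):
        eps = 1e-9
        assert viscosity_curve(6.0 - eps) == pytest.approx(viscosity_curve(6.0 + eps), abs=1e-6)

    def test_unique_maximum_at_inflexion(self):
        t = np.linspace(0, 48, 2881)
        mu = np.asarray(viscosity_curve(t))
        assert t[np.argmax(mu)] == pytest.approx(6.0, abs=0.02)

    def test_pressure_ordering_of_peaks(self):
        peaks = {p: viscosity_curve(6.0, pressure_mbar=p) for p in (100, 200, 300)}
        assert peaks[100] > peaks[200] > peaks[300]
        assert peaks[100] == pytest.approx(23.31)
        assert peaks[200] == pytest.approx(10.0)
        assert peaks[300] == pytest.approx(5.5)

    def test_unknown_pressure_raises(self):
        with pytest.raises(KeyError, match="250"):
            viscosity_curve(6.0, pressure_mbar=250)

    def test_lag_phase_is_rheologically_quiet(self):
        # within the lag phase viscosity stays near baseline
        t = np.linspace(0, 2.5, 16)
        mu = np.asarray(viscosity_curve(t))
        assert mu.max() - 1.83 < 0.25


class TestSpatialProfile:
    def test_uniform_regime_below_threshold(self, rng):
        p = spatial_profile(0.1, 1.5, pre_peak=True, rng=rng)
        assert p.regime == "uniform"
        assert np.std(p.values) == 0.0

    def test_patchy_regime_midrange(self, rng):
        p = spatial_profile(1.0, 10.0, pre_peak=True, rng=rng)
        assert p.regime == "patchy"
        assert np.std(p.values) > 0

    def test_rear_conglomerate_in_trailing_quarter(self, rng):
        p = spatial_profile(1.5, 23.0, pre_peak=True, rng=rng)
        assert p.regime == "rear_conglomerate"
        s = np.linspace(0, 1, 400, endpoint=False)
        assert s[np.argmax(p(s))] > 0.75

    def test_post_peak_always_uniform(self, rng):
        p = spatial_profile(2.5, 23.0, pre_peak=False, rng=rng)
        assert p.regime == "uniform"

    @pytest.mark.parametrize("od,mu,pre", [(0.05, 1.0, True), (1.2, 10.0, True), (2.8, 23.0, True)])
    def test_normalization_exact(self, rng, od, mu, pre):
        p = spatial_profile(od, mu, pre_peak=pre, rng=rng)
        assert p.mean() == pytest.approx(od, rel=1e-12)

    def test_regime_classification_thresholds(self):
        assert classify_regime(4.9, True) == "uniform"
        assert classify_regime(5.1, True) == "patchy"
        assert classify_regime(15.1, True) == "rear_conglomerate"
        assert classify_regime(23.0, False) == "uniform"


class TestCfuFromOd:
    def test_linearity_and_zero(self):
        assert dv.cfu_from_od(0.0) == 0.0
        assert dv.cfu_from_od(1.0) == 2 * dv.cfu_from_od(0.5)
        assert dv.cfu_from_od(0.5, factor=8e8) == pytest.approx(4e8)

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            dv.cfu_from_od(-0.1)


class TestGenerateRun:
    def test_default_run_shape(self, instrument):
        events, truth = generate_run(GrowthScenario(), instrument, np.random.default_rng(0))
        assert len(events) == 10 * 289
        assert len(truth) == 10 * 289
        assert set(events.columns) == {
            "replicate",
            "t_h",
            "passage_time_s",
            "integrated_signal_au",
        }

    def test_noise_free_round_trip_exact(self, instrument):
        from dropvisc.calibration import default_viscosity_calibration, viscosity_from_time
        from dropvisc.synthetic import ReplicateCV

        quiet = dv.Instrument(
            instrument.geometry,
            instrument.oil,
            instrument.network,
            dv.SensorModel(passage_time_jitter=0.0, integrated_signal_noise_rms=0.0),
        )
        scenario = GrowthScenario(
            n_replicates=2,
            duration_h=12.0,
            replicate_cv=ReplicateCV(mu_base=0.0, mu_max=0.0, od_max=0.0),
        )
        events, truth = generate_run(scenario, quiet, np.random.default_rng(0))
        cal = default_viscosity_calibration()
        recovered = np.array(
            [viscosity_from_time(dt, cal)[0] for dt in events["passage_time_s"]]
        )
        assert recovered == pytest.approx(truth["true_visc_cP"].to_numpy(), abs=1e-9)

    def test_seed_reproducibility_bit_identical(self, instrument):
        scenario = GrowthScenario(n_replicates=3, duration_h=6.0)
        ev1, tr1 = generate_run(scenario, instrument, np.random.default_rng(7))
        ev2, tr2 = generate_run(scenario, instrument, np.random.default_rng(7))
        pd.testing.assert_frame_equal(ev1, ev2)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_replicate_peak_viscosity_sd_matches_cv(self, instrument):
        # SD of per-replicate peaks ≈ CV·μ_max = 0.08·23.31 ≈ 1.86 cP
        scenario = GrowthScenario(n_replicates=80, duration_h=8.0)
        _, truth = generate_run(scenario, instrument, np.random.default_rng(3))
        peaks = truth.groupby("replicate")["true_visc_cP"].max()
        assert peaks.std() == pytest.approx(1.86, rel=0.35)

    def test_desk_scale_guard(self, instrument):
        scenario = GrowthScenario(n_replicates=10, duration_h=48.0, cadence_min=0.02)
        with pytest.raises(ValueError, match="events"):
            generate_run(scenario, instrument, np.random.default_rng(0))


class TestCalibrationSet:
    def test_record_count(self, instrument):
        df = generate_calibration_set([1, 5, 10, 20, 30], instrument, n_rep=10,
                                      rng=np.random.default_rng(0))
        assert len(df) == 50
        assert set(df.columns) == {"label", "known_value", "measured_value"}

    def test_noise_free_recovers_affine_law(self, instrument):
        quiet = dv.Instrument(
            instrument.geometry, instrument.oil, instrument.network,
            dv.SensorModel(passage_time_jitter=0.0),
        )
        df = generate_calibration_set([1, 5, 10, 20, 30], quiet, n_rep=2,
                                      rng=np.random.default_rng(0))
        cal = dv.fit_viscosity_calibration(df["measured_value"], df["known_value"])
        assert cal.slope == pytest.approx(29.0 / 13.0, rel=1e-9)
        assert cal.intercept == pytest.approx(-2974.0 / 13.0, rel=1e-9)

    def test_timing_scatter_matches_configured_jitter(self, instrument):
        df = generate_calibration_set([1.0], instrument, n_rep=1000,
                                      rng=np.random.default_rng(5))
        assert df["measured_value"].std() == pytest.approx(
            instrument.sensor.passage_time_jitter, rel=0.15
        )

    def test_refuses_unformable_standards(self, instrument):
        with pytest.raises(ValueError, match="60"):
            generate_calibration_set([65.0], instrument, rng=np.random.default_rng(0))


class TestNegativeControl:
    def test_constant_truth(self, instrument):
        events, truth = negative_control_run(instrument=instrument,
                                             rng=np.random.default_rng(0))
        assert truth["true_visc_cP"].nunique() == 1
        assert truth["true_od_au"].nunique() == 1

    def test_noise_free_is_exactly_constant(self, instrument):
        quiet = dv.Instrument(
            instrument.geometry, instrument.oil, instrument.network,
            dv.SensorModel(passage_time_jitter=0.0, integrated_signal_noise_rms=0.0),
        )
        events, _ = negative_control_run(instrument=quiet, rng=np.random.default_rng(0))
        assert events["passage_time_s"].nunique() == 1

    def test_mean_recovered_od_unbiased(self, instrument):
        import warnings

        from dropvisc.calibration import ExtrapolationWarning

        events, _ = negative_control_run(instrument=instrument,
                                         rng=np.random.default_rng(11))
        with warnings.catch_warnings():
            # half the noisy signals sit a hair above the 2.3 a.u. anchor
            warnings.simplefilter("ignore", ExtrapolationWarning)
            od = np.array([dv.od_from_signal(s) for s in events["integrated_signal_au"]])
        se = od.std(ddof=1) / np.sqrt(od.size)
        assert abs(od.mean() - 0.05) < 2 * se + 1e-9


class TestTraceLevel:
    def test_small_run_yields_trace_pairs(self, instrument):
        scenario = GrowthScenario(n_replicates=1, duration_h=0.5, cadence_min=10.0)
        records = simulate_growth_traces(scenario, instrument, np.random.default_rng(0))
        assert len(records) == 4
        assert {r["trace_a"].sensor_id for r in records} == {"A"}

    def test_large_run_refused(self, instrument):
        with pytest.raises(ValueError, match="event-level"):
            simulate_growth_traces(GrowthScenario(), instrument, np.random.default_rng(0))
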
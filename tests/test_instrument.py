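"""Unit tests of the plug-flow forward model and trace synthesis."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import dropvisc as dv
from dropvisc.instrument import InstrumentError, ModelValidityWarning


class TestPlugLength:
    def test_default_plug_is_six_diameters(self, instrument):
        length = dv.plug_length(2.4e-9, instrument.geometry)
        assert length == pytest.approx(4.7746e-3, rel=1e-4)
        assert round(length / instrument.geometry.inner_diameter) == 6

    def test_one_diameter_volume_gives_length_d(self, instrument):
        g = instrument.geometry
        assert dv.plug_length(g.cross_section * g.inner_diameter, g) == pytest.approx(
            g.inner_diameter, rel=1e-12
        )

    def test_length_linear_in_volume(self, instrument):
        g = instrument.geometry
        assert dv.plug_length(1.2e-9, g) == pytest.approx(dv.plug_length(2.4e-9, g) / 2, rel=1e-12)
        assert dv.plug_length(1.2e-9, g) == pytest.approx(2.3873e-3, rel=1e-4)

    def test_rejects_nonpositive_volume(self, instrument):
        with pytest.raises(InstrumentError):
            dv.plug_length(0.0, instrument.geometry)


class TestTubeResistance:
    def test_hand_computed_value(self):
        # 8·μ·L/(π r⁴) at oil viscosity over the full loop
        assert dv.tube_resistance(0.395e-3, 1.2, 0.4e-3) == pytest.approx(4.715e10, rel=1e-3)

    def test_scaling_laws(self):
        base = dv.tube_resistance(1e-3, 1.0, 1e-3)
        assert dv.tube_resistance(1e-3, 1.0, 2e-3) == pytest.approx(base / 16, rel=1e-12)
        assert dv.tube_resistance(1e-2, 1.0, 1e-3) == pytest.approx(base * 10, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(InstrumentError):
            dv.tube_resistance(-1e-3, 1.0, 1e-3)


class TestPassageTime:
    @pytest.mark.parametrize("mu_cp,expected_s", [(1.0, 103.0), (30.0, 116.0)])
    def test_calibration_anchor_points(self, instrument, op100, mu_cp, expected_s):
        res = dv.passage_time(
            dv.DropletState.from_cp(mu_cp), instrument.geometry, instrument.network, op100
        )
        assert res.passage_time == pytest.approx(expected_s, rel=1e-9)

    def test_inverse_pressure_scaling(self, instrument):
        res = dv.passage_time(
            dv.DropletState.from_cp(1.0),
            instrument.geometry,
            instrument.network,
            dv.OperatingPoint.from_mbar(200.0),
        )
        assert res.passage_time == pytest.approx(51.5, rel=1e-9)

    def test_transit_result_self_consistency(self, instrument, op100):
        g = instrument.geometry
        res = dv.passage_time(dv.DropletState.from_cp(5.0), g, instrument.network, op100)
        assert res.speed == pytest.approx(g.sensor_separation / res.passage_time, rel=1e-12)
        assert res.flow_rate == pytest.approx(res.speed * g.cross_section, rel=1e-12)

    def test_strictly_monotone_in_viscosity(self, instrument, op100):
        times = [
            dv.passage_time(
                dv.DropletState.from_cp(mu), instrument.geometry, instrument.network, op100
            ).passage_time
            for mu in (1, 5, 17, 30, 50)
        ]
        assert np.all(np.diff(times) > 0)

    def test_noise_free_affinity_r2_is_one(self, instrument, op100):
        mus = np.array([1.0, 3.0, 8.0, 15.0, 30.0])
        dts = np.array(
            [
                dv.passage_time(
                    dv.DropletState.from_cp(m), instrument.geometry, instrument.network, op100
                ).passage_time
                for m in mus
            ]
        )
        r = np.corrcoef(mus, dts)[0, 1]
        assert r**2 == pytest.approx(1.0, abs=1e-12)

    def test_out_of_validity_warns_not_raises(self, instrument, op100):
        with pytest.warns(ModelValidityWarning):
            dv.passage_time(
                dv.DropletState.from_cp(55.0), instrument.geometry, instrument.network, op100
            )

    def test_nonpositive_viscosity_rejected(self):
        with pytest.raises(InstrumentError):
            dv.DropletState.from_cp(0.0)

    def test_time_stepping_oracle_matches_closed_form(self, instrument, op100):
        """Independent brute-force integration of dx/dt = Δp/(S·(Rc+k_d μ))."""
        g, n = instrument.geometry, instrument.network
        for mu_cp in (1.0, 7.5, 30.0):
            speed = op100.pressure_difference / (
                g.cross_section * (n.channel_resistance + n.droplet_resistance_coefficient * mu_cp * 1e-3)
            )
            sol = solve_ivp(
                lambda t, x: [speed],
                (0.0, 1000.0),
                [0.0],
                events=lambda t, x: x[0] - g.sensor_separation,
                rtol=1e-12,
                atol=1e-12,
            )
            oracle_dt = sol.t_events[0][0]
            closed = dv.passage_time(
                dv.DropletState.from_cp(mu_cp), g, n, op100
            ).passage_time
            assert abs(oracle_dt - closed) / closed < 1e-9
            # the package's own stepping helper agrees as well
            assert dv.integrate_transit(
                dv.DropletState.from_cp(mu_cp), g, n, op100
            ) == pytest.approx(closed, rel=1e-9)


class TestDiagnostics:
    def test_capillary_number_at_reference_point(self):
        # v from Δt = 103 s over l = 1 m
        assert dv.capillary_number(0.395e-3, 1.0 / 103.0, 19e-3) == pytest.approx(2.02e-4, rel=5e-3)

    def test_capillary_number_linear_in_speed(self):
        assert dv.capillary_number(0.395e-3, 0.0, 19e-3) == 0.0
        assert dv.capillary_number(0.395e-3, 2e-3, 19e-3) == pytest.approx(
            2 * dv.capillary_number(0.395e-3, 1e-3, 19e-3), rel=1e-12
        )

    def test_capillary_number_zero_tension_raises(self):
        with pytest.raises(ZeroDivisionError):
            dv.capillary_number(0.395e-3, 1e-3, 0.0)

    def test_interface_shear_rate_at_reference_point(self, instrument):
        assert dv.interface_shear_rate(1.0 / 103.0, instrument.geometry) == pytest.approx(
            11.0, rel=1e-2
        )
        assert dv.interface_shear_rate(0.0, instrument.geometry) == 0.0


class TestDefaultInstrument:
    def test_back_solved_network_constants(self, instrument):
        assert instrument.network.channel_resistance == pytest.approx(2.040e12, rel=1e-3)
        # k_d = β·Δp/(l·S) with β = (13/29) s/cP expressed per Pa·s
        assert instrument.network.droplet_resistance_coefficient == pytest.approx(
            (13.0 / 29.0) * 1e3 * 1e4 / (1.0 * instrument.geometry.cross_section), rel=1e-9
        )

    def test_sensor_defaults_reproduce_od_map_endpoints(self, instrument):
        s = instrument.sensor
        assert s.voltage_of_od(2.5) == pytest.approx(1.8, abs=1e-12)
        assert s.voltage_of_od(0.05) == pytest.approx(2.3, abs=1e-12)


class TestSimulateTransit:
    def test_uniform_od_interior_voltage(self, instrument, op100, quiet_sensor):
        droplet = dv.DropletState.from_cp(1.0, od_profile=0.05)
        trace_a, _, _ = dv.simulate_transit(
            droplet, instrument.geometry, instrument.network, op100, quiet_sensor
        )
        # interior plateau away from spikes sits exactly at the OD map value
        t = trace_a.times
        interior = (t > 1.1) & (t < 1.3)
        assert trace_a.samples[interior] == pytest.approx(2.3, abs=1e-12)

    def test_noise_free_spike_separation_equals_closed_form(self, instrument, op100, quiet_sensor):
        droplet = dv.DropletState.from_cp(1.0)
        trace_a, trace_b, true_dt = dv.simulate_transit(
            droplet, instrument.geometry, instrument.network, op100, quiet_sensor
        )
        ev_a = dv.detect_event(trace_a)
        ev_b = dv.detect_event(trace_b)
        measured = dv.passage_time_between(ev_a, ev_b)
        assert abs(measured - true_dt) <= 1.0 / quiet_sensor.sampling_rate

    def test_coarse_sampling_rejected(self, instrument, op100):
        slow = dv.SensorModel(sampling_rate=20.0)
        with pytest.raises(InstrumentError, match="too coarse"):
            dv.simulate_transit(
                dv.DropletState.from_cp(1.0),
                instrument.geometry,
                instrument.network,
                op100,
                slow,
            )

    def test_trace_window_has_baseline_outside_plug(self, instrument, op100, quiet_sensor):
        trace_a, _, _ = dv.simulate_transit(
            dv.DropletState.from_cp(1.0, od_profile=1.0),
            instrument.geometry,
            instrument.network,
            op100,
            quiet_sensor,
        )
        assert trace_a.samples[0] == pytest.approx(quiet_sensor.baseline_voltage, abs=1e-12)
        assert trace_a.samples[-1] == pytest.approx(quiet_sensor.baseline_voltage, abs=1e-12)


class TestGeometryInvariants:
    def test_cross_section_identity(self):
        g = dv.ChannelGeometry(inner_diameter=1.1e-3)
        assert g.cross_section == pytest.approx(math.pi * 1.1e-3**2 / 4, rel=1e-15)

    def test_sensor_separation_must_fit_loop(self):
        with pytest.raises(InstrumentError):
            dv.ChannelGeometry(sensor_separation=1.5, loop_length=1.2)
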
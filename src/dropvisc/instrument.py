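"""Forward physical model of a two-sensor droplet viscometer.

A sample plug of volume ``V`` (aqueous medium, possibly carrying a bacterial
culture) is driven through FEP tubing of inner diameter ``d`` by a constant
pressure difference ``Δp`` applied across the loop, with a fluorinated oil as
the continuous phase. Treating the system as an electric circuit (Kirchhoff
analogy), the oil-filled channel and the plug act as two hydrodynamic
resistances in series,

    Rc + Rd = Δp / Q,        Rd = k_d · μ_d,

where ``Q = v·S`` is the volumetric flow rate, ``S = π d²/4`` the tube cross
section, ``μ_d`` the plug viscosity and ``k_d`` a lumped geometric
coefficient. Two optical sensors a distance ``l`` apart time the plug, so the
passage time

    Δt = l·S·(Rc + k_d·μ_d) / Δp

is affine in the plug viscosity and inversely proportional to the driving
pressure. ``Rc`` and ``k_d`` are anchored to a measured two-point calibration
(1 cP → 103 s, 30 cP → 116 s at 100 mbar) rather than computed ab initio,
because the thin lubricating oil film around a plug makes a bare
Hagen–Poiseuille estimate of ``Rd`` unreliable.

All quantities in this module are SI (m, s, Pa, Pa·s); viscosities in cP
appear only in named helpers and at configuration boundaries (1 cP = 1 mPa·s).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional

import numpy as np

# unit conversions applied at the boundaries
CP_TO_PA_S = 1.0e-3
PA_S_TO_CP = 1.0e3
MBAR_TO_PA = 100.0

#: calibration anchor points: (viscosity_cP, passage_time_s) at 100 mbar
CAL_ANCHOR_LOW = (1.0, 103.0)
CAL_ANCHOR_HIGH = (30.0, 116.0)
#: affine law Δt = ALPHA_S + BETA_S_PER_CP · μ[cP] at 100 mbar (exact two-point solution)
BETA_S_PER_CP = (CAL_ANCHOR_HIGH[1] - CAL_ANCHOR_LOW[1]) / (CAL_ANCHOR_HIGH[0] - CAL_ANCHOR_LOW[0])
ALPHA_S = CAL_ANCHOR_LOW[1] - BETA_S_PER_CP * CAL_ANCHOR_LOW[0]

#: plug viscosity above which monodisperse droplet formation degrades
VALIDITY_LIMIT_CP = 50.0

#: dimensionless coefficient in the interface shear-rate estimate c_s·v/r,
#: calibrated so that the 100-mbar, ~1 cP operating point gives ~11 s⁻¹
DEFAULT_SHEAR_COEFFICIENT = 0.453


class ModelValidityWarning(UserWarning):
    """Operating point outside the validated range of the resistance model."""


class InstrumentError(ValueError):
    """Invalid physical input to the instrument model."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Measurement tubing: inner diameter, sensor spacing and loop length (m)."""

    inner_diameter: float = 0.8e-3
    sensor_separation: float = 1.0
    loop_length: float = 1.2

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0:
            raise InstrumentError("inner_diameter must be positive")
        if not (0 < self.sensor_separation <= self.loop_length):
            raise InstrumentError("require 0 < sensor_separation <= loop_length")

    @property
    def radius(self) -> float:
        return self.inner_diameter / 2.0

    @property
    def cross_section(self) -> float:
        """Tube cross-sectional area S = π d²/4 (m²)."""
        return math.pi * self.inner_diameter**2 / 4.0


@dataclass(frozen=True)
class ContinuousPhase:
    """Carrier oil: dynamic viscosity (Pa·s) and interfacial tension vs. the sample (N/m)."""

    viscosity: float = 0.395e-3
    interfacial_tension: float = 19e-3
    label: str = "HFE-7200 + 5% PFO"

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.interfacial_tension <= 0:
            raise InstrumentError("oil viscosity and interfacial tension must be positive")


@dataclass(frozen=True)
class OperatingPoint:
    """Driving pressure difference (Pa) and bath temperature (°C, informational)."""

    pressure_difference: float = 100.0 * MBAR_TO_PA
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if self.pressure_difference <= 0:
            raise InstrumentError("pressure_difference must be positive")

    @classmethod
    def from_mbar(cls, pressure_mbar: float, temperature: float = 37.0) -> "OperatingPoint":
        return cls(pressure_mbar * MBAR_TO_PA, temperature)


@dataclass
class DropletState:
    """A sample plug: volume (m³), viscosity (Pa·s) and axial OD profile.

    ``od_profile`` maps normalized axial position ``s ∈ [0, 1]`` (0 = front of
    the plug) to local optical density; a scalar means a uniform profile.
    """

    volume: float = 2.4e-9
    viscosity: float = 1.0e-3
    od_profile: float | Callable[[np.ndarray], np.ndarray] = 0.0

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise InstrumentError("droplet volume must be positive")
        if self.viscosity <= 0:
            raise InstrumentError("droplet viscosity must be positive")

    @classmethod
    def from_cp(cls, viscosity_cp: float, volume: float = 2.4e-9,
                od_profile: float | Callable = 0.0) -> "DropletState":
        return cls(volume=volume, viscosity=viscosity_cp * CP_TO_PA_S, od_profile=od_profile)

    @property
    def viscosity_cp(self) -> float:
        return self.viscosity * PA_S_TO_CP

    def od_at(self, s: np.ndarray) -> np.ndarray:
        """Local optical density at normalized axial positions ``s``."""
        if callable(self.od_profile):
            return np.asarray(self.od_profile(np.asarray(s, dtype=float)), dtype=float)
        return np.full(np.shape(s), float(self.od_profile))


@dataclass(frozen=True)
class HydraulicNetwork:
    """Lumped series resistances: channel resistance Rc (Pa·s·m⁻³) and plug
    coefficient k_d (m⁻³) such that Rd = k_d·μ_d."""

    channel_resistance: float
    droplet_resistance_coefficient: float

    def __post_init__(self) -> None:
        if self.channel_resistance <= 0 or self.droplet_resistance_coefficient <= 0:
            raise InstrumentError("Rc and k_d must be positive")

    def total_resistance(self, droplet_viscosity: float) -> float:
        return self.channel_resistance + self.droplet_resistance_coefficient * droplet_viscosity

    @classmethod
    def from_calibration_endpoints(
        cls,
        geometry: ChannelGeometry,
        op: "OperatingPoint",
        low: tuple[float, float] = CAL_ANCHOR_LOW,
        high: tuple[float, float] = CAL_ANCHOR_HIGH,
    ) -> "HydraulicNetwork":
        """Back-solve Rc, k_d from two (viscosity_cP, passage_time_s) anchors.

        From Δt = l·S·(Rc + k_d·μ)/Δp the slope β and intercept α of the
        affine Δt(μ) law give Rc = α·Δp/(l·S) and k_d = β·Δp/(l·S).
        """
        (mu1, t1), (mu2, t2) = low, high
        if mu1 == mu2:
            raise InstrumentError("calibration anchors need distinct viscosities")
        beta = (t2 - t1) / ((mu2 - mu1) * CP_TO_PA_S)  # s per Pa·s
        alpha = t1 - beta * mu1 * CP_TO_PA_S  # s
        ls = geometry.sensor_separation * geometry.cross_section
        return cls(
            channel_resistance=alpha * op.pressure_difference / ls,
            droplet_resistance_coefficient=beta * op.pressure_difference / ls,
        )


class TransitResult(NamedTuple):
    """Kinematics and flow diagnostics of one plug transit."""

    passage_time: float      # s, sensor-to-sensor
    speed: float             # m/s
    flow_rate: float         # m³/s
    capillary_number: float  # dimensionless (nan if oil not given)
    interface_shear_rate: float  # s⁻¹


@dataclass(frozen=True)
class SensorModel:
    """Photodetector response and noise model.

    The interior of a plug attenuates the LED light, so the sensor voltage
    inside the plug follows the affine map ``V = intercept + slope·OD``; the
    defaults are anchored to the measured endpoints (OD 2.5 ↔ 1.8 a.u.,
    OD 0.05 ↔ 2.3 a.u.). Each meniscus (oil–water cap) produces a sharp
    voltage spike which delimits the plug in the trace.
    """

    baseline_voltage: float = 2.5
    od_voltage_slope: float = (1.8 - 2.3) / (2.5 - 0.05)   # a.u. per OD ≈ -0.20408
    od_voltage_intercept: float = 2.3 + 0.5 / 2.45 * 0.05  # a.u. ≈ 2.3102
    spike_amplitude: float = 0.3
    spike_width: float = 0.02       # s, full support of the meniscus spike
    spike_polarity: int = +1
    voltage_noise_rms: float = 5e-5
    sampling_rate: float = 2000.0
    # single-transit timing jitter; the default back-solves the two-sigma
    # resolution criterion 2·σ_Δt·(dμ/dΔt) = 0.05 cP at the 100-mbar slope,
    # i.e. σ_Δt = 0.05·β/2 ≈ 0.011207 s with β = 13/29 s/cP
    passage_time_jitter: float = 0.05 * BETA_S_PER_CP / 2.0
    # event-level noise on the time-averaged interior signal (a.u.)
    integrated_signal_noise_rms: float = 5e-5

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise InstrumentError("sampling_rate must be positive")
        if self.voltage_noise_rms < 0 or self.passage_time_jitter < 0:
            raise InstrumentError("noise magnitudes must be non-negative")

    def voltage_of_od(self, od: np.ndarray | float) -> np.ndarray | float:
        return self.od_voltage_intercept + self.od_voltage_slope * np.asarray(od, dtype=float)



@dataclass
class VoltageTrace:
    """Uniformly sampled photodetector voltage window around one sensor event."""

    start_time: float
    sampling_rate: float
    samples: np.ndarray
    sensor_id: str = "A"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InstrumentError("a trace needs at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sampling_rate

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, "voltage_au": self.samples})


class Instrument(NamedTuple):
    """Bundle of the four static instrument descriptions."""

    geometry: ChannelGeometry
    oil: ContinuousPhase
    network: HydraulicNetwork
    sensor: SensorModel


def plug_length(volume: float, geometry: ChannelGeometry) -> float:
    """Length of a cylindrical plug of ``volume`` in the tube (m).

    End caps are ignored: at the default operating point the plug is ~6
    diameters long, so the cap correction is small.
    """
    if volume <= 0:
        raise InstrumentError("volume must be positive")
    return volume / geometry.cross_section


def tube_resistance(viscosity: float, length: float, radius: float) -> float:
    """Hagen–Poiseuille resistance 8μL/(πr⁴) of a circular tube (Pa·s·m⁻³)."""
    if viscosity <= 0 or length <= 0 or radius <= 0:
        raise InstrumentError("viscosity, length and radius must all be positive")
    return 8.0 * viscosity * length / (math.pi * radius**4)


def capillary_number(oil_viscosity: float, speed: float, interfacial_tension: float) -> float:
    """Ca = μ_o·v/γ, the viscous-to-interfacial force ratio."""
    if interfacial_tension == 0:
        raise ZeroDivisionError("interfacial tension must be nonzero")
    return oil_viscosity * speed / interfacial_tension


def interface_shear_rate(
    speed: float, geometry: ChannelGeometry, coefficient: float = DEFAULT_SHEAR_COEFFICIENT
) -> float:
    """Estimated shear rate at the plug interface, c_s·v/r (s⁻¹).

    The shear rate vanishes on the plug centerline and peaks at the oil–water
    interface; ``coefficient`` is a calibrated lumped factor standing in for
    the full film-flow solution.
    """
    if coefficient <= 0:
        raise InstrumentError("shear coefficient must be positive")
    return coefficient * speed / geometry.radius


def passage_time(
    droplet: DropletState,
    geometry: ChannelGeometry,
    network: HydraulicNetwork,
    op: OperatingPoint,
    oil: Optional[ContinuousPhase] = None,
    shear_coefficient: float = DEFAULT_SHEAR_COEFFICIENT,
) -> TransitResult:
    """Closed-form transit of a plug between the two sensors.

    Δt = l·S·(Rc + k_d·μ_d)/Δp; the speed, flow rate, capillary number and
    interface shear rate follow from Δt. Emits :class:`ModelValidityWarning`
    above 50 cP, where monodisperse plug formation was not validated.
    """
    if droplet.viscosity_cp > VALIDITY_LIMIT_CP:
        warnings.warn(
            f"droplet viscosity {droplet.viscosity_cp:.1f} cP exceeds the "
            f"{VALIDITY_LIMIT_CP:.0f} cP validated range",
            ModelValidityWarning,
            stacklevel=2,
        )
    l, s = geometry.sensor_separation, geometry.cross_section
    dt = l * s * network.total_resistance(droplet.viscosity) / op.pressure_difference
    v = l / dt
    q = v * s
    if oil is not None:
        ca = capillary_number(oil.viscosity, v, oil.interfacial_tension)
    else:
        ca = math.nan
    shear = interface_shear_rate(v, geometry, shear_coefficient)
    return TransitResult(dt, v, q, ca, shear)


def integrate_transit(
    droplet: DropletState,
    geometry: ChannelGeometry,
    network: HydraulicNetwork,
    op: OperatingPoint,
    dt_step: float = 1e-3,
) -> float:
    """Passage time by explicit time-stepping of the plug position (s).

    Steps dx/dt = Δp/(S·(Rc + k_d·μ_d)) until the plug front has covered the
    sensor separation, interpolating the crossing inside the final step. Used
    as an internal cross-check of the closed form.
    """
    v = op.pressure_difference / (geometry.cross_section * network.total_resistance(droplet.viscosity))
    x, t = 0.0, 0.0
    target = geometry.sensor_separation
    while x < target:
        step = v * dt_step
        if x + step >= target:
            t += (target - x) / v
            x = target
        else:
            x += step
            t += dt_step
    return t


def _render_trace(
    start_time: float,
    front_time: float,
    pass_duration: float,
    droplet: DropletState,
    sensor: SensorModel,
    rng: Optional[np.random.Generator],
    window_pad: float,
    sensor_id: str,
) -> VoltageTrace:
    fs = sensor.sampling_rate
    n = int(round((2 * window_pad + pass_duration) * fs)) + 1
    t = start_time + np.arange(n) / fs
    volts = np.full(n, sensor.baseline_voltage)
    back_time = front_time + pass_duration
    inside = (t >= front_time) & (t <= back_time)
    s_pos = np.clip((t[inside] - front_time) / pass_duration, 0.0, 1.0)
    volts[inside] = sensor.voltage_of_od(droplet.od_at(s_pos))
    sigma = sensor.spike_width / 4.0
    for tm in (front_time, back_time):
        mask = np.abs(t - tm) <= sensor.spike_width
        volts[mask] += sensor.spike_polarity * sensor.spike_amplitude * np.exp(
            -((t[mask] - tm) ** 2) / (2.0 * sigma**2)
        )
    if rng is not None and sensor.voltage_noise_rms > 0:
        volts += rng.normal(0.0, sensor.voltage_noise_rms, size=n)
    return VoltageTrace(start_time=start_time, sampling_rate=fs, samples=volts, sensor_id=sensor_id)


def simulate_transit(
    droplet: DropletState,
    geometry: ChannelGeometry,
    network: HydraulicNetwork,
    op: OperatingPoint,
    sensor: SensorModel,
    rng: Optional[np.random.Generator] = None,
    oil: Optional[ContinuousPhase] = None,
    window_pad: float = 1.0,
) -> tuple[VoltageTrace, VoltageTrace, float]:
    """Synthesize the two sensor voltage windows for one plug transit.

    Returns ``(trace_A, trace_B, true_passage_time)``. Each window spans
    ``±window_pad`` seconds around the plug's pass over that sensor: oil
    baseline outside the plug, meniscus spike at each cap, interior voltage
    from the OD map assuming constant speed, and additive Gaussian noise.
    Sensor B's event is delayed by Δt plus one timing-jitter draw. Pass
    ``rng=None`` for a noise- and jitter-free transit.
    """
    result = passage_time(droplet, geometry, network, op, oil=oil)
    tau = plug_length(droplet.volume, geometry) / result.speed
    n_interior = int(tau * (1.0 - 0.2) * sensor.sampling_rate)
    if n_interior < 20:
        raise InstrumentError(
            f"sampling too coarse: only {n_interior} interior samples would resolve the plug"
        )
    jitter = 0.0
    if rng is not None and sensor.passage_time_jitter > 0:
        jitter = rng.normal(0.0, sensor.passage_time_jitter)
    trace_a = _render_trace(0.0, window_pad, tau, droplet, sensor, rng, window_pad, "A")
    offset = result.passage_time + jitter
    trace_b = _render_trace(offset, offset + window_pad, tau, droplet, sensor, rng, window_pad, "B")
    return trace_a, trace_b, result.passage_time


def default_instrument() -> Instrument:
    """The reference instrument: printed hardware constants with Rc and k_d
    back-solved from the two-point viscosity calibration at 100 mbar."""
    geometry = ChannelGeometry()
    oil = ContinuousPhase()
    op = OperatingPoint.from_mbar(100.0)
    network = HydraulicNetwork.from_calibration_endpoints(geometry, op)
    sensor = SensorModel()
    return Instrument(geometry, oil, network, sensor)
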
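"""Ground-truth growth scenarios and synthetic measurement runs.

This module stands in for the physical instrument. It generates coupled
optical-density / viscosity trajectories of a bacterial batch culture grown
inside a circulating droplet over 48 h, adds the replicate-to-replicate and
per-transit measurement variability of the viscometer, and emits the same
event records (passage time, integrated interior signal) the real pipeline
would produce.

Model of the culture
--------------------
OD follows a logistic rise (lag → log → stationary) with a slow linear
decline in the death phase:

    OD(t) = OD0 + (OD_max − OD0) / (1 + e^(−k(t − t_i))) − m·max(0, t − t_s)

Viscosity is slaved to the OD rise up to the OD inflexion t_i, where it
peaks, and then relaxes exponentially toward a long-time plateau:

    t ≤ t_i:  μ(t) = μ_base + (μ_max − μ_base)·ρ(t)^p,
              ρ(t) = (OD(t) − OD0) / (OD(t_i) − OD0)
    t > t_i:  μ(t) = μ_inf + (μ_max − μ_inf)·e^(−(t − t_i)/τ)

The exponent ``p`` (default 2) keeps the lag phase rheologically quiet —
viscosity stays near μ_base while OD creeps up — which is the observed
behaviour; ``p = 1`` recovers a strictly linear OD–viscosity coupling. The
peak viscosity depends on the driving pressure (higher pressure → higher
shear → weaker bacterial aggregation → lower peak): 23.31 / 10 / 5.5 cP at
100 / 200 / 300 mbar.

Spatial structure: below ~5 cP the plug interior is optically uniform; at
intermediate viscosities on the way up it develops a few patchy aggregates;
above ~15 cP (pre-peak) a single conglomerate sits in the trailing quarter of
the plug; after the peak the interior is homogeneous again at any viscosity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .instrument import (
    DropletState,
    Instrument,
    ModelValidityWarning,
    OperatingPoint,
    VoltageTrace,
    default_instrument,
    passage_time,
    simulate_transit,
)

MAX_EVENTS = 1_000_000  # desk-scale guard
CALIBRATION_HARD_LIMIT_CP = 60.0  # droplet formation fails above this


@dataclass(frozen=True)
class OdParams:
    """Logistic-plus-death parameters of the OD trajectory (a.u., h)."""

    od0: float = 0.05
    od_max: float = 2.83
    k_growth: float = 1.0        # h⁻¹, logistic rate
    t_inflex: float = 6.0        # h, logistic midpoint = OD inflexion
    t_stationary: float = 12.0   # h, onset of the death-phase decline
    death_slope: float = 0.0064  # a.u./h


@dataclass(frozen=True)
class ViscParams:
    """Viscosity trajectory parameters (cP, h)."""

    mu_base: float = 1.83
    mu_max_by_pressure: dict = field(
        default_factory=lambda: {100: 23.31, 200: 10.0, 300: 5.5}
    )
    mu_inf: float = 5.5
    decay_tau: float = 6.0           # h, post-peak relaxation time
    coupling_exponent: float = 2.0   # p in the pre-peak OD–viscosity coupling
    # regime thresholds (cP) for the spatial aggregate structure
    patchy_threshold: float = 5.0
    conglomerate_threshold: float = 15.0

    def mu_max(self, pressure_mbar: float) -> float:
        try:
            return self.mu_max_by_pressure[int(round(pressure_mbar))]
        except KeyError:
            raise KeyError(
                f"no peak viscosity configured for {pressure_mbar} mbar; "
                f"known pressures: {sorted(self.mu_max_by_pressure)}"
            ) from None


@dataclass(frozen=True)
class ReplicateCV:
    """Coefficients of variation of the per-replicate lognormal factors,
    back-solved from the measured replicate SDs (0.38/1.83, 1.86/23.31,
    0.07/2.83)."""

    mu_base: float = 0.21
    mu_max: float = 0.08
    od_max: float = 0.025


@dataclass(frozen=True)
class GrowthScenario:
    """One 48-h culture-in-a-droplet measurement campaign."""

    pressure_mbar: float = 100.0
    od_params: OdParams = field(default_factory=OdParams)
    visc_params: ViscParams = field(default_factory=ViscParams)
    replicate_cv: ReplicateCV = field(default_factory=ReplicateCV)
    cadence_min: float = 10.0
    duration_h: float = 48.0
    n_replicates: int = 10

    def __post_init__(self) -> None:
        p = self.od_params
        if not (p.od_max > p.od0 > 0):
            raise ValueError("require OD_max > OD0 > 0")
        v = self.visc_params
        if not (v.mu_max(self.pressure_mbar) >= v.mu_base > 0) or v.mu_inf <= 0:
            raise ValueError("require mu_max >= mu_base > 0 and mu_inf > 0")
        if self.cadence_min <= 0 or self.duration_h <= 0 or self.n_replicates < 1:
            raise ValueError("cadence, duration and replicate count must be positive")

    @property
    def times_h(self) -> np.ndarray:
        n_ticks = int(round(self.duration_h * 60.0 / self.cadence_min)) + 1
        return np.arange(n_ticks) * self.cadence_min / 60.0


def od_curve(t: np.ndarray | float, od: OdParams = OdParams()) -> np.ndarray | float:
    """Ground-truth OD at time ``t`` (h), floored at OD0."""
    t = np.asarray(t, dtype=float)
    logistic = od.od0 + (od.od_max - od.od0) / (1.0 + np.exp(-od.k_growth * (t - od.t_inflex)))
    value = logistic - od.death_slope * np.maximum(0.0, t - od.t_stationary)
    out = np.maximum(value, od.od0)
    return out if out.shape else float(out)


def viscosity_curve(
    t: np.ndarray | float,
    visc: ViscParams = ViscParams(),
    od: OdParams = OdParams(),
    pressure_mbar: float = 100.0,
) -> np.ndarray | float:
    """Ground-truth viscosity in cP at time ``t`` (h); continuous at the peak."""
    t = np.asarray(t, dtype=float)
    mu_max = visc.mu_max(pressure_mbar)
    od_i = od_curve(od.t_inflex, od)
    rho = (np.asarray(od_curve(np.minimum(t, od.t_inflex), od)) - od.od0) / (od_i - od.od0)
    rising = visc.mu_base + (mu_max - visc.mu_base) * np.clip(rho, 0.0, 1.0) ** visc.coupling_exponent
    falling = visc.mu_inf + (mu_max - visc.mu_inf) * np.exp(-(t - od.t_inflex) / visc.decay_tau)
    out = np.where(t <= od.t_inflex, rising, falling)
    return out if out.shape else float(out)


def classify_regime(viscosity_cp: float, pre_peak: bool, visc: ViscParams = ViscParams()) -> str:
    """Spatial aggregate regime of the plug interior."""
    if not pre_peak or viscosity_cp < visc.patchy_threshold:
        return "uniform"
    if viscosity_cp <= visc.conglomerate_threshold:
        return "patchy"
    return "rear_conglomerate"


class OdProfile:
    """Piecewise-constant axial OD profile over equal bins of s ∈ [0, 1].

    The bin mean equals the plug-average OD exactly, so a linear OD→voltage
    sensor map time-averaged over the interior reproduces the plug OD.
    """

    def __init__(self, values: np.ndarray, regime: str):
        self.values = np.asarray(values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("od profile must be non-negative")
        self.regime = regime

    def __call__(self, s: np.ndarray) -> np.ndarray:
        idx = np.clip((np.asarray(s) * len(self.values)).astype(int), 0, len(self.values) - 1)
        return self.values[idx]

    def mean(self) -> float:
        return float(self.values.mean())


def spatial_profile(
    true_od: float,
    true_viscosity_cp: float,
    pre_peak: bool,
    rng: np.random.Generator,
    visc: ViscParams = ViscParams(),
    n_support: int = 200,
) -> OdProfile:
    """Generate an axial OD profile for the given regime.

    The profile shape has unit mean by construction, so the spatial mean of
    the returned profile equals ``true_od`` to machine precision.
    """
    if true_od < 0 or true_viscosity_cp < 0:
        raise ValueError("od and viscosity must be non-negative")
    regime = classify_regime(true_viscosity_cp, pre_peak, visc)
    s = (np.arange(n_support) + 0.5) / n_support
    if regime == "uniform":
        shape = np.ones(n_support)
    elif regime == "patchy":
        n_bumps = int(rng.integers(2, 5))
        bump = np.zeros(n_support)
        for _ in range(n_bumps):
            c = rng.uniform(0.1, 0.9)
            w = rng.uniform(0.03, 0.08)
            a = rng.uniform(0.5, 1.5)
            bump += a * np.exp(-((s - c) ** 2) / (2 * w**2))
        shape = 0.7 + 0.3 * bump / bump.mean()
    else:  # rear_conglomerate: one large aggregate in the trailing quarter
        g = np.exp(-((s - 0.88) ** 2) / (2 * 0.05**2))
        shape = 0.55 + 0.45 * g / g.mean()
    return OdProfile(true_od * shape, regime)


def cfu_from_od(od: float, factor: float = 8e8) -> float:
    """Viable count (CFU/mL) from OD via a linear plate-count calibration.

    ``factor`` is a configurable conventional value; no measured conversion
    factor is available for this instrument.
    """
    if od < 0:
        raise ValueError("od must be non-negative")
    return factor * od


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Multiplicative lognormal factor with mean exactly 1 and the given CV."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def _event_noise(
    instrument: Instrument, scenario_pressure_mbar: float
) -> tuple[OperatingPoint, float, float]:
    op = OperatingPoint.from_mbar(scenario_pressure_mbar)
    sensor = instrument.sensor
    return op, sensor.passage_time_jitter, sensor.integrated_signal_noise_rms


def generate_run(
    scenario: GrowthScenario = GrowthScenario(),
    instrument: Optional[Instrument] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full replicated growth campaign at event level.

    Returns ``(events, truth)``. ``events`` has one row per replicate per
    cadence tick with the measured passage time and integrated interior
    signal; ``truth`` holds the underlying OD, viscosity and spatial regime.
    Per-replicate biological variability enters as mean-one lognormal factors
    on μ_base, μ_max and OD_max; per-transit measurement noise as Gaussian
    timing jitter and integrated-signal noise.
    """
    instrument = instrument or default_instrument()
    rng = rng if rng is not None else np.random.default_rng()
    times = scenario.times_h
    if scenario.n_replicates * times.size > MAX_EVENTS:
        raise ValueError(
            f"run would produce {scenario.n_replicates * times.size} events "
            f"(> {MAX_EVENTS}); reduce duration, cadence or replicates"
        )
    op, sigma_dt, sigma_sig = _event_noise(instrument, scenario.pressure_mbar)
    geometry, _, network, sensor = instrument

    ev_rows, truth_rows = [], []
    for rep in range(scenario.n_replicates):
        cv = scenario.replicate_cv
        f_base = _lognormal_factor(rng, cv.mu_base)
        f_max = _lognormal_factor(rng, cv.mu_max)
        f_od = _lognormal_factor(rng, cv.od_max)
        odp = replace(scenario.od_params, od_max=scenario.od_params.od_max * f_od)
        mu_max0 = scenario.visc_params.mu_max(scenario.pressure_mbar)
        vp = replace(
            scenario.visc_params,
            mu_base=scenario.visc_params.mu_base * f_base,
            mu_max_by_pressure={
                int(round(scenario.pressure_mbar)): max(
                    mu_max0 * f_max, scenario.visc_params.mu_base * f_base
                )
            },
        )
        true_od = np.asarray(od_curve(times, odp))
        true_mu = np.asarray(viscosity_curve(times, vp, odp, scenario.pressure_mbar))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ModelValidityWarning)
            dt_true = np.array(
                [
                    passage_time(DropletState.from_cp(mu), geometry, network, op).passage_time
                    for mu in true_mu
                ]
            )
        dt_meas = dt_true + (rng.normal(0.0, sigma_dt, times.size) if sigma_dt > 0 else 0.0)
        sig_true = np.asarray(sensor.voltage_of_od(true_od))
        sig_meas = sig_true + (rng.normal(0.0, sigma_sig, times.size) if sigma_sig > 0 else 0.0)
        regimes = [
            classify_regime(mu, t <= odp.t_inflex, scenario.visc_params)
            for mu, t in zip(true_mu, times)
        ]
        ev_rows.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "t_h": times,
                    "passage_time_s": dt_meas,
                    "integrated_signal_au": sig_meas,
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "t_h": times,
                    "true_od_au": true_od,
                    "true_visc_cP": true_mu,
                    "regime": regimes,
                }
            )
        )
    events = pd.concat(ev_rows, ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    return events, truth


def simulate_growth_traces(
    scenario: GrowthScenario,
    instrument: Optional[Instrument] = None,
    rng: Optional[np.random.Generator] = None,
    max_traces: int = 200,
) -> list[dict]:
    """Trace-level variant of :func:`generate_run` for small runs.

    Returns one record per replicate per tick with the two synthesized
    :class:`VoltageTrace` windows and the ground truth. Refuses runs larger
    than ``max_traces`` transits — full-length trace-level campaigns are out
    of desk scale; use the event-level generator instead.
    """
    instrument = instrument or default_instrument()
    rng = rng if rng is not None else np.random.default_rng()
    times = scenario.times_h
    n = scenario.n_replicates * times.size
    if n > max_traces:
        raise ValueError(
            f"{n} trace-level transits requested (> {max_traces}); "
            "use generate_run for event-level campaigns"
        )
    geometry, oil, network, sensor = instrument
    op = OperatingPoint.from_mbar(scenario.pressure_mbar)
    records = []
    for rep in range(scenario.n_replicates):
        for t in times:
            mu = float(viscosity_curve(t, scenario.visc_params, scenario.od_params, scenario.pressure_mbar))
            od = float(od_curve(t, scenario.od_params))
            profile = spatial_profile(
                od, mu, t <= scenario.od_params.t_inflex, rng, scenario.visc_params
            )
            droplet = DropletState.from_cp(mu, od_profile=profile)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ModelValidityWarning)
                trace_a, trace_b, dt_true = simulate_transit(
                    droplet, geometry, network, op, sensor, rng, oil=oil
                )
            records.append(
                {
                    "replicate": rep,
                    "t_h": float(t),
                    "trace_a": trace_a,
                    "trace_b": trace_b,
                    "true_passage_time_s": dt_true,
                    "true_od_au": od,
                    "true_visc_cP": mu,
                    "regime": profile.regime,
                }
            )
    return records


def generate_calibration_set(
    standards_cp: list[float],
    instrument: Optional[Instrument] = None,
    n_rep: int = 10,
    rng: Optional[np.random.Generator] = None,
    pressure_mbar: float = 100.0,
) -> pd.DataFrame:
    """Synthetic viscosity-standard measurements (water–glycerol analogues).

    Standards are entered with externally known viscosities; each is measured
    ``n_rep`` times with the event-level timing-noise model. Returns columns
    ``label, known_value, measured_value`` (cP, s).
    """
    instrument = instrument or default_instrument()
    rng = rng if rng is not None else np.random.default_rng()
    for mu in standards_cp:
        if mu <= 0:
            raise ValueError(f"standard viscosity must be positive, got {mu}")
        if mu > CALIBRATION_HARD_LIMIT_CP:
            raise ValueError(
                f"standard {mu} cP refused: droplet formation fails above "
                f"{CALIBRATION_HARD_LIMIT_CP:.0f} cP"
            )
    op, sigma_dt, _ = _event_noise(instrument, pressure_mbar)
    geometry, _, network, _ = instrument
    rows = []
    for mu in standards_cp:
        dt_true = passage_time(DropletState.from_cp(mu), geometry, network, op).passage_time
        noise = rng.normal(0.0, sigma_dt, n_rep) if sigma_dt > 0 else np.zeros(n_rep)
        for i in range(n_rep):
            rows.append(
                {"label": f"{mu:g}cP", "known_value": mu, "measured_value": dt_true + noise[i]}
            )
    return pd.DataFrame(rows)


def negative_control_run(
    duration_h: float = 48.0,
    instrument: Optional[Instrument] = None,
    rng: Optional[np.random.Generator] = None,
    cadence_min: float = 10.0,
    pressure_mbar: float = 100.0,
    mu_base_cp: float = 1.83,
    od0: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sterile-nutrient control: constant true viscosity and OD, measurement
    noise only. Returns ``(events, truth)`` in the same layout as
    :func:`generate_run` with a single replicate."""
    instrument = instrument or default_instrument()
    rng = rng if rng is not None else np.random.default_rng()
    op, sigma_dt, sigma_sig = _event_noise(instrument, pressure_mbar)
    geometry, _, network, sensor = instrument
    n_ticks = int(round(duration_h * 60.0 / cadence_min)) + 1
    if n_ticks > MAX_EVENTS:
        raise ValueError("run exceeds the desk-scale event guard")
    times = np.arange(n_ticks) * cadence_min / 60.0
    dt_true = passage_time(DropletState.from_cp(mu_base_cp), geometry, network, op).passage_time
    dt_meas = dt_true + (rng.normal(0.0, sigma_dt, n_ticks) if sigma_dt > 0 else 0.0)
    sig_true = float(sensor.voltage_of_od(od0))
    sig_meas = sig_true + (rng.normal(0.0, sigma_sig, n_ticks) if sigma_sig > 0 else 0.0)
    events = pd.DataFrame(
        {
            "replicate": 0,
            "t_h": times,
            "passage_time_s": dt_meas,
            "integrated_signal_au": sig_meas,
        }
    )
    truth = pd.DataFrame(
        {
            "replicate": 0,
            "t_h": times,
            "true_od_au": od0,
            "true_visc_cP": mu_base_cp,
            "regime": "uniform",
        }
    )
    return events, truth
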
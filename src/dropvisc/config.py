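"""Layered configuration: built-in defaults ← file (YAML/JSON) ← overrides.

All user-facing values are in bench units (mm, µL, cP, mbar, mN/m); the
conversion to SI happens once, here, when the domain objects are built.
Unknown keys and out-of-range values raise :class:`ConfigError` naming the
offending key.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any, Optional

import yaml

from .growth import SegmentationParams
from .instrument import (
    ChannelGeometry,
    ContinuousPhase,
    HydraulicNetwork,
    Instrument,
    OperatingPoint,
    SensorModel,
)
from .signals import DetectionParams
from .synthetic import GrowthScenario, OdParams, ReplicateCV, ViscParams


class ConfigError(ValueError):
    """Invalid or unknown configuration entry."""


DEFAULT_CONFIG: dict = {
    "geometry": {
        "inner_diameter_mm": 0.8,
        "sensor_separation_m": 1.0,
        "loop_length_m": 1.2,
    },
    "oil": {
        "viscosity_cP": 0.395,
        "interfacial_tension_mN_per_m": 19.0,
        "label": "HFE-7200 + 5% PFO",
    },
    "operating_point": {"pressure_mbar": 100.0, "temperature_C": 37.0},
    "droplet": {"volume_uL": 2.4},
    "sensor": {
        "baseline_voltage_au": 2.5,
        "spike_amplitude_au": 0.3,
        "spike_width_s": 0.02,
        "spike_polarity": 1,
        "voltage_noise_rms_au": 5e-5,
        "sampling_rate_hz": 2000.0,
        "passage_time_jitter_s": 0.05 * (13.0 / 29.0) / 2.0,
        "integrated_signal_noise_rms_au": 5e-5,
    },
    "network": {
        # two-point calibration anchors fixing Rc and k_d
        "anchor_low_cP": 1.0,
        "anchor_low_s": 103.0,
        "anchor_high_cP": 30.0,
        "anchor_high_s": 116.0,
        "anchor_pressure_mbar": 100.0,
    },
    "detection": {
        "prominence_factor": 4.0,
        "min_prominence_au": 0.01,
        "guard_fraction": 0.10,
        "min_interior_samples": 20,
    },
    "scenario": {
        "pressure_mbar": 100.0,
        "cadence_min": 10.0,
        "duration_h": 48.0,
        "n_replicates": 10,
        "od": {
            "od0": 0.05,
            "od_max": 2.83,
            "k_growth_per_h": 1.0,
            "t_inflex_h": 6.0,
            "t_stationary_h": 12.0,
            "death_slope_per_h": 0.0064,
        },
        "viscosity": {
            "mu_base_cP": 1.83,
            "mu_max_cP_by_pressure": {"100": 23.31, "200": 10.0, "300": 5.5},
            "mu_inf_cP": 5.5,
            "decay_tau_h": 6.0,
            "coupling_exponent": 2.0,
            "patchy_threshold_cP": 5.0,
            "conglomerate_threshold_cP": 15.0,
        },
        "replicate_cv": {"mu_base": 0.21, "mu_max": 0.08, "od_max": 0.025},
    },
    "analysis": {
        "smooth_window_ticks": 3,
        "lag_fraction": 0.05,
        "plateau_fraction": 0.05,
        "decline_ticks": 3,
        "min_dynamic_range_au": 0.1,
    },
}

_POSITIVE_KEYS = {
    "inner_diameter_mm",
    "sensor_separation_m",
    "loop_length_m",
    "viscosity_cP",
    "interfacial_tension_mN_per_m",
    "pressure_mbar",
    "volume_uL",
    "sampling_rate_hz",
    "cadence_min",
    "duration_h",
    "mu_base_cP",
    "mu_inf_cP",
    "decay_tau_h",
    "od0",
    "od_max",
}


def _merge(base: dict, update: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in update.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and key != "mu_max_cP_by_pressure":
            if not isinstance(value, dict):
                raise ConfigError(f"{here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def _validate(cfg: dict, path: str = "") -> None:
    for key, value in cfg.items():
        here = f"{path}.{key}" if path else str(key)
        if isinstance(value, dict) and key != "mu_max_cP_by_pressure":
            _validate(value, here)
        elif "replicate_cv" in path:
            if not isinstance(value, (int, float)) or value < 0:
                raise ConfigError(f"{here} must be a non-negative number, got {value!r}")
        elif key in _POSITIVE_KEYS:
            if not isinstance(value, (int, float)) or value <= 0:
                raise ConfigError(f"{here} must be a positive number, got {value!r}")


def load_config(
    path: Optional[str | Path] = None, overrides: Optional[dict] = None
) -> dict:
    """Merge built-in defaults, an optional YAML/JSON file, and overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"configuration file not found: {path}")
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data:
            cfg = _merge(cfg, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    _validate(cfg)
    return cfg


def build_instrument(cfg: dict) -> Instrument:
    g, o, s, n = cfg["geometry"], cfg["oil"], cfg["sensor"], cfg["network"]
    geometry = ChannelGeometry(
        inner_diameter=g["inner_diameter_mm"] * 1e-3,
        sensor_separation=g["sensor_separation_m"],
        loop_length=g["loop_length_m"],
    )
    oil = ContinuousPhase(
        viscosity=o["viscosity_cP"] * 1e-3,
        interfacial_tension=o["interfacial_tension_mN_per_m"] * 1e-3,
        label=o["label"],
    )
    network = HydraulicNetwork.from_calibration_endpoints(
        geometry,
        OperatingPoint.from_mbar(n["anchor_pressure_mbar"]),
        low=(n["anchor_low_cP"], n["anchor_low_s"]),
        high=(n["anchor_high_cP"], n["anchor_high_s"]),
    )
    sensor = SensorModel(
        baseline_voltage=s["baseline_voltage_au"],
        spike_amplitude=s["spike_amplitude_au"],
        spike_width=s["spike_width_s"],
        spike_polarity=int(s["spike_polarity"]),
        voltage_noise_rms=s["voltage_noise_rms_au"],
        sampling_rate=s["sampling_rate_hz"],
        passage_time_jitter=s["passage_time_jitter_s"],
        integrated_signal_noise_rms=s["integrated_signal_noise_rms_au"],
    )
    return Instrument(geometry, oil, network, sensor)


def build_operating_point(cfg: dict) -> OperatingPoint:
    op = cfg["operating_point"]
    return OperatingPoint.from_mbar(op["pressure_mbar"], op["temperature_C"])


def build_scenario(cfg: dict, **overrides: Any) -> GrowthScenario:
    sc = cfg["scenario"]
    od = sc["od"]
    vp = sc["viscosity"]
    mu_max = {int(k): float(v) for k, v in vp["mu_max_cP_by_pressure"].items()}
    kwargs = dict(
        pressure_mbar=sc["pressure_mbar"],
        od_params=OdParams(
            od0=od["od0"],
            od_max=od["od_max"],
            k_growth=od["k_growth_per_h"],
            t_inflex=od["t_inflex_h"],
            t_stationary=od["t_stationary_h"],
            death_slope=od["death_slope_per_h"],
        ),
        visc_params=ViscParams(
            mu_base=vp["mu_base_cP"],
            mu_max_by_pressure=mu_max,
            mu_inf=vp["mu_inf_cP"],
            decay_tau=vp["decay_tau_h"],
            coupling_exponent=vp["coupling_exponent"],
            patchy_threshold=vp["patchy_threshold_cP"],
            conglomerate_threshold=vp["conglomerate_threshold_cP"],
        ),
        replicate_cv=ReplicateCV(**sc["replicate_cv"]),
        cadence_min=sc["cadence_min"],
        duration_h=sc["duration_h"],
        n_replicates=sc["n_replicates"],
    )
    kwargs.update(overrides)
    return GrowthScenario(**kwargs)


def build_detection_params(cfg: dict) -> DetectionParams:
    d = cfg["detection"]
    return DetectionParams(
        prominence_factor=d["prominence_factor"],
        min_prominence=d["min_prominence_au"],
        guard_fraction=d["guard_fraction"],
        min_interior_samples=int(d["min_interior_samples"]),
    )


def build_segmentation_params(cfg: dict) -> SegmentationParams:
    a = cfg["analysis"]
    return SegmentationParams(
        smooth_window=int(a["smooth_window_ticks"]),
        lag_fraction=a["lag_fraction"],
        plateau_fraction=a["plateau_fraction"],
        decline_ticks=int(a["decline_ticks"]),
        min_dynamic_range=a["min_dynamic_range_au"],
    )
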
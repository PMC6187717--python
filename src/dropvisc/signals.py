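"""Droplet-event extraction from photodetector voltage traces.

A plug passing a sensor produces two sharp meniscus spikes (front and back
cap) bracketing an interior plateau whose level encodes the plug's optical
density. Detection finds the spikes by prominence, times the transit between
sensors front-spike to front-spike, and reads the OD channel as the
time-averaged voltage over a guarded interior window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .instrument import VoltageTrace


class NoDropletError(ValueError):
    """The trace does not contain a detectable droplet (fewer than 2 spikes)."""


class SensorOrderError(ValueError):
    """Sensor-B event does not follow the sensor-A event of the same transit."""


class MultipletWarning(UserWarning):
    """More than two qualifying spikes; the outermost pair was used."""


@dataclass(frozen=True)
class DetectionParams:
    """Spike-detection and interior-window settings.

    The prominence threshold is ``prominence_factor`` times a robust noise
    estimate (median absolute successive difference), floored at
    ``min_prominence`` so that pure-noise traces never yield spurious events.
    The interior window shrinks the inter-spike interval by ``guard_fraction``
    on each side to exclude meniscus lensing from the OD average.
    """

    prominence_factor: float = 4.0
    min_prominence: float = 0.01
    guard_fraction: float = 0.10
    min_interior_samples: int = 20


@dataclass(frozen=True)
class DropletEvent:
    """One plug pass over one sensor."""

    sensor_id: str
    front_spike_time: float
    back_spike_time: float
    interior_window: tuple[float, float]
    integrated_signal: float  # time-averaged interior voltage, a.u.
    n_interior_samples: int


def _robust_noise_rms(samples: np.ndarray) -> float:
    d = np.diff(samples)
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / np.sqrt(2.0)


def detect_event(trace: VoltageTrace, params: Optional[DetectionParams] = None) -> DropletEvent:
    """Locate the meniscus spikes and interior window of one plug pass.

    Raises :class:`NoDropletError` when fewer than two spikes qualify; with
    more than two, the outermost pair is taken as the menisci and a
    :class:`MultipletWarning` is emitted.
    """
    params = params or DetectionParams()
    v = trace.samples
    prominence = max(params.prominence_factor * _robust_noise_rms(v), params.min_prominence)
    peaks, _ = find_peaks(v, prominence=prominence)
    if peaks.size < 2:
        raise NoDropletError(
            f"found {peaks.size} qualifying spike(s); a droplet needs a front and a back meniscus"
        )
    if peaks.size > 2:
        warnings.warn(
            f"{peaks.size} spikes found; using the outermost pair", MultipletWarning, stacklevel=2
        )
    t = trace.times
    front, back = float(t[peaks[0]]), float(t[peaks[-1]])
    span = back - front
    w0 = front + params.guard_fraction * span
    w1 = back - params.guard_fraction * span
    mask = (t >= w0) & (t <= w1)
    n = int(mask.sum())
    if n < params.min_interior_samples:
        raise NoDropletError(
            f"only {n} interior samples between the spikes "
            f"(need >= {params.min_interior_samples})"
        )
    return DropletEvent(
        sensor_id=trace.sensor_id,
        front_spike_time=front,
        back_spike_time=back,
        interior_window=(w0, w1),
        integrated_signal=float(v[mask].mean()),
        n_interior_samples=n,
    )


def passage_time_between(event_a: DropletEvent, event_b: DropletEvent) -> float:
    """Sensor-to-sensor passage time, leading edge to leading edge (s).

    The front-spike convention is insensitive to plug-length changes between
    the sensors. Raises :class:`SensorOrderError` for a non-positive result.
    """
    dt = event_b.front_spike_time - event_a.front_spike_time
    if dt <= 0:
        raise SensorOrderError(
            f"sensor-B front spike ({event_b.front_spike_time:.4f} s) does not "
            f"follow sensor-A front spike ({event_a.front_spike_time:.4f} s)"
        )
    return dt


def scan_profile(
    trace: VoltageTrace, event: DropletEvent, n_bins: int = 20
) -> np.ndarray:
    """Along-droplet voltage profile from one sensor pass.

    Partitions the interior window into ``n_bins`` equal time bins and maps
    time fraction to normalized axial position ``s`` under the constant-speed
    assumption (front of the plug at ``s = 0``). Returns an array of shape
    ``(n_bins, 2)`` with columns ``(s_center, mean_voltage)``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    t = trace.times
    w0, w1 = event.interior_window
    mask = (t >= w0) & (t <= w1)
    if mask.sum() < n_bins:
        raise ValueError(f"only {int(mask.sum())} interior samples for {n_bins} bins")
    tt = t[mask]
    vv = trace.samples[mask]
    frac = np.clip((tt - w0) / (w1 - w0), 0.0, 1.0 - 1e-12)
    idx = (frac * n_bins).astype(int)
    centers = (np.arange(n_bins) + 0.5) / n_bins
    means = np.array([vv[idx == i].mean() for i in range(n_bins)])
    return np.column_stack([centers, means])
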
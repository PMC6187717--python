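"""Calibrated growth-curve assembly, phase segmentation and summaries.

Takes event-level measurements (passage time, integrated interior signal) per
replicate, inverts them through the viscosity and OD calibrations, aggregates
replicates, segments the canonical batch-growth phases (lag / log /
stationary / death) from the OD curve, locates the OD inflexion, and reports
summary statistics. Also provides the sterile-control invariance test: under
the null of no growth, the least-squares time slope of viscosity (and OD)
should be statistically indistinguishable from zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import (
    ExtrapolationWarning,
    LinearCalibration,
    NegativeOdWarning,
    default_od_calibration,
    default_viscosity_calibration,
    od_from_signal,
    viscosity_from_time,
)


class NoInflexionError(ValueError):
    """OD curve is flat (or monotone without dynamic range); no inflexion."""


@dataclass
class GrowthRecord:
    """Calibrated (t, viscosity, OD) series of one replicate."""

    replicate: int
    data: pd.DataFrame  # columns: t_h, visc_cP, visc_se, od_au, od_se

    def __post_init__(self) -> None:
        t = self.data["t_h"].to_numpy()
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing within a replicate")


@dataclass
class PhaseSegmentation:
    """Detected growth-phase boundaries (h). ``None`` marks an absent phase
    (e.g. a sterile control never leaves lag)."""

    lag_end: Optional[float]
    od_inflexion: Optional[float]
    log_end: Optional[float]
    stationary_end: Optional[float]
    labels: np.ndarray  # per-point phase label


@dataclass(frozen=True)
class SegmentationParams:
    """Conventions for phase boundaries; the 5%-of-range thresholds and the
    3-tick decline rule are package choices, all overridable."""

    smooth_window: int = 3          # ticks, centered moving average
    lag_fraction: float = 0.05      # of OD dynamic range
    plateau_fraction: float = 0.05  # of OD dynamic range
    decline_ticks: int = 3          # consecutive decreasing ticks = sustained decline
    min_dynamic_range: float = 0.1  # a.u.; below this the curve counts as flat


@dataclass(frozen=True)
class InvarianceResult:
    """Least-squares time-slope test of one channel of a control run."""

    slope_per_h: float
    ci_low: float
    ci_high: float
    passed: bool  # 95% CI covers zero


def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return np.asarray(y, dtype=float)
    return pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()


def assemble(
    events: pd.DataFrame,
    viscosity_cal: Optional[LinearCalibration] = None,
    od_cal: Optional[LinearCalibration] = None,
) -> list[GrowthRecord]:
    """Invert event records into per-replicate (t, μ, OD) series.

    ``events`` needs columns ``replicate, t_h, passage_time_s,
    integrated_signal_au``. Points outside the calibration validity are kept
    and flagged by the calibrations' own warnings (suppressed here to one
    summary warning per run).
    """
    viscosity_cal = viscosity_cal or default_viscosity_calibration()
    od_cal = od_cal or default_od_calibration()
    if events.empty:
        warnings.warn("empty event list; returning no records", UserWarning, stacklevel=2)
        return []
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        warnings.simplefilter("ignore", NegativeOdWarning)
        for rep, grp in events.groupby("replicate"):
            grp = grp.sort_values("t_h")
            mu, mu_se, od, od_se = [], [], [], []
            for _, row in grp.iterrows():
                m, se = viscosity_from_time(float(row["passage_time_s"]), viscosity_cal)
                mu.append(m)
                mu_se.append(se)
                od.append(od_from_signal(float(row["integrated_signal_au"]), od_cal))
                od_se.append(od_cal.predict(float(row["integrated_signal_au"]), check_range=False)[1])
            records.append(
                GrowthRecord(
                    replicate=int(rep),
                    data=pd.DataFrame(
                        {
                            "t_h": grp["t_h"].to_numpy(dtype=float),
                            "visc_cP": mu,
                            "visc_se": mu_se,
                            "od_au": od,
                            "od_se": od_se,
                        }
                    ),
                )
            )
    return records


def aggregate_replicates(records: Sequence[GrowthRecord]) -> pd.DataFrame:
    """Pointwise mean ± SD across replicates on the common time grid."""
    if len(records) < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    ref_t = records[0].data["t_h"].to_numpy()
    columns_mu, columns_od = [], []
    for rec in records:
        t = rec.data["t_h"].to_numpy()
        if t.size != ref_t.size or not np.allclose(t, ref_t, atol=np.median(np.diff(ref_t))):
            raise ValueError("replicates are not on a common cadence grid")
        columns_mu.append(rec.data["visc_cP"].to_numpy())
        columns_od.append(rec.data["od_au"].to_numpy())
    mu = np.vstack(columns_mu)
    od = np.vstack(columns_od)
    return pd.DataFrame(
        {
            "t_h": ref_t,
            "visc_mean_cP": mu.mean(axis=0),
            "visc_sd_cP": mu.std(axis=0, ddof=1),
            "od_mean_au": od.mean(axis=0),
            "od_sd_au": od.std(axis=0, ddof=1),
            "n": len(records),
        }
    )


def od_inflexion(
    t_h: np.ndarray, od_au: np.ndarray, params: Optional[SegmentationParams] = None
) -> float:
    """Time of the OD inflexion: maximum first difference of the smoothed
    curve, assigned to the right edge of the steepest interval, earliest tie
    wins. Raises :class:`NoInflexionError` on a flat curve."""
    params = params or SegmentationParams()
    t = np.asarray(t_h, dtype=float)
    od = np.asarray(od_au, dtype=float)
    if t.size < 7:
        raise ValueError("need at least 7 points to locate an inflexion")
    sm = moving_average(od, params.smooth_window)
    if np.ptp(sm) < params.min_dynamic_range:
        raise NoInflexionError(
            f"OD dynamic range {np.ptp(sm):.3g} a.u. below "
            f"{params.min_dynamic_range:g}; curve is flat"
        )
    d = np.diff(sm)
    i = int(np.argmax(d))  # argmax returns the earliest maximum
    return float(t[i + 1])


def segment_phases(
    t_h: np.ndarray, od_au: np.ndarray, params: Optional[SegmentationParams] = None
) -> PhaseSegmentation:
    """Segment lag / log / stationary / death phases from an OD curve.

    lag ends at the last time the smoothed OD is below OD0 + 5% of range
    (before the maximum); log ends when it first exceeds the observed
    maximum − 5% of range; the stationary phase ends at the last tick before
    a sustained (3-tick) decline. A flat curve (sterile control) is labelled
    lag throughout.
    """
    params = params or SegmentationParams()
    t = np.asarray(t_h, dtype=float)
    od = np.asarray(od_au, dtype=float)
    if t.size < 5:
        raise ValueError("curve too short to segment")
    sm = moving_average(od, params.smooth_window)
    od0, od_max = float(sm.min()), float(sm.max())
    rng = od_max - od0
    labels = np.full(t.size, "lag", dtype=object)
    if rng < params.min_dynamic_range:
        return PhaseSegmentation(float(t[-1]), None, None, None, labels)

    i_max = int(np.argmax(sm))
    below = np.nonzero(sm[: i_max + 1] < od0 + params.lag_fraction * rng)[0]
    i_lag = int(below[-1]) if below.size else 0
    above = np.nonzero(sm > od_max - params.plateau_fraction * rng)[0]
    i_log = int(above[0]) if above.size else i_max
    i_log = max(i_log, i_lag)

    # sustained decline: decline_ticks consecutive decreasing steps after the peak
    i_stat = t.size - 1
    d = np.diff(sm)
    k = params.decline_ticks
    for i in range(i_max, t.size - k):
        if np.all(d[i : i + k] < 0):
            i_stat = i
            break
    i_stat = max(i_stat, i_log)

    try:
        t_inflex = od_inflexion(t, od, params)
    except NoInflexionError:
        t_inflex = None
    if t_inflex is not None:
        t_inflex = min(max(t_inflex, float(t[i_lag])), float(t[i_log]))

    labels[(t > t[i_lag]) & (t <= t[i_log])] = "log"
    labels[(t > t[i_log]) & (t <= t[i_stat])] = "stationary"
    labels[t > t[i_stat]] = "death"
    return PhaseSegmentation(
        lag_end=float(t[i_lag]),
        od_inflexion=t_inflex,
        log_end=float(t[i_log]),
        stationary_end=float(t[i_stat]),
        labels=labels,
    )


def summarize(
    record: GrowthRecord | pd.DataFrame,
    params: Optional[SegmentationParams] = None,
) -> dict:
    """Summary statistics of one calibrated series (or aggregate curve).

    Returns baseline (lag-phase mean) viscosity, the smoothed-curve viscosity
    maximum and its time, the OD maximum, and the final values.
    """
    params = params or SegmentationParams()
    df = record.data if isinstance(record, GrowthRecord) else record
    if df.empty:
        raise ValueError("empty series")
    t = df["t_h"].to_numpy(dtype=float)
    mu = df[[c for c in ("visc_cP", "visc_mean_cP") if c in df]].iloc[:, 0].to_numpy(dtype=float)
    od = df[[c for c in ("od_au", "od_mean_au") if c in df]].iloc[:, 0].to_numpy(dtype=float)
    seg = segment_phases(t, od, params)
    lag_mask = seg.labels == "lag"
    mu_smooth = moving_average(mu, params.smooth_window)
    i_peak = int(np.argmax(mu_smooth))
    return {
        "visc_baseline_cP": float(mu[lag_mask].mean()) if lag_mask.any() else float(mu[0]),
        "visc_max_cP": float(mu_smooth[i_peak]),
        "t_visc_max_h": float(t[i_peak]),
        "od_max_au": float(od.max()),
        "visc_final_cP": float(mu[-1]),
        "od_final_au": float(od[-1]),
        "lag_end_h": seg.lag_end,
        "od_inflexion_h": seg.od_inflexion,
        "log_end_h": seg.log_end,
        "stationary_end_h": seg.stationary_end,
    }


def invariance_test(
    t_h: np.ndarray, values: np.ndarray, alpha: float = 0.05
) -> InvarianceResult:
    """Least-squares slope of a channel vs. time with a (1−α) CI.

    The sterile control passes when the CI covers zero (no temporal trend).
    """
    t = np.asarray(t_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 points for the invariance test")
    res = stats.linregress(t, y)
    if res.stderr == 0:
        return InvarianceResult(float(res.slope), float(res.slope), float(res.slope), res.slope == 0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, t.size - 2)
    lo = res.slope - tcrit * res.stderr
    hi = res.slope + tcrit * res.stderr
    return InvarianceResult(float(res.slope), float(lo), float(hi), bool(lo <= 0.0 <= hi))
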
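"""Linear calibrations of the viscometer and their inversion.

Three affine maps tie the raw observables to the quantities of interest:

* viscosity (cP) vs. passage time (s) — from water–glycerol standards; at
  the reference operating point (100 mbar) the measured endpoints
  (103 s ↔ 1 cP, 116 s ↔ 30 cP) fix the default line μ = (29/13)·Δt − 2974/13;
* optical density (a.u.) vs. time-averaged interior voltage (a.u.) — the
  default line passes through (1.8 a.u. ↔ OD 2.5) and (2.3 a.u. ↔ OD 0.05),
  i.e. OD = −4.9·V + 11.32;
* CFU/mL vs. OD — a plate-count calibration, fitted from user data.

The instrument's viscosity resolution is quoted as twice the single-transit
timing SD expressed in viscosity units (two-sigma criterion): the smallest
viscosity difference whose passage-time distributions are visually separated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
from .instrument import ALPHA_S, BETA_S_PER_CP

VISCOSITY_KIND = "viscosity_vs_passage_time"
OD_KIND = "od_vs_integrated_signal"
CFU_KIND = "cfu_vs_od"


class DegenerateFitError(ValueError):
    """All predictor values identical; no line can be fitted."""


class CalibrationTypeError(TypeError):
    """Calibration used for a quantity it does not map."""


class ExtrapolationWarning(UserWarning):
    """Inversion outside the fitted/valid predictor range."""


class NegativeOdWarning(UserWarning):
    """Inverted OD was negative and has been floored at zero."""


@dataclass
class LinearCalibration:
    """A fitted affine map ``y = slope·x + intercept`` with diagnostics."""

    slope: float
    intercept: float
    kind: str
    x_label: str = "x"
    y_label: str = "y"
    valid_range: tuple[float, float] = (-np.inf, np.inf)
    r_squared: float = 1.0
    residual_sd: float = 0.0
    n_points: int = 2
    x_mean: float = 0.0
    sxx: float = np.inf  # Σ(x−x̄)²; inf ⇒ no parameter uncertainty

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a line needs at least 2 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def predict(self, x: float, check_range: bool = True) -> tuple[float, float]:
        """Evaluate the line at ``x``; returns ``(y, standard_error)``.

        The SE propagates the fit-parameter covariance,
        SE² = s²·(1/n + (x − x̄)²/Sxx). Values outside ``valid_range`` are
        evaluated anyway with an :class:`ExtrapolationWarning`.
        """
        if check_range and not (self.valid_range[0] <= x <= self.valid_range[1]):
            warnings.warn(
                f"{self.kind}: predictor {x:g} outside valid range "
                f"[{self.valid_range[0]:g}, {self.valid_range[1]:g}]",
                ExtrapolationWarning,
                stacklevel=3,
            )
        y = self.slope * x + self.intercept
        if np.isfinite(self.sxx) and self.sxx > 0:
            se = self.residual_sd * np.sqrt(1.0 / self.n_points + (x - self.x_mean) ** 2 / self.sxx)
        else:
            se = 0.0
        return float(y), float(se)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["valid_range"] = list(self.valid_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LinearCalibration":
        d = dict(d)
        d["valid_range"] = tuple(d.get("valid_range", (-np.inf, np.inf)))
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "LinearCalibration":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ResolutionEstimate:
    """Instrument viscosity resolution under the two-sigma criterion."""

    sigma_dt: float        # s, single-transit timing SD
    slope_cp_per_s: float  # cP/s, inverse-calibration slope
    resolution: float      # cP, = 2·sigma_dt·slope
    criterion: str = "two-sigma single-measurement"


def fit_line(
    x: Sequence[float],
    y: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    kind: str = "generic",
    x_label: str = "x",
    y_label: str = "y",
    through_origin: bool = False,
) -> LinearCalibration:
    """Ordinary (or weighted) least-squares line through ``(x, y)`` pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 (x, y) pairs of equal length")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all predictor values are identical")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if through_origin:
        slope = float(np.sum(w * x * y) / np.sum(w * x * x))
        intercept = 0.0
    else:
        wsum = w.sum()
        xm = float(np.sum(w * x) / wsum)
        ym = float(np.sum(w * y) / wsum)
        sxx = float(np.sum(w * (x - xm) ** 2))
        sxy = float(np.sum(w * (x - xm) * (y - ym)))
        slope = sxy / sxx
        intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    dof = x.size - (1 if through_origin else 2)
    residual_sd = float(np.sqrt(ss_res / dof)) if dof > 0 else 0.0
    xm_plain = float(x.mean())
    sxx_plain = float(np.sum((x - xm_plain) ** 2))
    return LinearCalibration(
        slope=float(slope),
        intercept=float(intercept),
        kind=kind,
        x_label=x_label,
        y_label=y_label,
        valid_range=(float(x.min()), float(x.max())),
        r_squared=min(r2, 1.0),
        residual_sd=residual_sd,
        n_points=int(x.size),
        x_mean=xm_plain,
        sxx=sxx_plain,
    )


def fit_viscosity_calibration(
    passage_times_s: Sequence[float], viscosities_cp: Sequence[float]
) -> LinearCalibration:
    """Fit the μ(Δt) inversion line from standards measurements."""
    return fit_line(
        passage_times_s,
        viscosities_cp,
        kind=VISCOSITY_KIND,
        x_label="passage_time_s",
        y_label="viscosity_cP",
    )


def default_viscosity_calibration(pressure_mbar: float = 100.0) -> LinearCalibration:
    """The factory μ(Δt) line from the two measured anchors at 100 mbar.

    At other driving pressures the passage time scales as 1/Δp, so the slope
    scales with pressure while the intercept (in cP) is unchanged.
    """
    scale = pressure_mbar / 100.0
    slope = scale / BETA_S_PER_CP
    intercept = -ALPHA_S / BETA_S_PER_CP
    return LinearCalibration(
        slope=slope,
        intercept=intercept,
        kind=VISCOSITY_KIND,
        x_label="passage_time_s",
        y_label="viscosity_cP",
        valid_range=(103.0 / scale, 116.0 / scale),
    )


def default_od_calibration() -> LinearCalibration:
    """The factory OD(voltage) line through the two measured endpoint pairs."""
    slope = (2.5 - 0.05) / (1.8 - 2.3)  # = -4.9 OD per a.u.
    intercept = 2.5 - slope * 1.8       # = 11.32
    return LinearCalibration(
        slope=slope,
        intercept=intercept,
        kind=OD_KIND,
        x_label="integrated_signal_au",
        y_label="od_au",
        valid_range=(1.8, 2.3),
    )


def viscosity_from_time(dt_s: float, cal: LinearCalibration) -> tuple[float, float]:
    """Invert a passage time to viscosity (cP); returns ``(μ, standard_error)``."""
    if cal.kind != VISCOSITY_KIND:
        raise CalibrationTypeError(
            f"expected a {VISCOSITY_KIND} calibration, got {cal.kind}"
        )
    return cal.predict(dt_s)


def od_from_signal(signal_au: float, cal: Optional[LinearCalibration] = None) -> float:
    """Invert a time-averaged interior voltage to optical density (a.u.).

    Negative inversions (bright droplets beyond the calibration anchor) are
    floored at zero with a :class:`NegativeOdWarning`.
    """
    cal = cal or default_od_calibration()
    if cal.kind != OD_KIND:
        raise CalibrationTypeError(f"expected an {OD_KIND} calibration, got {cal.kind}")
    od, _ = cal.predict(signal_au)
    if od < 0:
        warnings.warn(f"inverted OD {od:.4g} < 0; floored at 0", NegativeOdWarning, stacklevel=2)
        od = 0.0
    return od


def fit_gaussian(passage_times: Sequence[float]) -> tuple[float, float]:
    """Normal fit to a passage-time sample: ``(mean, sd)`` with sample SD."""
    x = np.asarray(passage_times, dtype=float)
    if x.size < 10:
        raise ValueError(f"need at least 10 passage times for a normal fit, got {x.size}")
    return float(x.mean()), float(x.std(ddof=1))


def resolution(sigma_dt: float, cal: LinearCalibration) -> ResolutionEstimate:
    """Viscosity resolution 2·σ_Δt·(dμ/dΔt) from the timing SD (cP)."""
    if sigma_dt < 0:
        raise ValueError("sigma_dt must be non-negative")
    if cal.kind != VISCOSITY_KIND:
        raise CalibrationTypeError(
            f"expected a {VISCOSITY_KIND} calibration, got {cal.kind}"
        )
    return ResolutionEstimate(
        sigma_dt=sigma_dt,
        slope_cp_per_s=cal.slope,
        resolution=2.0 * sigma_dt * abs(cal.slope),
    )


def fit_cfu_calibration(
    od: Sequence[float], cfu: Sequence[float], through_origin: bool = False
) -> LinearCalibration:
    """Linear plate-count calibration CFU/mL vs. OD."""
    return fit_line(
        od,
        cfu,
        kind=CFU_KIND,
        x_label="od_au",
        y_label="cfu_per_ml",
        through_origin=through_origin,
    )
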
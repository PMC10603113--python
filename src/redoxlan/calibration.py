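"""Linear calibration between optical readouts and Fe redox state.

The luminescent nanoprobe reports the Fe2+/Fe_total ratio through a
log-linear law: log10(intensity) = slope * ratio + intercept.  The same
ordinary-least-squares machinery also serves the o-phenanthroline
absorbance standard curve (absorbance at 510 nm versus Fe2+ in mg/L),
so :class:`LinearCalibration` is deliberately unit-agnostic.

The ratio convention is configurable: ``percent`` expresses Fe2+/Fe_total
on 0-100, ``fraction`` on 0-1.  Percent is the default; under it the
reference constants (slope 0.01764, intercept 2.126) span log-intensity
2.126 at fully oxidised iron to 3.890 at fully reduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import (
    CalibrationRangeError,
    DegenerateDesignError,
    InsufficientDataError,
    NonInvertibleCalibrationError,
)

Convention = Literal["percent", "fraction"]

#: Reference constants of the packaged luminescence calibration
#: (log10-intensity per percent ratio unit, and log10-intensity at ratio 0).
REFERENCE_SLOPE = 0.01764
REFERENCE_INTERCEPT = 2.126


@dataclass(frozen=True)
class LinearCalibration:
    """A straight-line calibration ``response = slope * predictor + intercept``.

    Parameters
    ----------
    slope
        Response change per predictor unit.  Must be finite; a zero slope
        yields a non-invertible calibration.
    intercept
        Response at predictor zero.
    convention
        Scale of the Fe2+/Fe_total predictor: ``"percent"`` (0-100,
        default) or ``"fraction"`` (0-1).
    """

    slope: float
    intercept: float
    convention: Convention = "percent"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("slope and intercept must be finite")
        if self.convention not in ("percent", "fraction"):
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def ratio_max(self) -> float:
        """Upper end of the predictor range under this convention."""
        return 100.0 if self.convention == "percent" else 1.0


def reference_calibration(convention: Convention = "percent") -> LinearCalibration:
    """The packaged luminescence calibration of the nanoprobe verifier.

    The slope is stated per percent ratio unit; under the fraction
    convention it is rescaled so the line maps [0, 1] onto the same
    log-intensity span.
    """
    if convention == "percent":
        return LinearCalibration(REFERENCE_SLOPE, REFERENCE_INTERCEPT, "percent")
    return LinearCalibration(REFERENCE_SLOPE * 100.0, REFERENCE_INTERCEPT, "fraction")


def predict_log_intensity(calib: LinearCalibration, ratio: float) -> float:
    """Forward model: log10 luminescence intensity at a given Fe2+/Fe_total ratio.

    Raises
    ------
    CalibrationRangeError
        If ``ratio`` lies outside [0, 100] (percent) or [0, 1] (fraction).
    """
    ratio = float(ratio)
    if not 0.0 <= ratio <= calib.ratio_max:
        raise CalibrationRangeError(
            f"ratio {ratio} outside [0, {calib.ratio_max:g}] for the "
            f"{calib.convention!r} convention"
        )
    return calib.slope * ratio + calib.intercept


@dataclass(frozen=True)
class InverseResult:
    """Inverse prediction with an out-of-range clipping flag."""

    ratio: float
    clipped: bool


def invert_to_ratio(calib: LinearCalibration, log_intensity: float) -> InverseResult:
    """Invert the calibration line: recover the Fe2+/Fe_total ratio.

    Values falling outside the convention range (measurement noise can
    push readouts slightly past the calibrated endpoints) are clipped to
    the range and flagged rather than rejected.
    """
    if calib.slope == 0.0:
        raise NonInvertibleCalibrationError("calibration slope is zero")
    raw = (float(log_intensity) - calib.intercept) / calib.slope
    clipped = not (0.0 <= raw <= calib.ratio_max)
    return InverseResult(float(np.clip(raw, 0.0, calib.ratio_max)), clipped)


def fe2_from_intensity(
    calib: LinearCalibration, intensity: float, fe_total: float
) -> tuple[float, float]:
    """Convert a raw luminescence readout to (Fe2+, Fe3+) concentrations in mM.

    The raw intensity is converted to log10 before inversion; zero or
    negative readouts are rejected because their logarithm is undefined.

    Returns
    -------
    tuple of float
        ``(fe2, fe3)`` with ``fe2 + fe3 == fe_total`` exactly.
    """
    intensity = float(intensity)
    if intensity <= 0.0:
        raise ValueError(f"intensity must be positive, got {intensity}")
    if fe_total <= 0.0:
        raise ValueError(f"fe_total must be positive, got {fe_total}")
    inv = invert_to_ratio(calib, np.log10(intensity))
    fe2 = fe_total * inv.ratio / calib.ratio_max
    return fe2, fe_total - fe2


@dataclass(frozen=True)
class CalibrationFit:
    """OLS standard-curve fit with its residual summary."""

    calibration: LinearCalibration
    rss: float
    pearson_r: float
    n: int
    residuals: np.ndarray = field(repr=False)


def fit_linear_calibration(
    predictors: Sequence[float],
    responses: Sequence[float],
    convention: Convention = "percent",
) -> CalibrationFit:
    """Fit a standard curve by ordinary least squares.

    Requires at least two pairs with at least two distinct predictor
    values.  Reports slope, intercept, residual sum of squares and the
    Pearson correlation of predictor with response (zero when the
    response is constant).
    """
    x = np.asarray(predictors, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predictors and responses must be 1-D and equally long")
    if x.size < 2:
        raise InsufficientDataError(f"need >= 2 pairs, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("all predictor values identical")

    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (slope * x + intercept)
    rss = float(resid @ resid)
    sy = np.std(y)
    r = float(np.corrcoef(x, y)[0, 1]) if sy > 0 else 0.0
    return CalibrationFit(
        calibration=LinearCalibration(float(slope), float(intercept), convention),
        rss=rss,
        pearson_r=r,
        n=int(x.size),
        residuals=resid,
    )
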
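"""Ratiometric pHluorin calibration.

The excitation ratio R = F390/F470 of ratiometric pHluorin responds
sigmoidally to pH.  A four-parameter Boltzmann (log-logistic in pH) curve

    R(pH) = r_min + (r_max - r_min) / (1 + 10 ** (k * (ph_mid - pH)))

is fitted to buffer standards by least squares and inverted in closed form
to convert background-subtracted well ratios to cytosolic pH.  The form is
chosen for the two properties the pipeline needs: strict monotonicity
(k > 0) and analytic invertibility on the open interval (r_min, r_max).

Background is the per-plate, per-channel, per-timepoint mean of the blank
wells.  Ratios that fall outside the invertible interval yield NaN pH with
a warning — single noisy wells must not abort a screen, and clipping would
bias downstream Z-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import CalibrationError, ValidationError
from .plate_io import PlateTimeCourse

__all__ = [
    "CalibrationStandard", "CalibrationCurve", "sigmoid_ratio",
    "subtract_background", "fit_calibration", "ratio_to_ph", "ph_to_ratio",
    "plate_background", "plate_to_ph",
]


@dataclass(frozen=True)
class CalibrationStandard:
    """One buffer standard: known pH and measured (background-free) ratio."""

    ph: float
    ratio: float

    def __post_init__(self) -> None:
        if not 5.0 <= self.ph <= 8.5:
            raise ValidationError(
                f"standard pH {self.ph} outside the usable range [5.0, 8.5]"
            )
        if not self.ratio > 0:
            raise ValidationError(f"standard ratio must be > 0, got {self.ratio}")


def sigmoid_ratio(ph, r_min, r_max, ph_mid, slope_k):
    """Boltzmann response R(pH); increasing in pH for slope_k > 0."""
    ph = np.asarray(ph, dtype=float)
    return r_min + (r_max - r_min) / (1.0 + 10.0 ** (slope_k * (ph_mid - ph)))


@dataclass
class CalibrationCurve:
    """Fitted monotone map between pH and fluorescence ratio."""

    r_min: float
    r_max: float
    ph_mid: float
    slope_k: float
    valid_range: tuple[float, float] = (5.0, 8.5)
    rmse: float = float("nan")

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise CalibrationError(
                f"r_min ({self.r_min}) must be below r_max ({self.r_max})"
            )
        if not self.slope_k > 0:
            raise CalibrationError("slope_k must be positive (monotone curve)")

    def ratio(self, ph):
        """Forward map pH -> ratio."""
        return sigmoid_ratio(ph, self.r_min, self.r_max, self.ph_mid, self.slope_k)

    def ph(self, ratio):
        """Closed-form inverse ratio -> pH; NaN outside (r_min, r_max)."""
        return ratio_to_ph(self, ratio)


def subtract_background(signal, blank):
    """Elementwise ``signal - blank``.

    Values <= 0 after subtraction are unusable for ratioing; callers mask
    them to NaN at the ratio step (see :func:`plate_to_ph`).
    """
    signal = np.asarray(signal, dtype=float)
    blank = np.asarray(blank, dtype=float)
    if signal.shape != blank.shape:
        raise ValidationError(
            f"signal shape {signal.shape} != blank shape {blank.shape}"
        )
    return signal - blank


def fit_calibration(standards) -> CalibrationCurve:
    """Least-squares sigmoid fit through >=5 standards spanning >=1.5 pH units.

    Standards whose rank correlation between pH and ratio is below 0.8
    (non-monotone or degenerate, e.g. a flat line) raise
    :class:`CalibrationError`.
    """
    standards = list(standards)
    ph = np.array([s.ph for s in standards], dtype=float)
    ratio = np.array([s.ratio for s in standards], dtype=float)
    if len(np.unique(ph)) < 5:
        raise ValidationError("need >=5 standards at distinct pH values")
    if np.ptp(ph) < 1.5:
        raise ValidationError(
            f"standards span {np.ptp(ph):.2f} pH units; >=1.5 required"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input warning -> NaN rho
        rho = stats.spearmanr(ph, ratio).statistic
    if not np.isfinite(rho) or rho < 0.8:
        raise CalibrationError(
            f"standards are not monotone in pH (Spearman rho = {rho!r})"
        )
    p0 = (
        max(ratio.min() * 0.9, 1e-6),
        ratio.max() * 1.1,
        float(np.median(ph)),
        1.0,
    )
    bounds = (
        [0.0, 1e-9, ph.min() - 2.0, 1e-3],
        [np.inf, np.inf, ph.max() + 2.0, 1e3],
    )
    try:
        popt, _ = optimize.curve_fit(
            sigmoid_ratio, ph, ratio, p0=p0, bounds=bounds, maxfev=20000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except RuntimeError as exc:
        raise CalibrationError(f"calibration fit failed to converge: {exc}") from exc
    r_min, r_max, ph_mid, slope_k = (float(v) for v in popt)
    resid = ratio - sigmoid_ratio(ph, *popt)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    return CalibrationCurve(
        r_min=r_min, r_max=r_max, ph_mid=ph_mid, slope_k=slope_k,
        valid_range=(float(ph.min()), float(ph.max())), rmse=rmse,
    )


def ratio_to_ph(curve: CalibrationCurve, ratio):
    """Invert the calibration sigmoid; NaN (with a warning) outside (r_min, r_max)."""
    ratio = np.asarray(ratio, dtype=float)
    inside = (ratio > curve.r_min) & (ratio < curve.r_max)
    n_out = int(np.sum(~inside & np.isfinite(ratio)))
    if n_out:
        warnings.warn(
            f"{n_out} ratio value(s) outside the invertible interval "
            f"({curve.r_min:.4g}, {curve.r_max:.4g}); set to NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (curve.r_max - curve.r_min) / (ratio - curve.r_min) - 1.0
        ph = np.where(inside, curve.ph_mid - np.log10(np.where(arg > 0, arg, np.nan))
                      / curve.slope_k, np.nan)
    if np.ndim(ratio) == 0:
        return float(ph)
    return ph


def ph_to_ratio(curve: CalibrationCurve, ph):
    """Forward map, provided for symmetry with :func:`ratio_to_ph`."""
    return curve.ratio(ph)


def plate_background(plate: PlateTimeCourse) -> dict[str, np.ndarray]:
    """Per-channel, per-timepoint mean of the plate's blank wells.

    Plates without blanks get a zero background and a warning.
    """
    mask = plate.role_mask("blank")
    if not mask.any():
        warnings.warn(
            f"plate {plate.plate_id}: no blank wells; assuming zero background",
            stacklevel=2,
        )
        zero = np.zeros(len(plate.times))
        return {"f390": zero, "f470": zero.copy()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            "f390": np.nanmean(plate.f390[mask], axis=0),
            "f470": np.nanmean(plate.f470[mask], axis=0),
        }


def plate_to_ph(plate: PlateTimeCourse, curve: CalibrationCurve) -> pd.DataFrame:
    """Convert a plate's non-blank wells to pH time series.

    Returns a DataFrame indexed by well id with one column per timepoint
    (hours).  Channel values <= 0 after background subtraction, and ratios
    outside the invertible interval, propagate as NaN.
    """
    keep = ~plate.role_mask("blank")
    if not keep.any():
        raise CalibrationError(
            f"plate {plate.plate_id} contains only blank wells"
        )
    bg = plate_background(plate)
    f390 = subtract_background(plate.f390[keep], np.broadcast_to(
        bg["f390"], plate.f390[keep].shape))
    f470 = subtract_background(plate.f470[keep], np.broadcast_to(
        bg["f470"], plate.f470[keep].shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((f390 > 0) & (f470 > 0), f390 / f470, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # out-of-range ratios already NaN-flagged
        ph = ratio_to_ph(curve, ratio)
    if np.all(np.isnan(ph)):
        raise CalibrationError(
            f"plate {plate.plate_id}: zero usable dynamic range after "
            "background subtraction"
        )
    wells = [w.well for w, k in zip(plate.wells, keep) if k]
    return pd.DataFrame(ph, index=wells, columns=plate.times)
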
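"""Microplate growth-curve analysis.

Plate readers underestimate OD600 at high cell density.  Readings are
linearised with the empirical quadratic

    OD_cor = 1.1252 * OD_obs**2 + 0.6808 * OD_obs - 0.0002

calibrated against cuvette measurements of diluted cultures.  The specific
growth rate mu(t) (h^-1) is the ordinary least-squares slope of ln(OD_cor)
over a sliding window of consecutive points (default 6 points = 1 h at
10-minute sampling), assigned to the window-centre time so that mu aligns
unbiasedly with per-timepoint pH.

Points with OD_cor <= 0 (possible near the polynomial's small negative
intercept at very low density) are NaN-masked, never floored: flooring
would fabricate zero slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError

OD_POLY = (1.1252, 0.6808, -0.0002)  # a*x^2 + b*x + c


def correct_od(od_obs):
    """Linearise raw plate-reader OD600 with the calibration polynomial."""
    x = np.asarray(od_obs, dtype=float)
    a, b, c = OD_POLY
    out = a * x ** 2 + b * x + c
    if np.ndim(od_obs) == 0:
        return float(out)
    return out


def invert_correct_od(od_cor):
    """Raw reading that linearises to ``od_cor`` (positive branch).

    Used by the synthetic generator to emit raw readings consistent with a
    simulated true OD.  Values below the polynomial minimum are clipped to
    the vertex with a warning.
    """
    y = np.asarray(od_cor, dtype=float)
    a, b, c = OD_POLY
    disc = b ** 2 - 4.0 * a * (c - y)
    n_bad = int(np.sum(disc < 0))
    if n_bad:
        warnings.warn(
            f"{n_bad} OD value(s) below the invertible range; clipped",
            stacklevel=2,
        )
    disc = np.clip(disc, 0.0, None)
    out = (-b + np.sqrt(disc)) / (2.0 * a)
    if np.ndim(od_cor) == 0:
        return float(out)
    return out


def _window_slopes(times: np.ndarray, y: np.ndarray, window: int):
    """OLS slope of y vs t in each window of `window` consecutive points."""
    tw = sliding_window_view(times, window)
    yw = sliding_window_view(y, window)
    tm = tw.mean(axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ym = yw.mean(axis=1, keepdims=True)
        cov = ((tw - tm) * (yw - ym)).sum(axis=1)
        var = ((tw - tm) ** 2).sum(axis=1)
        slopes = cov / var
    slopes[np.isnan(yw).any(axis=1)] = np.nan
    centers = tw.mean(axis=1)
    return centers, slopes


def growth_rate_series(times, od_cor, window: int = 6):
    """Sliding-window specific growth rate of one well.

    Returns ``(centers, mu)`` where ``mu[i]`` is the least-squares slope of
    ln(od_cor) over points ``i .. i+window-1`` and ``centers[i]`` is the mean
    time of that window.  ``len(mu) == len(times) - window + 1``.  Windows
    containing any masked (NaN) log-OD point are NaN.
    """
    times = np.asarray(times, dtype=float)
    od_cor = np.asarray(od_cor, dtype=float)
    if window < 2:
        raise ValidationError("window must span at least 2 points")
    if times.shape != od_cor.shape or times.ndim != 1:
        raise ValidationError("times and od_cor must be equal-length 1-D arrays")
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValidationError("times must be strictly increasing")
    with np.errstate(divide="ignore", invalid="ignore"):
        ln_od = np.where(od_cor > 0, np.log(np.where(od_cor > 0, od_cor, 1.0)),
                         np.nan)
    if np.sum(np.isfinite(ln_od)) < window:
        warnings.warn(
            f"fewer than {window} usable points; returning empty series",
            stacklevel=2,
        )
        return np.empty(0), np.empty(0)
    return _window_slopes(times, ln_od, window)


def window_means(times, values, window: int = 6):
    """Sliding-window nanmean of a companion series (e.g. pH), aligned to the
    same window centres as :func:`growth_rate_series`."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    tw = sliding_window_view(times, window)
    vw = sliding_window_view(values, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(vw, axis=1)
    return tw.mean(axis=1), means


@dataclass
class GrowthCurve:
    """One well's corrected growth curve and derived rate series."""

    times: np.ndarray
    od_cor: np.ndarray
    window: int = 6
    ln_od: np.ndarray = field(init=False)
    mu_times: np.ndarray = field(init=False)
    mu: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od_cor = np.asarray(self.od_cor, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.ln_od = np.where(
                self.od_cor > 0, np.log(np.where(self.od_cor > 0, self.od_cor, 1.0)),
                np.nan,
            )
        self.mu_times, self.mu = growth_rate_series(
            self.times, self.od_cor, self.window
        )

    @classmethod
    def from_raw(cls, times, od_raw, window: int = 6) -> "GrowthCurve":
        """Build from raw plate-reader readings (applies :func:`correct_od`)."""
        return cls(times=times, od_cor=correct_od(np.asarray(od_raw, float)),
                   window=window)
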
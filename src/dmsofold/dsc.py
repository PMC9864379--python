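"""DSC thermogram processing: excess heat capacity, Tm extraction, and the
parabolic melting-point-vs-DMSO stability fit."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

log = logging.getLogger(__name__)


class ThermogramError(ValueError):
    """Raised for invalid thermogram data."""


@dataclass
class Thermogram:
    """A Cp(T) trace at one DMSO condition; temperature in degrees C."""

    temperature_C: np.ndarray
    cp: np.ndarray
    dmso_vv_percent: float = 0.0
    scan_rate_C_per_h: float = 200.0

    def __post_init__(self) -> None:
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.temperature_C.shape != self.cp.shape:
            raise ThermogramError("temperature and cp must have the same length")
        dT = np.diff(self.temperature_C)
        bad = np.flatnonzero(dT <= 0)
        if bad.size:
            raise ThermogramError(
                f"temperature grid not strictly increasing at index {int(bad[0]) + 1}"
            )

    def __len__(self) -> int:
        return len(self.temperature_C)


@dataclass
class MeltPoint:
    dmso_vv_percent: float
    tm_C: float
    tm_err_C: float


@dataclass
class ParabolaFit:
    """Tm(x) = p1*x^2 + p2*x + p3 with x in DMSO v/v%."""

    p1: float
    p2: float
    p3: float
    r_squared: float
    p1_err: float = np.nan
    p2_err: float = np.nan
    p3_err: float = np.nan
    n_points: int = 0


def excess_heat_capacity(
    sample: Thermogram,
    reference: Optional[Thermogram] = None,
    baseline: str = "chord",
    pre_window_C: float = 5.0,
    post_window_C: float = 5.0,
) -> Thermogram:
    """Reference-subtract and baseline-correct a thermogram.

    The reference buffer trace (if given; grids must match) is subtracted
    first; the remaining baseline is removed as a linear chord through the
    means of a pre-transition and a post-transition window at the edges of
    the scan. A warning is emitted if the trace maximum lies inside either
    window (baseline windows overlapping the transition).
    """
    T = sample.temperature_C
    cp = sample.cp.copy()
    if reference is not None:
        if (len(reference) != len(sample)
                or not np.allclose(reference.temperature_C, T)):
            raise ThermogramError("sample/reference temperature grids differ")
        cp = cp - reference.cp

    if baseline == "chord":
        pre = T <= T[0] + pre_window_C
        post = T >= T[-1] - post_window_C
        if np.argmax(cp) in np.flatnonzero(pre | post):
            warnings.warn("baseline window overlaps the transition peak",
                          stacklevel=2)
        x1, y1 = float(np.mean(T[pre])), float(np.mean(cp[pre]))
        x2, y2 = float(np.mean(T[post])), float(np.mean(cp[post]))
        slope = (y2 - y1) / (x2 - x1)
        cp = cp - (y1 + slope * (T - x1))
    elif baseline != "none":
        raise ThermogramError(f"unknown baseline method {baseline!r}")

    return Thermogram(T, cp, sample.dmso_vv_percent, sample.scan_rate_C_per_h)


def extract_tm(
    thermogram: Thermogram,
    half_window: int = 5,
    min_prominence_frac: float = 0.05,
    secondary_frac: float = 0.50,
) -> MeltPoint:
    """Melting temperature as the excess-Cp maximum, refined by a local
    quadratic fit over +/- ``half_window`` grid points.

    Raises on flat traces (no peak with prominence above
    ``min_prominence_frac`` of the signal span) and on multi-modal traces
    whose secondary peak exceeds ``secondary_frac`` of the main one.
    """
    T, cp = thermogram.temperature_C, thermogram.cp
    span = float(np.max(cp) - np.min(cp))
    if span <= 0 or not np.isfinite(span):
        raise ThermogramError("flat trace: no endotherm found")
    peaks, props = find_peaks(cp, prominence=min_prominence_frac * span)
    if peaks.size == 0:
        raise ThermogramError("flat trace: no endotherm found")
    heights = cp[peaks] - np.min(cp)
    order = np.argsort(heights)[::-1]
    main = peaks[order[0]]
    if order.size > 1 and heights[order[1]] > secondary_frac * heights[order[0]]:
        raise ThermogramError(
            f"multi-modal trace: secondary peak at "
            f"{T[peaks[order[1]]]:.2f} C exceeds {secondary_frac:.0%} of main"
        )

    lo = max(main - half_window, 0)
    hi = min(main + half_window + 1, len(T))
    t_loc, c_loc = T[lo:hi], cp[lo:hi]
    # local quadratic: vertex of the fitted parabola
    coef, cov = np.polyfit(t_loc - T[main], c_loc, 2, cov=True)
    a, b = coef[0], coef[1]
    if a >= 0:
        tm = float(T[main])
    else:
        tm = float(T[main] - b / (2.0 * a))
    grid = float(np.median(np.diff(t_loc)))
    # vertex error from the (a, b) covariance, floored at half the grid step
    with np.errstate(divide="ignore", invalid="ignore"):
        var_v = (cov[1, 1] / (4 * a * a)
                 + (b * b / (4 * a**4)) * cov[0, 0]
                 - (b / (2 * a**3)) * cov[0, 1])
    err = float(np.sqrt(max(var_v, 0.0))) if np.isfinite(var_v) else 0.0
    err = max(err, 0.5 * grid)
    return MeltPoint(thermogram.dmso_vv_percent, tm, err)


def fit_tm_parabola(points: list[MeltPoint]) -> ParabolaFit:
    """Ordinary least squares Tm(x) = p1*x^2 + p2*x + p3 over melt points."""
    if len(points) < 3:
        raise ThermogramError(f"need >= 3 melt points, got {len(points)}")
    if len(points) == 3:
        warnings.warn("3 points interpolate the parabola exactly (R^2 = 1)",
                      stacklevel=2)
    x = np.array([p.dmso_vv_percent for p in points], dtype=float)
    y = np.array([p.tm_C for p in points], dtype=float)
    if len(points) > 3:
        coef, cov = np.polyfit(x, y, 2, cov=True)
        errs = np.sqrt(np.diag(cov))
    else:
        coef = np.polyfit(x, y, 2)
        errs = np.full(3, np.nan)
    pred = np.polyval(coef, x)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit = ParabolaFit(float(coef[0]), float(coef[1]), float(coef[2]),
                      min(max(r2, 0.0), 1.0),
                      float(errs[0]), float(errs[1]), float(errs[2]),
                      n_points=len(points))
    log.info("Tm parabola: p1=%.4g p2=%.4g p3=%.4g R2=%.4f (n=%d)",
             fit.p1, fit.p2, fit.p3, fit.r_squared, fit.n_points)
    return fit


def predict_tm(fit: ParabolaFit, x) -> float:
    """Evaluate the fitted parabola at DMSO content x (v/v%)."""
    xv = np.asarray(x, dtype=float)
    out = fit.p1 * xv**2 + fit.p2 * xv + fit.p3
    return float(out) if np.isscalar(x) else out
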
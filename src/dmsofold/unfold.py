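"""Two-state denaturant unfolding model and per-peak fitting.

The folded fraction follows the linear free-energy model

    dG(c)  = dG0 - m*c
    f_F(c) = 1 / (1 + exp((-dG0 + m*c) / RT))
    dG0    = m * c50

and the observed folded-peak intensity ratio is I/I0 = a * f_F with a free
plateau amplitude a. Fitting is weighted nonlinear least squares in
(a, m, c50); the standard free energy dG0 = m*c50 is derived from the fit
with its error propagated from the (m, c50) covariance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .config import R_KJ
from .correct import TitrationSeries

log = logging.getLogger(__name__)


class UnfoldingError(ValueError):
    """Raised for invalid unfolding-fit inputs."""


def vv_to_molar(vv: float, density: float = 1.10, molar_mass: float = 78.13) -> float:
    """Convert a v/v% cosolvent fraction to molarity.

    c [mol/L] = (vv/100) * density[g/mL] * 1000 / molar_mass[g/mol].
    70 v/v% DMSO (rho=1.10, M=78.13) gives 9.855 M -- "nearly 10 M".
    """
    vv_arr = np.asarray(vv, dtype=float)
    if np.any(vv_arr < 0) or np.any(vv_arr > 100):
        raise UnfoldingError(f"v/v% out of [0, 100]: {vv}")
    out = vv_arr / 100.0 * density * 1000.0 / molar_mass
    return float(out) if np.isscalar(vv) else out


def molar_to_vv(conc: float, density: float = 1.10, molar_mass: float = 78.13) -> float:
    """Inverse of :func:`vv_to_molar`."""
    return np.asarray(conc, dtype=float) * molar_mass / (10.0 * density)


def folded_fraction(dG0, m, conc, T, R: float = R_KJ):
    """Folded population f_F = 1/(1 + exp((-dG0 + m*conc)/(R*T)))."""
    if T <= 0:
        raise UnfoldingError("temperature must be > 0")
    x = (-np.asarray(dG0, dtype=float) + np.asarray(m) * np.asarray(conc)) / (R * T)
    return 1.0 / (1.0 + np.exp(x))


def dG_at_conc(dG0, m, conc):
    """Unfolding free energy at denaturant concentration conc: dG0 - m*conc."""
    return np.asarray(dG0, dtype=float) - np.asarray(m) * np.asarray(conc)


def intensity_model(conc, a, m, d50, T, R: float = R_KJ):
    """Folded-peak intensity ratio a/(1 + exp(m*(conc - d50)/(R*T))).

    Algebraically identical to a * folded_fraction(m*d50, m, conc, T).
    """
    if T <= 0:
        raise UnfoldingError("temperature must be > 0")
    return a / (1.0 + np.exp(np.asarray(m) * (np.asarray(conc, dtype=float) - d50) / (R * T)))


@dataclass
class UnfoldingFit:
    """Per-peak two-state fit result.

    dG0 = m * d50 exactly (derived, never refit); dG0_err propagates the
    full (m, d50) covariance.
    """

    peak_id: str
    a: float
    m: float                  # kJ/mol/M
    d50: float                # mol/L
    dG0: float                # kJ/mol
    temperature_K: float
    a_err: float = math.nan
    m_err: float = math.nan
    d50_err: float = math.nan
    dG0_err: float = math.nan
    converged: bool = True
    n_points: int = 0
    message: str = ""


@dataclass
class PooledUnfolding:
    """Unweighted mean +/- sample SD of dG0 over converged per-peak fits."""

    fits: list[UnfoldingFit]
    mean_dG0: float
    sd_dG0: float
    n_peaks: int


def _initial_guess(conc: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    a0 = float(np.max(y))
    half = a0 / 2.0
    d50_0 = float(conc[np.argmin(np.abs(y - half))])
    if d50_0 <= 0:
        d50_0 = float(np.median(conc[conc > 0])) if np.any(conc > 0) else 1.0
    # slope of the central portion -> m ~ 4*RT*|dy/dc| / a at the midpoint
    order = np.argsort(conc)
    dy = np.gradient(y[order], conc[order])
    slope = float(np.min(dy))  # most negative
    m0 = max(4.0 * R_KJ * 310.0 * abs(slope) / max(a0, 1e-12), 0.1)
    return a0, m0, d50_0


def fit_two_state(
    series: TitrationSeries,
    T: float,
    density: float = 1.10,
    molar_mass: float = 78.13,
    weights: np.ndarray | None = None,
    R: float = R_KJ,
) -> UnfoldingFit:
    """Fit a, m and [denaturant]_50 to a corrected titration series.

    Uses non-censored points only. Raises if fewer points than parameters;
    flags non-convergence (without reporting parameters) when the data show
    no transition, e.g. a flat I/I0 profile.
    """
    pts = [p for p in series.points if not p.censored and p.i_rel is not None]
    if len(pts) < 3:
        raise UnfoldingError(
            f"series {series.peak_id!r}: {len(pts)} usable points < 3 parameters"
        )
    conc = np.array([
        p.dmso_molar if p.dmso_molar is not None
        else vv_to_molar(p.dmso_vv_percent, density, molar_mass)
        for p in pts
    ])
    y = np.array([p.i_rel for p in pts], dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    span = float(np.max(y) - np.min(y))
    if span < 0.05 * float(np.max(np.abs(y))):
        log.info("series %s: flat profile, no transition in range", series.peak_id)
        return UnfoldingFit(series.peak_id, math.nan, math.nan, math.nan, math.nan,
                            T, converged=False, n_points=len(pts),
                            message="no transition in concentration range")

    a0, m0, d50_0 = _initial_guess(conc, y)
    x0 = np.array([min(a0, 1.5), m0, d50_0])

    def resid(theta: np.ndarray) -> np.ndarray:
        a, m, d50 = theta
        return w * (intensity_model(conc, a, m, d50, T, R) - y)

    res = least_squares(
        resid, x0,
        bounds=([1e-6, 1e-6, 1e-6], [1.5, np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    a, m, d50 = res.x
    dG0 = m * d50

    # covariance from the Jacobian, scaled by residual variance
    dof = len(y) - 3
    cov = None
    if dof > 0:
        try:
            JTJ = res.jac.T @ res.jac
            cov = np.linalg.inv(JTJ) * (2.0 * res.cost / dof)
        except np.linalg.LinAlgError:
            cov = None
    if cov is not None:
        a_err, m_err, d50_err = np.sqrt(np.clip(np.diag(cov), 0, None))
        var_dG0 = (d50**2 * cov[1, 1] + m**2 * cov[2, 2]
                   + 2.0 * m * d50 * cov[1, 2])
        dG0_err = math.sqrt(max(var_dG0, 0.0))
    else:
        a_err = m_err = d50_err = dG0_err = math.nan

    converged = bool(res.success) and d50 > 0
    # a midpoint far outside the sampled range means the transition was not seen
    if d50 > 2.0 * float(np.max(conc)):
        converged = False
    fit = UnfoldingFit(series.peak_id, a, m, d50, dG0, T,
                       a_err, m_err, d50_err, dG0_err,
                       converged=converged, n_points=len(pts), message=res.message)
    log.info("fit %s: a=%.4g+/-%.2g m=%.4g+/-%.2g d50=%.4g+/-%.2g dG0=%.4g+/-%.2g "
             "converged=%s", fit.peak_id, a, a_err, m, m_err, d50, d50_err,
             dG0, dG0_err, converged)
    return fit


def pool_peaks(fits: list[UnfoldingFit]) -> PooledUnfolding:
    """Unweighted mean and sample SD of dG0 over converged fits."""
    good = [f for f in fits if f.converged]
    if not good:
        raise UnfoldingError("no converged fits to pool")
    vals = np.array([f.dG0 for f in good])
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return PooledUnfolding(good, float(np.mean(vals)), sd, len(good))
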
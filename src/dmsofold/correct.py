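"""Viscosity-, volume- and calibration-correction of dual-delay HSQC peak volumes.

Peak volumes measured at two transverse-evolution delays t1 < t2 are
back-extrapolated to zero time assuming monoexponential T2 decay, which
removes the viscosity-driven intensity bias across a DMSO titration. The
zero-time volumes are then compensated for solution-volume dilution and for
per-point pulse-calibration scale factors, and finally normalized to the
reference (lowest-DMSO) point to give I/I0 ratios for two-state fitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class CorrectionError(ValueError):
    """Raised for invalid correction inputs."""


@dataclass
class TitrationPoint:
    """One titration condition: dual-delay peak volumes plus bookkeeping."""

    dmso_vv_percent: float
    volume_short: float          # peak volume at delay t1
    volume_long: float           # peak volume at delay t2
    solution_volume: float       # uL
    pulse_scale: float = 1.0
    dmso_molar: Optional[float] = None

    # filled in by correct_series
    i0_extrap: Optional[float] = None
    t2_apparent_ms: Optional[float] = None
    i_rel: Optional[float] = None
    censored: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.dmso_vv_percent <= 100.0):
            raise CorrectionError(
                f"dmso_vv_percent must be in [0, 100], got {self.dmso_vv_percent}"
            )


@dataclass
class TitrationSeries:
    """All titration points of one HSQC cross-peak, sorted by DMSO content."""

    peak_id: str
    points: list[TitrationPoint] = field(default_factory=list)
    t1_ms: float = 5.5
    t2_ms: float = 11.0
    i_zero_reference: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t2_ms <= self.t1_ms or self.t1_ms <= 0:
            raise CorrectionError("delays must satisfy t2 > t1 > 0")
        self.points.sort(key=lambda p: p.dmso_vv_percent)

    def __len__(self) -> int:
        return len(self.points)


def back_extrapolate_intensity(
    i1: float, i2: float, t1: float, t2: float
) -> tuple[float, float]:
    """Back-extrapolate dual-delay volumes to zero time.

    Assuming I(t) = I0 * exp(-t/T2),

        I0 = exp(ln i1 + t1 * (ln i1 - ln i2) / (t2 - t1))
        T2 = (t2 - t1) / ln(i1 / i2)

    For t2 = 2*t1 this reduces to I0 = i1^2 / i2.

    Returns
    -------
    (i0, t2_apparent)
        Zero-time volume and apparent T2 in the units of t1/t2. When
        i2 >= i1 (non-decaying signal) a warning is emitted and
        (i1, inf) is returned without extrapolation.
    """
    if i1 <= 0 or i2 <= 0:
        raise CorrectionError(f"volumes must be positive, got i1={i1}, i2={i2}")
    if t2 <= t1 or t1 <= 0:
        raise CorrectionError(f"delays must satisfy t2 > t1 > 0, got t1={t1}, t2={t2}")
    if i2 >= i1:
        warnings.warn(
            f"non-decaying signal (i2={i2} >= i1={i1}); returning i1 unextrapolated",
            stacklevel=2,
        )
        return i1, math.inf
    log_slope = (math.log(i1) - math.log(i2)) / (t2 - t1)
    i0 = math.exp(math.log(i1) + t1 * log_slope)
    t2_app = 1.0 / log_slope
    return i0, t2_app


def volume_correct(intensity: float, solution_volume: float, reference_volume: float) -> float:
    """Compensate dilution of a fixed solute amount: I * (V / V_ref)."""
    if solution_volume <= 0 or reference_volume <= 0:
        raise CorrectionError("solution volumes must be positive")
    return intensity * (solution_volume / reference_volume)


def correct_series(
    series: TitrationSeries, reference_index: int | None = None
) -> TitrationSeries:
    """Produce normalized I/I0 ratios for one peak's titration.

    Per point: back-extrapolate the dual-delay volumes to zero time, scale by
    the solution-volume ratio relative to the reference point, divide by the
    pulse-calibration factor, then normalize to the corrected reference
    intensity. The reference point (lowest DMSO unless overridden) has
    i_rel exactly 1. Points with missing or nonpositive volumes are marked
    censored and carry no ratio.
    """
    if not series.points:
        raise CorrectionError(f"series {series.peak_id!r} has no points")
    ref_i = 0 if reference_index is None else reference_index
    ref_point = series.points[ref_i]
    if _is_censored(ref_point):
        raise CorrectionError(
            f"series {series.peak_id!r}: reference point "
            f"({ref_point.dmso_vv_percent} v/v%) has no usable volumes"
        )
    if ref_point.solution_volume <= 0:
        raise CorrectionError(f"series {series.peak_id!r}: nonpositive reference volume")

    out_points: list[TitrationPoint] = []
    for p in series.points:
        if _is_censored(p):
            out_points.append(replace(p, censored=True, i0_extrap=None,
                                      t2_apparent_ms=None, i_rel=None))
            continue
        i0, t2_app = back_extrapolate_intensity(
            p.volume_short, p.volume_long, series.t1_ms, series.t2_ms
        )
        corrected = volume_correct(i0, p.solution_volume, ref_point.solution_volume)
        corrected /= p.pulse_scale
        out_points.append(replace(p, i0_extrap=corrected, t2_apparent_ms=t2_app,
                                  censored=False))

    ref_corrected = out_points[ref_i].i0_extrap
    for q in out_points:
        if not q.censored:
            q.i_rel = q.i0_extrap / ref_corrected

    return TitrationSeries(
        peak_id=series.peak_id,
        points=out_points,
        t1_ms=series.t1_ms,
        t2_ms=series.t2_ms,
        i_zero_reference=ref_corrected,
    )


def _is_censored(p: TitrationPoint) -> bool:
    for v in (p.volume_short, p.volume_long):
        if v is None or not np.isfinite(v) or v <= 0:
            return True
    return False
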
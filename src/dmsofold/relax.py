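"""Backbone 15N relaxation analysis.

Forward R1/R2/NOE rates from Lipari-Szabo spectral densities, reduced
spectral density mapping (single high-frequency sampling point at 0.87*wH),
a two-stage model-free fit (global correlation time + per-residue order
parameters S2, isotropic tumbling, no internal correlation time by default),
and an R1*R2 chemical-exchange screen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .config import PhysicalConstants

log = logging.getLogger(__name__)

#: highest NOE ratio physically sensible for amide 15N
NOE_SANITY_MAX = 1.25


class RelaxationError(ValueError):
    """Raised for invalid relaxation data or failed global fits."""


@dataclass
class RelaxationRecord:
    residue: int
    R1: float
    R1_err: float
    R2: float
    R2_err: float
    NOE: float
    NOE_err: float

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R2 <= 0:
            raise RelaxationError(
                f"residue {self.residue}: rates must be positive "
                f"(R1={self.R1}, R2={self.R2})"
            )
        if self.NOE > NOE_SANITY_MAX:
            raise RelaxationError(
                f"residue {self.residue}: NOE={self.NOE} exceeds sanity bound "
                f"{NOE_SANITY_MAX}"
            )


@dataclass
class RelaxationDataset:
    records: list[RelaxationRecord]
    field_15N_MHz: float
    truth: Optional[dict] = None   # embedded ground truth from the simulator

    def __len__(self) -> int:
        return len(self.records)

    def arrays(self) -> tuple[np.ndarray, ...]:
        """(residues, R1, R1e, R2, R2e, NOE, NOEe) as float arrays."""
        cols = [(r.residue, r.R1, r.R1_err, r.R2, r.R2_err, r.NOE, r.NOE_err)
                for r in self.records]
        return tuple(np.array(c, dtype=float) for c in zip(*cols))


@dataclass
class SpectralDensities:
    """J(0), J(wN) and J(0.87*wH) in s/rad; unphysical (negative J0) flagged."""

    residue: int
    J0: float
    JwN: float
    JwH: float
    unphysical: bool = False


@dataclass
class ModelFreeResult:
    tau_c_ns: float
    tau_c_err_ns: float
    residues: np.ndarray
    S2: np.ndarray
    S2_err: np.ndarray
    chi2: np.ndarray
    model: str = "isotropic-S2"
    converged: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


@dataclass
class TaucEstimate:
    tau_c_ns: float
    per_residue_ns: np.ndarray
    used: np.ndarray            # mask of residues contributing to the aggregate
    flags: list[str]


def lipari_szabo_J(omega, S2: float, tau_c: float, tau_e: float | None = None):
    """Lipari-Szabo spectral density, s/rad.

    J(w) = (2/5) [ S2*tc/(1+(w tc)^2) + (1-S2)*t/(1+(w t)^2) ],
    1/t = 1/tc + 1/te. The internal-motion term is omitted when tau_e is
    None. For S2=1 this is the rigid Lorentzian with J(0) = 0.4*tau_c.
    """
    if not (0.0 <= S2 <= 1.0):
        raise RelaxationError(f"S2 must be in [0, 1], got {S2}")
    if tau_c <= 0:
        raise RelaxationError(f"tau_c must be positive, got {tau_c}")
    w = np.asarray(omega, dtype=float)
    J = 0.4 * S2 * tau_c / (1.0 + (w * tau_c) ** 2)
    if tau_e is not None and S2 < 1.0:
        tau = 1.0 / (1.0 / tau_c + 1.0 / tau_e)
        J = J + 0.4 * (1.0 - S2) * tau / (1.0 + (w * tau) ** 2)
    return J


def _dcw(field_15N_MHz: float, constants: PhysicalConstants):
    d = constants.dipolar_d
    c = constants.csa_c(field_15N_MHz)
    wN = constants.omega_N(field_15N_MHz)
    wH = constants.omega_H(field_15N_MHz)
    return d, c, wN, wH


def forward_rates(
    S2,
    tau_c: float,
    tau_e: float | None,
    field_15N_MHz: float,
    Rex=0.0,
    constants: PhysicalConstants = PhysicalConstants(),
):
    """Forward-compute (R1, R2, NOE) from model-free parameters.

    Standard dipolar + CSA expressions for an amide 15N spin relaxed by its
    attached proton; Rex adds to R2 only. Accepts scalar or array S2/Rex.
    """
    d, c, wN, wH = _dcw(field_15N_MHz, constants)
    # gammaN < 0: the signed 15N frequency places the "sum" combination
    # below wH and the "difference" above it, which is what makes the
    # 0.87*wH reduced-mapping convention work
    wN_signed = math.copysign(wN, constants.gamma_N)
    S2a = np.atleast_1d(np.asarray(S2, dtype=float))
    Rexa = np.broadcast_to(np.atleast_1d(np.asarray(Rex, dtype=float)), S2a.shape)

    def J(w):
        return np.array([lipari_szabo_J(w, s, tau_c, tau_e) for s in S2a])

    J0 = J(0.0)
    JN = J(wN)
    JH = J(wH)
    JHmN = J(wH - wN_signed)
    JHpN = J(wH + wN_signed)

    d2 = d * d
    c2 = c * c
    R1 = (d2 / 4.0) * (JHmN + 3.0 * JN + 6.0 * JHpN) + c2 * JN
    R2 = ((d2 / 8.0) * (4.0 * J0 + JHmN + 3.0 * JN + 6.0 * JH + 6.0 * JHpN)
          + (c2 / 6.0) * (4.0 * J0 + 3.0 * JN) + Rexa)
    gamma_ratio = constants.gamma_H / constants.gamma_N
    NOE = 1.0 + (d2 / 4.0) * gamma_ratio * (6.0 * JHpN - JHmN) / R1

    if np.isscalar(S2) or np.ndim(S2) == 0:
        return float(R1[0]), float(R2[0]), float(NOE[0])
    return R1, R2, NOE


def reduced_jmap(
    rec: RelaxationRecord,
    field_15N_MHz: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> SpectralDensities:
    """Reduced spectral density mapping of one residue's (R1, R2, NOE).

    All high-frequency terms are sampled at the single point 0.87*wH:

        sigma = R1 * (NOE - 1) * gammaN/gammaH
        J(0.87wH) = 4*sigma / (5 d^2)
        J(wN) = (R1 - 7 d^2/4 * J(0.87wH)) / (3 d^2/4 + c^2)
        J(0)  = (R2 - d^2/8 * (3 J(wN) + 13 J(0.87wH)) - c^2/2 * J(wN))
                / (d^2/2 + 2 c^2/3)

    A negative J(0) (noise or exchange) is flagged unphysical but returned.
    """
    d, c, _, _ = _dcw(field_15N_MHz, constants)
    d2, c2 = d * d, c * c
    sigma = rec.R1 * (rec.NOE - 1.0) * (constants.gamma_N / constants.gamma_H)
    JwH = 4.0 * sigma / (5.0 * d2)
    JwN = (rec.R1 - (7.0 * d2 / 4.0) * JwH) / (3.0 * d2 / 4.0 + c2)
    J0 = ((rec.R2 - (d2 / 8.0) * (3.0 * JwN + 13.0 * JwH) - (c2 / 2.0) * JwN)
          / (d2 / 2.0 + 2.0 * c2 / 3.0))
    unphysical = J0 < 0
    if unphysical:
        log.warning("residue %s: negative J(0)=%.3g (noise or exchange)",
                    rec.residue, J0)
    return SpectralDensities(rec.residue, J0, JwN, JwH, unphysical)


def rigid_r2_over_r1(tau_c: float, field_15N_MHz: float,
                     constants: PhysicalConstants = PhysicalConstants()) -> float:
    """R2/R1 of a rigid (S2 = 1) residue tumbling isotropically at tau_c."""
    R1, R2, _ = forward_rates(1.0, tau_c, None, field_15N_MHz, 0.0, constants)
    return R2 / R1


_TAUC_LO_NS, _TAUC_HI_NS = 0.05, 100.0


def estimate_tauc_r2r1(
    dataset: RelaxationDataset,
    noe_min: float = 0.65,
    r2_trim_sd: float = 1.5,
    constants: PhysicalConstants = PhysicalConstants(),
) -> TaucEstimate:
    """Global correlation time from per-residue rigid-limit R2/R1 ratios.

    Residues with NOE below ``noe_min`` (mobile termini/loops) or with R2
    outside ``r2_trim_sd`` SDs of the 10%-trimmed R2 mean (exchange) are
    excluded; each remaining ratio is inverted numerically and the
    10%-trimmed mean of the per-residue solutions is returned.
    """
    if len(dataset) < 5:
        raise RelaxationError(f"need >= 5 residues, got {len(dataset)}")
    res, R1, _, R2, _, NOE, _ = dataset.arrays()
    field = dataset.field_15N_MHz
    flags: list[str] = []

    keep = NOE >= noe_min
    for i in np.flatnonzero(~keep):
        flags.append(f"residue {int(res[i])}: NOE={NOE[i]:.3f} below filter "
                     f"{noe_min} (mobile)")
    r2_tm, r2_tsd = _trimmed_mean_sd(R2[keep] if keep.any() else R2)
    if r2_tsd > 0:
        keep &= np.abs(R2 - r2_tm) <= r2_trim_sd * r2_tsd

    lo = rigid_r2_over_r1(_TAUC_LO_NS * 1e-9, field, constants)
    hi = rigid_r2_over_r1(_TAUC_HI_NS * 1e-9, field, constants)
    per = np.full(len(res), np.nan)
    for i in np.flatnonzero(keep):
        ratio = R2[i] / R1[i]
        if ratio <= lo:
            flags.append(f"residue {int(res[i])}: R2/R1={ratio:.3f} below solver "
                         "grid (extreme narrowing)")
            keep[i] = False
            continue
        if ratio >= hi:
            flags.append(f"residue {int(res[i])}: R2/R1={ratio:.3f} above solver grid")
            keep[i] = False
            continue
        per[i] = brentq(
            lambda t: rigid_r2_over_r1(t * 1e-9, field, constants) - ratio,
            _TAUC_LO_NS, _TAUC_HI_NS, xtol=1e-6,
        )
    if not keep.any():
        raise RelaxationError("all residues filtered out in tau_c estimation; "
                              + "; ".join(flags))
    tm, _ = _trimmed_mean_sd(per[keep])
    return TaucEstimate(float(tm), per, keep, flags)


def _trimmed_mean_sd(x: np.ndarray, trim: float = 0.10) -> tuple[float, float]:
    x = np.sort(np.asarray(x, dtype=float))
    k = int(len(x) * trim)
    core = x[k:len(x) - k] if len(x) > 2 * k else x
    return float(np.mean(core)), float(np.std(core, ddof=1)) if len(core) > 1 else 0.0


def _rate_coeffs(tau_c_s: float, field: float, constants: PhysicalConstants):
    """R1 = S2*A1, R2 = S2*A2 and the (S2-free) NOE for the no-tau_e model."""
    A1, A2, NOE = forward_rates(1.0, tau_c_s, None, field, 0.0, constants)
    return A1, A2, NOE


def _fit_s2_at_tauc(tau_c_s, R1, R1e, R2, R2e, NOE, NOEe, field, constants):
    """Analytic weighted LS for S2 (rates are linear in S2), plus chi2."""
    A1, A2, noe_model = _rate_coeffs(tau_c_s, field, constants)
    w1, w2 = 1.0 / R1e**2, 1.0 / R2e**2
    S2 = (w1 * R1 * A1 + w2 * R2 * A2) / (w1 * A1**2 + w2 * A2**2)
    S2 = np.clip(S2, 0.0, 1.0)
    chi2 = (w1 * (R1 - S2 * A1) ** 2 + w2 * (R2 - S2 * A2) ** 2
            + ((NOE - noe_model) / NOEe) ** 2)
    return S2, chi2


def fit_model_free(
    dataset: RelaxationDataset,
    field_15N_MHz: float | None = None,
    mc_reps: int = 200,
    seed: int = 0,
    noe_min: float = 0.65,
    constants: PhysicalConstants = PhysicalConstants(),
) -> ModelFreeResult:
    """Two-parameter model-free fit: one global tau_c, per-residue S2.

    Stage 1 seeds tau_c from the rigid-limit R2/R1 estimator; stage 2 solves
    per-residue S2 by (analytic) weighted least squares at fixed tau_c;
    stage 3 refines tau_c by minimizing the summed chi2. Parameter errors
    come from seeded Monte-Carlo resampling of the rates within their stated
    uncertainties.
    """
    if len(dataset) < 5:
        raise RelaxationError(f"need >= 5 residues, got {len(dataset)}")
    field = dataset.field_15N_MHz if field_15N_MHz is None else field_15N_MHz
    res, R1, R1e, R2, R2e, NOE, NOEe = dataset.arrays()
    R1e = np.where(R1e > 0, R1e, 0.02 * R1)
    R2e = np.where(R2e > 0, R2e, 0.02 * R2)
    NOEe = np.where(NOEe > 0, NOEe, 0.02)

    tauc0 = estimate_tauc_r2r1(dataset, noe_min=noe_min, constants=constants).tau_c_ns

    def total_chi2(tau_ns, r1, r2, noe):
        _, chi2 = _fit_s2_at_tauc(tau_ns * 1e-9, r1, R1e, r2, R2e, noe, NOEe,
                                  field, constants)
        return float(np.sum(chi2))

    def refine(r1, r2, noe, start):
        opt = minimize_scalar(
            lambda t: total_chi2(t, r1, r2, noe),
            bounds=(max(0.25 * start, _TAUC_LO_NS), min(4.0 * start, _TAUC_HI_NS)),
            method="bounded",
            options={"xatol": 1e-7},
        )
        if not opt.success:
            raise RelaxationError(f"global tau_c refinement failed: {opt.message}")
        return float(opt.x)

    tauc = refine(R1, R2, NOE, tauc0)
    S2, chi2 = _fit_s2_at_tauc(tauc * 1e-9, R1, R1e, R2, R2e, NOE, NOEe,
                               field, constants)

    rng = np.random.default_rng(seed)
    tauc_mc = np.empty(mc_reps)
    S2_mc = np.empty((mc_reps, len(res)))
    for k in range(mc_reps):
        r1 = np.abs(R1 + rng.normal(0.0, R1e))
        r2 = np.abs(R2 + rng.normal(0.0, R2e))
        noe = NOE + rng.normal(0.0, NOEe)
        t_k = refine(r1, r2, noe, tauc)
        tauc_mc[k] = t_k
        S2_mc[k], _ = _fit_s2_at_tauc(t_k * 1e-9, r1, R1e, r2, R2e, noe, NOEe,
                                      field, constants)
    tauc_err = float(np.std(tauc_mc, ddof=1)) if mc_reps > 1 else 0.0
    S2_err = np.std(S2_mc, axis=0, ddof=1) if mc_reps > 1 else np.zeros_like(S2)

    converged = np.isfinite(S2)
    log.info("model-free fit: tau_c=%.4g +/- %.2g ns, mean S2=%.3f (n=%d, seed=%d)",
             tauc, tauc_err, float(np.mean(S2)), len(res), seed)
    return ModelFreeResult(tauc, tauc_err, res.astype(int), S2, S2_err, chi2,
                           converged=converged)


@dataclass
class ExchangeScreen:
    residues: np.ndarray
    product: np.ndarray          # R1*R2 per residue, s^-2
    product_err: np.ndarray      # propagated error of the product
    threshold: float
    flagged: np.ndarray          # boolean mask


def exchange_screen_r1r2(dataset: RelaxationDataset, k: float = 1.5) -> ExchangeScreen:
    """Flag chemical-exchange candidates with elevated R1*R2 products.

    A residue is flagged when its R1*R2 exceeds the 10%-trimmed mean by more
    than ``k`` trimmed SDs. Per-residue products are reported with errors
    propagated from the stated rate uncertainties.
    """
    if len(dataset) < 5:
        raise RelaxationError(f"need >= 5 residues, got {len(dataset)}")
    res, R1, R1e, R2, R2e, _, _ = dataset.arrays()
    prod = R1 * R2
    prod_err = np.sqrt((R2 * R1e) ** 2 + (R1 * R2e) ** 2)
    tm, tsd = _trimmed_mean_sd(prod)
    threshold = tm + k * tsd
    flagged = prod > threshold + 1e-12 * max(tm, 1.0)
    return ExchangeScreen(res.astype(int), prod, prod_err, float(threshold), flagged)
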
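"""Seeded synthetic-data generators for titration, relaxation and DSC inputs.

Each generator draws from a ground-truth forward model (the same equations
the analysis inverts), applies configurable noise, and embeds the generating
parameters in the returned object so tests can close the loop without any
external data. Identical spec + seed always reproduces identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .config import R_KJ, CELSIUS_OFFSET, PhysicalConstants
from .correct import TitrationPoint, TitrationSeries
from .dsc import Thermogram
from .relax import RelaxationDataset, RelaxationRecord, forward_rates
from .unfold import intensity_model, vv_to_molar


class SimulationError(ValueError):
    """Raised for invalid simulation specs."""


# ---------------------------------------------------------------------------
# titration


@dataclass
class TitrationSimSpec:
    """Forward model of a dual-delay HSQC intensity titration.

    The folded-peak signal follows the two-state sigmoid in molar DMSO;
    transverse relaxation shortens linearly across the titration (viscosity
    proxy) and the solution volume grows as DMSO is added. Noise is one
    multiplicative factor per titration point, shared by the two delay
    measurements (a sample-level perturbation), so that corrected I/I0
    ratios carry the injected noise level undistorted.
    """

    a: float = 1.0
    m: float = 2.3                    # kJ/mol/M
    d50: float = 10.0                 # mol/L
    T: float = 310.0                  # K
    dmso_grid_vv: np.ndarray = dc_field(
        default_factory=lambda: np.linspace(0.0, 88.0, 12))
    t1_ms: float = 5.5
    t2_ms: float = 11.0
    t2_profile_ms: tuple[float, float] = (80.0, 25.0)   # T2 at first/last point
    volume_profile_uL: tuple[float, float] = (350.0, 990.0)
    base_intensity: float = 1.0e4
    noise_sd: float = 0.0             # fractional, per point
    noise_kind: str = "gaussian"      # or "lognormal"
    vanish_above_vv: Optional[float] = 82.0
    density: float = 1.10
    molar_mass: float = 78.13
    peak_ids: tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5", "P6")
    seed: int = 0


@dataclass
class TitrationSim:
    series: list[TitrationSeries]
    truth: dict


def simulate_titration(spec: TitrationSimSpec) -> TitrationSim:
    """Generate raw dual-delay titration series for each configured peak."""
    if spec.noise_kind not in ("gaussian", "lognormal"):
        raise SimulationError(f"unknown noise_kind {spec.noise_kind!r}")
    rng = np.random.default_rng(spec.seed)
    vv = np.asarray(spec.dmso_grid_vv, dtype=float)
    n = len(vv)
    frac = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
    t2_ms = spec.t2_profile_ms[0] + frac * (spec.t2_profile_ms[1] - spec.t2_profile_ms[0])
    vol = (spec.volume_profile_uL[0]
           + frac * (spec.volume_profile_uL[1] - spec.volume_profile_uL[0]))
    conc = vv_to_molar(vv, spec.density, spec.molar_mass)
    ratio = intensity_model(conc, spec.a, spec.m, spec.d50, spec.T)

    series = []
    for pid in spec.peak_ids:
        points = []
        for i in range(n):
            if spec.vanish_above_vv is not None and vv[i] > spec.vanish_above_vv:
                points.append(TitrationPoint(vv[i], 0.0, 0.0, vol[i],
                                             dmso_molar=float(conc[i])))
                continue
            if spec.noise_sd > 0:
                if spec.noise_kind == "gaussian":
                    f = 1.0 + spec.noise_sd * rng.standard_normal()
                else:
                    f = math.exp(spec.noise_sd * rng.standard_normal())
                f = max(f, 1e-6)
            else:
                f = 1.0
            amp = (spec.base_intensity * ratio[i]
                   * (vol[0] / vol[i]) * f)
            i1 = amp * math.exp(-spec.t1_ms / t2_ms[i])
            i2 = amp * math.exp(-spec.t2_ms / t2_ms[i])
            points.append(TitrationPoint(vv[i], i1, i2, vol[i],
                                         dmso_molar=float(conc[i])))
        series.append(TitrationSeries(pid, points, spec.t1_ms, spec.t2_ms))

    truth = {
        "a": spec.a, "m": spec.m, "d50": spec.d50, "T": spec.T,
        "dmso_vv": vv.tolist(), "dmso_molar": conc.tolist(),
        "true_ratio": ratio.tolist(), "t2_ms": t2_ms.tolist(),
        "solution_volume_uL": vol.tolist(), "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return TitrationSim(series, truth)


# ---------------------------------------------------------------------------
# relaxation


@dataclass
class RelaxSimSpec:
    n_residues: int = 50
    exclude_residues: tuple[int, ...] = ()
    s2_mean: float = 0.87
    s2_sd: float = 0.06
    s2_floor: float = 0.0
    s2_ceil: float = 1.0
    tau_c_ns: float = 7.7
    field_15N_MHz: float = 70.966
    rex_residues: dict[int, float] = dc_field(default_factory=dict)
    noise_sd: float = 0.0             # fractional on R1/R2, absolute on NOE
    seed: int = 0
    constants: PhysicalConstants = dc_field(default_factory=PhysicalConstants)


def simulate_relaxation(spec: RelaxSimSpec) -> RelaxationDataset:
    """Per-residue (R1, R2, NOE) from the model-free forward model.

    S2 values are drawn from a clipped normal; optional per-residue Rex adds
    to R2. Fractional Gaussian noise perturbs R1/R2 (additive noise of the
    same magnitude perturbs the dimensionless NOE); stated errors match the
    injected noise level.
    """
    residues = [r for r in range(1, spec.n_residues + 1)
                if r not in set(spec.exclude_residues)]
    rng = np.random.default_rng(spec.seed)
    if spec.s2_sd > 0:
        S2 = np.clip(rng.normal(spec.s2_mean, spec.s2_sd, len(residues)),
                     spec.s2_floor, spec.s2_ceil)
    else:
        S2 = np.full(len(residues), float(np.clip(spec.s2_mean, spec.s2_floor,
                                                  spec.s2_ceil)))
    S2 = np.clip(S2, 0.0, 1.0)
    rex = np.array([spec.rex_residues.get(r, 0.0) for r in residues])

    R1, R2, NOE = forward_rates(S2, spec.tau_c_ns * 1e-9, None,
                                spec.field_15N_MHz, rex, spec.constants)
    sd = spec.noise_sd
    if sd > 0:
        R1n = R1 * (1.0 + sd * rng.standard_normal(len(residues)))
        R2n = R2 * (1.0 + sd * rng.standard_normal(len(residues)))
        NOEn = NOE + sd * rng.standard_normal(len(residues))
        R1e, R2e, NOEe = sd * R1, sd * R2, np.full(len(residues), sd)
    else:
        R1n, R2n, NOEn = R1, R2, NOE
        R1e, R2e, NOEe = 0.0 * R1, 0.0 * R2, 0.0 * NOE
    records = [
        RelaxationRecord(res, float(R1n[i]), float(R1e[i]), float(R2n[i]),
                         float(R2e[i]), float(NOEn[i]), float(NOEe[i]))
        for i, res in enumerate(residues)
    ]
    truth = {
        "tau_c_ns": spec.tau_c_ns, "S2": dict(zip(residues, S2.tolist())),
        "rex": {r: spec.rex_residues.get(r, 0.0) for r in residues},
        "field_15N_MHz": spec.field_15N_MHz, "noise_sd": sd, "seed": spec.seed,
    }
    return RelaxationDataset(records, spec.field_15N_MHz, truth=truth)


# ---------------------------------------------------------------------------
# DSC


@dataclass
class DscSimSpec:
    """Two-state excess-heat-capacity traces whose Tm follows a parabola in
    DMSO v/v%. The equilibrium van't Hoff shape is used only to place a
    well-defined peak; only its position is ever analyzed."""

    p1: float = -2.98e-3
    p2: float = -59.0e-3
    p3: float = 93.2
    dH_vH: float = 500.0              # kJ/mol, shape parameter only
    dmso_grid_vv: np.ndarray = dc_field(
        default_factory=lambda: np.arange(0.0, 56.0, 5.0))
    temp_grid_C: np.ndarray = dc_field(
        default_factory=lambda: np.round(np.arange(40.0, 130.0 + 1e-9, 0.1), 10))
    baseline_slope: float = 0.0       # per deg C
    baseline_intercept: float = 0.0
    noise_sd: float = 0.0             # fraction of peak height
    seed: int = 0


@dataclass
class DscSim:
    thermograms: list[Thermogram]
    reference: Thermogram
    truth: dict


def two_state_excess_cp(T_C: np.ndarray, tm_C: float, dH_vH: float) -> np.ndarray:
    """Equilibrium two-state excess heat capacity.

    Cp_ex(T) = dH^2/(R T^2) * K/(1+K)^2 with
    K = exp(-(dH/R) * (1/T - 1/Tm)), temperatures in kelvin internally.
    The integral over the full transition equals dH_vH.
    """
    T = np.asarray(T_C, dtype=float) + CELSIUS_OFFSET
    tm = tm_C + CELSIUS_OFFSET
    K = np.exp(-(dH_vH / R_KJ) * (1.0 / T - 1.0 / tm))
    return dH_vH**2 / (R_KJ * T**2) * K / (1.0 + K) ** 2


def simulate_dsc(spec: DscSimSpec) -> DscSim:
    """One thermogram per DMSO condition plus a shared buffer reference."""
    rng = np.random.default_rng(spec.seed)
    T = np.asarray(spec.temp_grid_C, dtype=float)
    ref_cp = np.full_like(T, 0.02)    # flat buffer trace
    reference = Thermogram(T, ref_cp, dmso_vv_percent=-1.0)

    thermos = []
    tms = {}
    for x in np.asarray(spec.dmso_grid_vv, dtype=float):
        tm = spec.p1 * x**2 + spec.p2 * x + spec.p3
        if not (T[0] < tm < T[-1]):
            raise SimulationError(
                f"Tm={tm:.1f} C at x={x}% outside scanned range "
                f"[{T[0]}, {T[-1]}] C"
            )
        peak = two_state_excess_cp(T, tm, spec.dH_vH)
        baseline = spec.baseline_intercept + spec.baseline_slope * (T - T[0])
        cp = peak + baseline + ref_cp
        if spec.noise_sd > 0:
            cp = cp + spec.noise_sd * float(np.max(peak)) * rng.standard_normal(len(T))
        thermos.append(Thermogram(T, cp, dmso_vv_percent=float(x)))
        tms[float(x)] = float(tm)

    truth = {
        "p1": spec.p1, "p2": spec.p2, "p3": spec.p3, "dH_vH": spec.dH_vH,
        "tm_C": tms, "noise_sd": spec.noise_sd, "seed": spec.seed,
    }
    return DscSim(thermos, reference, truth)
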
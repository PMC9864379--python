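"""Run configuration and physical constants.

All temperatures are handled internally in kelvin; the DSC I/O boundary
converts from/to degrees Celsius. Free energies are in kJ/mol, denaturant
sensitivities (m-values) in kJ/mol/M, concentrations in mol/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

#: Gas constant in kJ mol^-1 K^-1
R_KJ = 8.314e-3

#: 1H gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.6752218744e8
#: 15N gyromagnetic ratio, rad s^-1 T^-1 (negative)
GAMMA_N = -2.7126e7

MU_0 = 4.0e-7 * math.pi
HBAR = 1.054571817e-34

CELSIUS_OFFSET = 273.15


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Interaction constants for amide 15N relaxation.

    The dipolar constant ``d`` and CSA constant ``c`` are derived from the
    primary quantities on demand -- never hard-coded -- so that changing
    ``r_nh_A`` or ``delta_sigma_ppm`` propagates everywhere.
    """

    gamma_H: float = GAMMA_H
    gamma_N: float = GAMMA_N
    r_nh_A: float = 1.02
    delta_sigma_ppm: float = -160.0
    mu0: float = MU_0
    hbar: float = HBAR

    @property
    def dipolar_d(self) -> float:
        """(mu0/4pi) * hbar * gammaH * gammaN / r_NH^3, rad/s (negative)."""
        r = self.r_nh_A * 1e-10
        return (self.mu0 / (4.0 * math.pi)) * self.hbar * self.gamma_H * self.gamma_N / r**3

    def omega_N(self, field_15N_MHz: float) -> float:
        """15N angular Larmor frequency, rad/s."""
        return 2.0 * math.pi * field_15N_MHz * 1e6

    def omega_H(self, field_15N_MHz: float) -> float:
        """1H angular Larmor frequency for the same field, rad/s."""
        return self.omega_N(field_15N_MHz) * abs(self.gamma_H / self.gamma_N)

    def csa_c(self, field_15N_MHz: float) -> float:
        """CSA constant c = omegaN * delta_sigma / sqrt(3), rad/s."""
        return self.omega_N(field_15N_MHz) * self.delta_sigma_ppm * 1e-6 / math.sqrt(3.0)


@dataclass
class RunConfig:
    """Pipeline-wide options shared by all stages.

    Defaults follow the experimental conditions of the study this pipeline
    models: 310 K titrations, DMSO density 1.10 g/mL and molar mass
    78.13 g/mol for the v/v% -> molar conversion.
    """

    temperature_K: float = 310.0
    gas_constant: float = R_KJ
    dmso_density: float = 1.10        # g/mL
    dmso_molar_mass: float = 78.13    # g/mol
    field_15N_MHz: float = 50.684
    rng_seed: int = 0

    # relaxation analysis
    r_nh_A: float = 1.02
    delta_sigma_ppm: float = -160.0
    mc_reps: int = 200
    noe_filter: float = 0.65
    r2_trim_sd: float = 1.5
    rex_k: float = 1.5

    # titration correction
    t1_ms: float = 5.5
    t2_ms: float = 11.0
    censor_above_vv: float = 82.0

    # DSC
    baseline_window_C: float = 5.0

    paths: dict[str, str] = field(default_factory=dict)
    options: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ConfigError("temperature_K must be > 0")
        if self.dmso_density <= 0:
            raise ConfigError("dmso_density must be > 0")
        if self.dmso_molar_mass <= 0:
            raise ConfigError("dmso_molar_mass must be > 0")
        if self.gas_constant <= 0:
            raise ConfigError("gas_constant must be > 0")

    @property
    def RT(self) -> float:
        """Thermal energy R*T in kJ/mol."""
        return self.gas_constant * self.temperature_K

    @property
    def constants(self) -> PhysicalConstants:
        return PhysicalConstants(r_nh_A=self.r_nh_A, delta_sigma_ppm=self.delta_sigma_ppm)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
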
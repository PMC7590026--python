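"""Heating models: linear response theory and its Langevin-saturated
extension.

Linear response theory (LRT) gives the volumetric heating power of a
superparamagnetic suspension in an alternating field H(t) = Hmax cos(wt):

    P = mu0 * pi * chi'' * f * Hmax^2,
    chi'' = chi0 * w tau / (1 + (w tau)^2),
    chi0 = mu0 * Ms_vol^2 * V_m / (3 kB T).

P is quadratic in Hmax and maximal at w tau = 1. LRT only holds while the
Zeeman energy stays below thermal energy (xi < 1). At hyperthermia-grade
amplitudes the equilibrium response saturates; replacing the linear chi0
branch by the Langevin function and letting tau itself depend on the field
yields the saturating specific absorption rate

    SAR(H) = Gamma(H) * L(xi) * w tau(H) / (1 + (w tau(H))^2),
    Gamma(H) = pi * mu0 * f * H * Ms_vol / rho,

which reduces exactly to LRT/rho as xi -> 0 and flattens above the field
where w tau crosses unity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import KB, MU0, DEFAULTS
from .magnetometry import langevin, langevin_argument
from .relaxation import (ParticleModel, brown_time_zero_field,
                         neel_time_field_empirical)

__all__ = [
    "DrivingField",
    "SarModelParams",
    "static_susceptibility",
    "chi_imaginary",
    "lrt_volumetric_power",
    "gamma_coefficient",
    "sar_saturation_model",
]


@dataclass(frozen=True)
class DrivingField:
    """Alternating magnetic field: frequency f (Hz), amplitude Hmax (A/m)."""

    f: float
    Hmax: float = 0.0

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("frequency must be positive")
        if self.Hmax < 0:
            raise ValueError("field amplitude must be nonnegative")

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.f


@dataclass
class SarModelParams:
    """Parameters of the Langevin-saturation SAR model.

    gamma_per_field : Gamma/H, W/kg per (A/m). When None it is computed
        physically as pi*mu0*f*Ms_vol/density.
    tau_N0 : zero-field Neel time (s) feeding the empirical field-dependent
        Neel expression with amplitude A and exponent C.
    """

    particle: ParticleModel
    tau_N0: float
    A: float = 2.0
    C: float = 3.0
    density: float = DEFAULTS.density
    gamma_per_field: float | None = None

    def __post_init__(self) -> None:
        if self.tau_N0 <= 0:
            raise ValueError("tau_N0 must be positive")
        if self.gamma_per_field is not None and self.gamma_per_field < 0:
            raise ValueError("gamma_per_field must be nonnegative")


def static_susceptibility(p: ParticleModel) -> float:
    """Equilibrium susceptibility chi0 = mu0 * Ms_vol^2 * V_m / (3 kB T)."""
    return MU0 * p.Ms_vol ** 2 * p.V_m / (3.0 * KB * p.T)


def chi_imaginary(chi0: float, omega: float, tau):
    """Out-of-phase susceptibility chi'' = chi0 * w tau / (1 + (w tau)^2).

    Maximal (= chi0/2) at w tau = 1 and symmetric under
    w tau <-> 1/(w tau).
    """
    wt = omega * np.asarray(tau, dtype=float)
    out = chi0 * wt / (1.0 + wt * wt)
    return out if np.ndim(out) else float(out)


def lrt_volumetric_power(field: DrivingField, chi_imag: float) -> float:
    """LRT volumetric heating power P = mu0 * pi * chi'' * f * Hmax^2 (W/m^3)."""
    return MU0 * math.pi * chi_imag * field.f * field.Hmax ** 2


def gamma_coefficient(field: DrivingField, Ms_vol: float,
                      density: float = DEFAULTS.density) -> float:
    """Saturation-model prefactor Gamma = pi * mu0 * f * Hmax * Ms_vol / rho
    (W/kg)."""
    if density <= 0:
        raise ValueError("density must be positive")
    return math.pi * MU0 * field.f * field.Hmax * Ms_vol / density


def _effective_tau(params: SarModelParams, H):
    """Field-dependent effective relaxation time of the model (vectorized)."""
    p = params.particle
    xi = langevin_argument(p.Ms_vol, p.D, np.asarray(H, dtype=float), p.T)
    tau_N = neel_time_field_empirical(params.tau_N0, xi, params.A, params.C)
    tb0 = brown_time_zero_field(p)
    if math.isinf(tb0):
        return np.asarray(tau_N, dtype=float), xi
    tau_B = tb0 / np.sqrt(1.0 + 0.07 * xi * xi)
    tau = tau_N * tau_B / (tau_N + tau_B)
    return tau, xi


def sar_saturation_model(H, f: float, params: SarModelParams):
    """Specific absorption rate (W/kg) of the Langevin-saturation model.

    SAR(H) = gamma * H * L(xi) * w tau / (1 + (w tau)^2), with xi the
    Langevin argument at amplitude H, tau the field-dependent effective
    relaxation time (empirical Neel branch combined with the Brownian
    branch unless Brownian rotation is disabled), and gamma = Gamma/H
    either supplied or computed from pi*mu0*f*Ms_vol/rho.

    Continuous at H = 0 with value 0; nonnegative for H >= 0.
    """
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("field amplitudes must be nonnegative")
    p = params.particle
    gamma = params.gamma_per_field
    if gamma is None:
        gamma = math.pi * MU0 * f * p.Ms_vol / params.density
    tau, xi = _effective_tau(params, H)
    omega = 2.0 * math.pi * f
    wt = omega * tau
    out = gamma * H * langevin(xi) * wt / (1.0 + wt * wt)
    return out if np.ndim(out) else float(out)
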
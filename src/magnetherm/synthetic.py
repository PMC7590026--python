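"""Ground-truth generators for every stage of the analysis.

Each generator is a pure function of a :class:`SyntheticSpec` (seed, noise
model, ground-truth parameters): identical specs give bit-identical output,
and every generated dataset carries its generating parameters so recovery
tests can assert against them.

The study-like dataset emulates the structure of the experimental campaign:
four zinc levels (x = 0, 0.1, 0.3, 0.5) with their measured room-temperature
Ms values, each heated in three dispersion conditions (aqueous suspension,
solid matrix with random orientation, solid matrix pre-aligned in a static
field) over 5-65 kA/m at 355 kHz. Saturation SAR is proportional to Ms
within each condition; immobilization lowers it by 30% and pre-alignment
recovers 20% (zinc-doped) or 40% (undoped) on top of the immobilized value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np

from .calorimetry import HeatingCurve
from .config import DEFAULTS, MU0
from .magnetometry import LogNormalFit, MagnetizationCurve, ensemble_magnetization
from .relaxation import ParticleModel
from .sar_models import SarModelParams, sar_saturation_model
from .sarfit import SarCurve

__all__ = [
    "SyntheticSpec",
    "STUDY_MS_300K",
    "STUDY_DISPERSIVITY",
    "STUDY_D_MEAN_NM",
    "gen_magnetization_curve",
    "gen_heating_curve",
    "gen_sar_curve",
    "gen_study_like_dataset",
]

#: Room-temperature saturation mass magnetization (A m^2/kg) per zinc level.
STUDY_MS_300K = {0.0: 65.9, 0.1: 78.5, 0.3: 93.4, 0.5: 82.1}
#: Magnetic-size log-normal parameters per zinc level (mean diameter nm,
#: dispersivity index).
STUDY_D_MEAN_NM = {0.0: 8.69, 0.1: 8.51, 0.3: 7.76, 0.5: 8.19}
STUDY_DISPERSIVITY = {0.0: 0.16, 0.1: 0.15, 0.3: 0.08, 0.5: 0.07}

# Ground-truth parameters of the saturation-model forward curves: magnetic
# diameter and relaxation parameters in the range the SAR(H) fits occupy.
_STUDY_D = 18e-9
_STUDY_C = 3.0
_STUDY_A = 2.0
_STUDY_TAU_N0 = 3e-5
_IMMOBILIZATION_FACTOR = 0.70
_ALIGNMENT_FACTOR = {0.0: 1.40, 0.1: 1.20, 0.3: 1.20, 0.5: 1.20}


@dataclass(frozen=True)
class SyntheticSpec:
    """Reproducibility contract of one synthetic dataset."""

    seed: int = 0
    noise_model: str = "none"        # none | gaussian-multiplicative | gaussian-additive
    noise_level: float = 0.0
    ground_truth: dict = dc_field(default_factory=dict)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply_noise(self, values: np.ndarray,
                    rng: np.random.Generator | None = None) -> np.ndarray:
        if self.noise_model == "none" or self.noise_level == 0.0:
            return np.array(values, copy=True)
        rng = rng if rng is not None else self.rng()
        noise = rng.standard_normal(values.shape)
        if self.noise_model == "gaussian-multiplicative":
            return values * (1.0 + self.noise_level * noise)
        if self.noise_model == "gaussian-additive":
            return values + self.noise_level * noise
        raise ValueError(f"unknown noise model {self.noise_model!r}")


def gen_magnetization_curve(spec: SyntheticSpec, Ms: float, D0: float,
                            sigma_disp: float, chi_para: float = 0.0,
                            T: float = 300.0, H_grid=None,
                            density: float = DEFAULTS.density,
                            ) -> tuple[MagnetizationCurve, LogNormalFit]:
    """Forward log-normal Langevin magnetization curve plus its ground truth.

    The default field grid is geometric over 0.5-5500 kA/m (the +-7 T
    positive branch), dense at low field where the size information lives.
    """
    if H_grid is None:
        H_grid = np.geomspace(5e2, 5.5e6, 50)
    truth = LogNormalFit(Ms=Ms, D0=D0, sigma_disp=sigma_disp,
                         chi_para=chi_para)
    M = ensemble_magnetization(H_grid, truth, T, density)
    M = spec.apply_noise(M)
    return MagnetizationCurve(H=np.asarray(H_grid, float), M=M, T=T), truth


def gen_heating_curve(spec: SyntheticSpec, P: float,
                      sample_mass: float = DEFAULTS.mass_water,
                      specific_heat: float = DEFAULTS.c_water,
                      loss_coeff: float = 0.0, T_env: float = 37.0,
                      duration: float = 600.0,
                      iron_mass: float = float("nan")) -> HeatingCurve:
    """Linear-plus-Newton-cooling heating curve sampled at 1 Hz.

    T(t) = T_env + (P/k) (1 - exp(-k t / (m c))) for loss coefficient
    k > 0 (W/K); the adiabatic limit k = 0 gives the straight line
    T_env + P t/(m c). Initial slope is P/(m c) in both cases.
    """
    if P < 0 or loss_coeff < 0 or sample_mass <= 0 or specific_heat <= 0:
        raise ValueError("P, loss_coeff >= 0 and mass, heat capacity > 0")
    t = np.arange(0.0, duration + 0.5, 1.0)
    mc = sample_mass * specific_heat
    if loss_coeff == 0.0:
        T = T_env + P * t / mc
    else:
        T = T_env + (P / loss_coeff) * (1.0 - np.exp(-loss_coeff * t / mc))
    T = spec.apply_noise(T)
    return HeatingCurve(t=t, T=T, sample_mass=sample_mass,
                        specific_heat=specific_heat, iron_mass=iron_mass)


def _study_particle(Ms_vol: float, condition: str,
                    D: float = _STUDY_D) -> ParticleModel:
    solid = condition in ("solid_random", "solid_aligned")
    return ParticleModel(
        D=D, Ms_vol=Ms_vol, K=2.0e4, shell=DEFAULTS.shell_water,
        tau0=DEFAULTS.tau0, T=DEFAULTS.temperature_hyperthermia,
        eta=DEFAULTS.eta_solid if solid else DEFAULTS.eta_water,
        brown_disabled=solid)


def gen_sar_curve(spec: SyntheticSpec, params: SarModelParams,
                  H_grid=None, condition: str = "water",
                  f: float = DEFAULTS.frequency,
                  composition_x: float = 0.0) -> SarCurve:
    """Forward SAR(H) curve from the Langevin-saturation model plus noise."""
    if H_grid is None:
        H_grid = np.arange(5e3, 65e3 + 1.0, 5e3)
    H_grid = np.asarray(H_grid, dtype=float)
    sar = sar_saturation_model(H_grid, f, params)
    sar = spec.apply_noise(sar)
    return SarCurve(H=H_grid, SAR=sar, condition=condition,
                    composition_x=composition_x, f=f)


def gen_study_like_dataset(spec: SyntheticSpec) -> dict[str, Any]:
    """Twelve SAR(H) curves + four magnetization curves mimicking the study.

    Returns a dict with keys ``sar_curves`` (list of SarCurve),
    ``magnetization_curves`` (dict x -> (MagnetizationCurve, LogNormalFit)),
    and ``ground_truth`` (per-curve generating parameters and the exact
    condition factors).

    Construction: per zinc level the aqueous curve comes from the
    saturation model with that sample's Ms; its amplitude is rescaled so
    the high-field plateau is exactly proportional to Ms across samples.
    The solid-matrix curve uses the Neel-only model rescaled to 70% of the
    aqueous plateau, and the pre-aligned curve is the solid curve times
    1.2 (zinc-doped) or 1.4 (undoped). Rescaling acts on the gamma
    prefactor, so every curve remains an exact model curve with known
    parameters.
    """
    rng = spec.rng()
    H_grid = np.arange(5e3, 65e3 + 1.0, 5e3)
    f = DEFAULTS.frequency
    ms_ref = STUDY_MS_300K[0.3]

    def plateau(values: np.ndarray) -> float:
        return float(np.mean(values[H_grid >= 50e3]))

    # reference aqueous plateau (x = 0.3) sets the absolute scale
    def raw_curve(Ms_mass: float, condition: str) -> tuple[np.ndarray, SarModelParams]:
        p = _study_particle(Ms_mass * DEFAULTS.density, condition)
        params = SarModelParams(particle=p, tau_N0=_STUDY_TAU_N0, A=_STUDY_A,
                                C=_STUDY_C, density=DEFAULTS.density)
        return sar_saturation_model(H_grid, f, params), params

    ref_vals, _ = raw_curve(ms_ref, "water")
    scale_ref = plateau(ref_vals)

    sar_curves: list[SarCurve] = []
    truths: list[dict[str, Any]] = []
    for x, Ms in STUDY_MS_300K.items():
        targets = {}
        targets["water"] = scale_ref * Ms / ms_ref
        targets["solid_random"] = targets["water"] * _IMMOBILIZATION_FACTOR
        targets["solid_aligned"] = targets["solid_random"] * _ALIGNMENT_FACTOR[x]
        shapes = {
            "water": raw_curve(Ms, "water"),
            "solid_random": raw_curve(Ms, "solid_random"),
        }
        shapes["solid_aligned"] = shapes["solid_random"]
        for condition in ("water", "solid_random", "solid_aligned"):
            vals, params = shapes[condition]
            s = targets[condition] / plateau(vals)
            gamma_phys = math.pi * MU0 * f * params.particle.Ms_vol / params.density
            gamma_eff = gamma_phys * s
            scaled = vals * s
            noisy = spec.apply_noise(scaled, rng)
            sar_curves.append(SarCurve(H=H_grid.copy(), SAR=noisy,
                                       condition=condition, composition_x=x,
                                       f=f))
            truths.append({
                "composition_x": x, "condition": condition,
                "D": _STUDY_D, "C": _STUDY_C, "A": _STUDY_A,
                "tau_N0": _STUDY_TAU_N0, "gamma_per_field": gamma_eff,
                "Gamma": gamma_eff * float(H_grid.max()),
                "Ms_mass": Ms, "plateau": targets[condition],
            })

    mag_curves = {}
    for x, Ms in STUDY_MS_300K.items():
        sub = SyntheticSpec(seed=int(rng.integers(0, 2 ** 31 - 1)),
                            noise_model=spec.noise_model,
                            noise_level=spec.noise_level)
        d_mean = STUDY_D_MEAN_NM[x] * 1e-9
        sigma = STUDY_DISPERSIVITY[x]
        d0 = d_mean * math.exp(-sigma ** 2 / 2.0)
        mag_curves[x] = gen_magnetization_curve(
            sub, Ms=Ms, D0=d0, sigma_disp=sigma, chi_para=1e-6,
            T=DEFAULTS.temperature_magnetometry)

    return {
        "sar_curves": sar_curves,
        "magnetization_curves": mag_curves,
        "ground_truth": {
            "curves": truths,
            "immobilization_factor": _IMMOBILIZATION_FACTOR,
            "alignment_factor": dict(_ALIGNMENT_FACTOR),
            "ms_300K": dict(STUDY_MS_300K),
        },
    }
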
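"""Calorimetric SAR extraction by the initial-slope method.

A suspension heated by an alternating field releases power
P = m * c * dT/dt at early times, before losses to the non-adiabatic
surroundings bend the curve over. The specific absorption rate normalizes
that power to the iron content:

    SAR = m * c * (dT/dt)|_initial / m_Fe        [W/kg Fe]

with the initial slope taken over the first ~10 s of the heating curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import DEFAULTS

__all__ = ["HeatingCurve", "initial_slope", "sar_from_heating_curve"]


@dataclass
class HeatingCurve:
    """Temperature-vs-time record of one calorimetry run.

    t : time (s), strictly increasing, nominally 1 Hz sampling
    T : temperature (deg C; only differences enter the analysis)
    sample_mass : total sample mass (kg)
    specific_heat : medium specific heat (J/(kg K))
    iron_mass : iron mass in the sample (kg)
    """

    t: np.ndarray
    T: np.ndarray
    sample_mass: float = DEFAULTS.mass_water
    specific_heat: float = DEFAULTS.c_water
    iron_mass: float = float("nan")

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.t.shape != self.T.shape or self.t.ndim != 1 or self.t.size < 3:
            raise ValueError("t and T must be equal-length 1-D arrays, n >= 3")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")


def initial_slope(curve: HeatingCurve, window_s: float = DEFAULTS.slope_window,
                  two_point: bool = False) -> float:
    """Initial heating rate dT/dt (K/s) over t <= window_s.

    Ordinary least squares by default (robust against the 1 Hz
    quantization of fibre-optic probes); ``two_point=True`` uses the plain
    endpoint difference DT/Dt instead.
    """
    mask = curve.t <= window_s + 1e-12
    t, T = curve.t[mask], curve.T[mask]
    if t.size < 3:
        raise ValueError(
            f"only {t.size} samples within the {window_s} s window; need >= 3")
    if two_point:
        return float((T[-1] - T[0]) / (t[-1] - t[0]))
    return float(stats.linregress(t, T).slope)


def sar_from_heating_curve(curve: HeatingCurve,
                           window_s: float = DEFAULTS.slope_window,
                           two_point: bool = False) -> float:
    """SAR (W per kg of iron) from the initial slope of a heating curve."""
    if not curve.iron_mass > 0:
        raise ValueError("iron_mass must be positive")
    slope = initial_slope(curve, window_s, two_point=two_point)
    return curve.sample_mass * curve.specific_heat * slope / curve.iron_mass


def iron_mass_conventions(mass_fraction: float, concentration_kg_per_m3: float,
                          volume_m3: float) -> dict[str, float]:
    """Both iron-mass conventions for a suspension of given concentration.

    ``per_volume`` is mass_fraction * concentration * volume (the literal
    reading of a c mg/mL, V mL sample); ``per_unit_mg`` is the iron mass in
    exactly 1 mg of particles. The two differ by the particle mass actually
    present; both are reported so the normalization choice is explicit.
    """
    particle_mass = concentration_kg_per_m3 * volume_m3
    return {
        "per_volume": mass_fraction * particle_mass,
        "per_unit_mg": mass_fraction * 1e-6,
    }
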
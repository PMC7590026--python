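"""Stoichiometry, iron content, and crystallography helpers for Zn-doped
magnetite, Zn_x Fe_(3-x) O_4.

Zinc substitutes iron one-for-one in the spinel formula unit, so the iron
mass per unit sample mass follows directly from x and the atomic masses.
The XRD helpers invert peak position/width into crystallite size (Scherrer)
and cubic lattice parameter (Bragg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Stoichiometry",
    "XrdPeak",
    "iron_mass_fraction",
    "x_from_edx",
    "cation_percentages",
    "scherrer_size",
    "cubic_lattice_parameter",
]

# IUPAC 2021 standard atomic weights (u)
M_FE = 55.845
M_ZN = 65.38
M_O = 15.999


@dataclass(frozen=True)
class Stoichiometry:
    """Zinc substitution level of Zn_x Fe_(3-x) O_4.

    Parameters
    ----------
    x : float
        Zinc substitution level, 0 <= x <= 3 (in practice x < 0.5).
    m_fe, m_zn, m_o : float
        Atomic masses (u); overridable for reproducing historical tables.
    """

    x: float
    m_fe: float = M_FE
    m_zn: float = M_ZN
    m_o: float = M_O

    def __post_init__(self) -> None:
        if not 0.0 <= self.x <= 3.0:
            raise ValueError(f"zinc level x={self.x} outside [0, 3]")
        if self.formula_mass <= 0:
            raise ValueError("non-positive formula-unit mass")

    @property
    def formula_mass(self) -> float:
        """Formula-unit mass (u)."""
        return self.x * self.m_zn + (3.0 - self.x) * self.m_fe + 4.0 * self.m_o


@dataclass(frozen=True)
class XrdPeak:
    """One indexed powder-diffraction peak.

    two_theta and fwhm are in degrees; wavelength in nm (Cu K-alpha1
    0.154056 nm by default).
    """

    two_theta: float
    fwhm: float = float("nan")
    hkl: tuple[int, int, int] = (3, 1, 1)
    wavelength: float = 0.154056

    def __post_init__(self) -> None:
        if not 0.0 < self.two_theta < 180.0:
            raise ValueError(f"two_theta={self.two_theta} outside (0, 180)")


def iron_mass_fraction(s: Stoichiometry | float) -> float:
    """Mass fraction of iron in Zn_x Fe_(3-x) O_4.

    For a 1 mg/mL suspension this is also the iron mass (mg) per mg of
    particles, the m_Fe entering calorimetric SAR normalization.

    >>> round(iron_mass_fraction(0.0), 3)
    0.724
    """
    if not isinstance(s, Stoichiometry):
        s = Stoichiometry(float(s))
    return (3.0 - s.x) * s.m_fe / s.formula_mass


def x_from_edx(fe_pct: float, zn_pct: float) -> float:
    """Invert EDX cation atomic percentages into the zinc level x.

    Only the Fe:Zn ratio matters; the percentages need not sum to 100.
    """
    if fe_pct < 0 or zn_pct < 0:
        raise ValueError("atomic percentages must be nonnegative")
    total = fe_pct + zn_pct
    if total <= 0:
        raise ValueError("Fe and Zn percentages are both zero")
    return 3.0 * zn_pct / total


def cation_percentages(s: Stoichiometry | float) -> tuple[float, float]:
    """Theoretical (Fe %, Zn %) of the cation sublattice for a given x."""
    if not isinstance(s, Stoichiometry):
        s = Stoichiometry(float(s))
    return 100.0 * (3.0 - s.x) / 3.0, 100.0 * s.x / 3.0


def scherrer_size(p: XrdPeak, shape_factor: float = 0.9) -> float:
    """Crystallite size (nm) from peak broadening, D = K*lambda/(beta*cos theta).

    beta is the FWHM in degrees (converted to radians internally); the
    default shape factor K=0.9 is the customary value for near-spherical
    crystallites.
    """
    if not p.fwhm > 0:
        raise ValueError(f"fwhm={p.fwhm} must be positive")
    beta = math.radians(p.fwhm)
    theta = math.radians(p.two_theta / 2.0)
    return shape_factor * p.wavelength / (beta * math.cos(theta))


def cubic_lattice_parameter(p: XrdPeak) -> float:
    """Cubic lattice parameter (Angstrom) from Bragg's law.

    a = lambda * sqrt(h^2+k^2+l^2) / (2 sin theta), with lambda in nm
    converted to Angstrom on output.
    """
    h, k, l = p.hkl
    s = h * h + k * k + l * l
    if s == 0:
        raise ValueError("hkl=(0,0,0) is not a reflection")
    theta = math.radians(p.two_theta / 2.0)
    a_nm = p.wavelength * math.sqrt(s) / (2.0 * math.sin(theta))
    return 10.0 * a_nm


def bragg_two_theta(a_angstrom: float, hkl: tuple[int, int, int],
                    wavelength: float = 0.154056) -> float:
    """Forward Bragg helper: 2-theta (degrees) of reflection hkl for a cubic
    lattice parameter a (Angstrom)."""
    h, k, l = hkl
    d = a_angstrom / 10.0 / math.sqrt(h * h + k * k + l * l)  # nm
    return 2.0 * math.degrees(math.asin(wavelength / (2.0 * d)))
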
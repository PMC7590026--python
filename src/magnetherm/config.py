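"""Physical constants and study-level defaults.

All internal computation is in SI units; unit conversion happens only at the
I/O boundary (:mod:`magnetherm.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import math

#: Vacuum magnetic permeability (H/m). Exact in the pre-2019 SI convention
#: used throughout the magnetism literature; the 2019 revision changes it
#: below the precision relevant here.
MU0 = 4.0e-7 * math.pi

#: Boltzmann constant (J/K), exact since the 2019 SI revision.
KB = 1.380649e-23


@dataclass
class RunConfig:
    """Defaults shared across the analysis chain.

    Every value is overridable per call; this object only centralizes the
    choices that several modules must agree on.

    Attributes
    ----------
    density : float
        Particle mass density (kg/m^3) used to convert between mass
        magnetization (A m^2/kg) and volume magnetization (A/m).
        Default is bulk magnetite, 5180 kg/m^3.
    tau0 : float
        Attempt time of the Neel process (s). Default 1e-9 s, the upper end
        of the customary 1e-9 to 1e-10 s range.
    shell_water : float
        Coating-layer thickness (m) for particles suspended in water; sets
        the hydrodynamic diameter D_h = D + 2*shell. Default 10 nm.
    shell_map : float
        Shell thickness (m) used for relaxation-regime maps. Default 2 nm.
    eta_water : float
        Dynamic viscosity of water (Pa s). Default 1e-3.
    eta_solid : float
        Viscosity surrogate used to switch off Brownian rotation for
        particles frozen in a solid matrix. Default 1e100 Pa s.
    temperature_magnetometry : float
        Temperature (K) for magnetization-curve work. Default 300 K.
    temperature_hyperthermia : float
        Temperature (K) for heating calculations (physiological). 310 K.
    frequency : float
        AMF frequency (Hz). Default 355 kHz.
    c_water, c_peg8k : float
        Specific heats (J/(kg K)) of the two suspension media.
    mass_water, mass_peg8k : float
        Sample masses (kg) of the standard 0.5 mL calorimetry aliquot in
        water (density 1 g/mL) and PEG 8k (1.0852 g/mL).
    slope_window : float
        Initial-slope window (s) for calorimetric SAR extraction.
    A_fixed : float
        Fixed amplitude parameter of the empirical field-dependent Neel
        time used during SAR(H) fitting.
    """

    density: float = 5180.0
    tau0: float = 1.0e-9
    shell_water: float = 10.0e-9
    shell_map: float = 2.0e-9
    eta_water: float = 1.0e-3
    eta_solid: float = 1.0e100
    temperature_magnetometry: float = 300.0
    temperature_hyperthermia: float = 310.0
    frequency: float = 355.0e3
    c_water: float = 4186.8
    c_peg8k: float = 2135.27
    mass_water: float = 0.5e-3
    mass_peg8k: float = 0.5426e-3
    slope_window: float = 10.0
    A_fixed: float = 2.0
    extras: dict[str, Any] = field(default_factory=dict)

    def with_overrides(self, **kwargs: Any) -> "RunConfig":
        return replace(self, **kwargs)


DEFAULTS = RunConfig()
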
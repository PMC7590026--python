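"""Neel and Brown relaxation times, their field dependence, and
(D, H) relaxation-regime maps.

Two mechanisms let a single-domain particle's magnetization follow an
alternating field: internal moment reversal over the anisotropy barrier
(Neel, tau_N) and rigid-body rotation in the solvent (Brown,
tau_B0 = 3 eta V_h / kB T). They act in parallel,
1/tau = 1/tau_N + 1/tau_B, so the faster one dominates.

Both times shrink with the field amplitude. Three field-dependent forms are
implemented:

* Brown's expression for tau_N(h), h = H/H_k (valid h < 0.4, singular at
  h = 1);
* the Yoshida-Enpuku result tau_B = tau_B0 / sqrt(1 + 0.07 xi^2) (xi < 20);
* an empirical Neel analogue tau_N = tau_N0 / sqrt(1 + A xi^C), whose
  asymptote tau_N ~ H^(-C/2) is steeper than the Brownian H^(-1) for C = 3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import KB, MU0, DEFAULTS
from .magnetometry import langevin_argument

__all__ = [
    "ParticleModel",
    "RelaxationState",
    "brown_time_zero_field",
    "neel_time_zero_field",
    "neel_time_field_brown",
    "brown_time_field",
    "neel_time_field_empirical",
    "effective_time",
    "anisotropy_field",
    "relaxation_map",
]


@dataclass
class ParticleModel:
    """Physical description of one nanoparticle population.

    D : core (magnetic) diameter, m
    shell : nonmagnetic coating thickness, m; hydrodynamic diameter
        D_h = D + 2*shell
    Ms_vol : volume saturation magnetization, A/m
    K : effective anisotropy constant, J/m^3
    tau0 : Neel attempt time, s
    T : temperature, K
    eta : solvent dynamic viscosity, Pa s; ``brown_disabled`` is an explicit
        alternative to the eta = 1e100 Pa s surrogate
    """

    D: float
    Ms_vol: float
    K: float
    shell: float = DEFAULTS.shell_map
    tau0: float = DEFAULTS.tau0
    T: float = 300.0
    eta: float = DEFAULTS.eta_water
    brown_disabled: bool = False

    def __post_init__(self) -> None:
        for name in ("D", "Ms_vol", "K", "tau0", "T", "eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.shell < 0:
            raise ValueError("shell must be nonnegative")

    @property
    def D_h(self) -> float:
        return self.D + 2.0 * self.shell

    @property
    def V_m(self) -> float:
        return math.pi * self.D ** 3 / 6.0

    @property
    def V_h(self) -> float:
        return math.pi * self.D_h ** 3 / 6.0

    @property
    def sigma_a(self) -> float:
        """Anisotropy-to-thermal energy ratio K V_m / kB T."""
        return self.K * self.V_m / (KB * self.T)


@dataclass
class RelaxationState:
    tau_N: float
    tau_B: float
    tau_eff: float
    regime: str


def brown_time_zero_field(p: ParticleModel) -> float:
    """Zero-field Brownian rotation time tau_B0 = 3 eta V_h / kB T (s)."""
    if p.brown_disabled:
        return float("inf")
    return 3.0 * p.eta * p.V_h / (KB * p.T)


def neel_time_zero_field(p: ParticleModel) -> float:
    """Zero-field Neel time tau_N0 = tau0 * exp(sigma_a) / 2 (s).

    This is the h = 0 limit of Brown's field-dependent expression. For
    sigma_a > ~700 the exponential overflows; +inf is returned with a
    warning (the particle is thermally blocked on any laboratory scale).
    """
    s = p.sigma_a
    if s > 700.0:
        warnings.warn(
            f"sigma_a = {s:.1f} overflows exp(); Neel time is effectively "
            "infinite", RuntimeWarning, stacklevel=2)
        return float("inf")
    return p.tau0 * math.exp(s) / 2.0


def anisotropy_field(p: ParticleModel) -> float:
    """Anisotropy field H_k = 2 K / (mu0 * Ms_vol) (A/m)."""
    return 2.0 * p.K / (MU0 * p.Ms_vol)


def neel_time_field_brown(p: ParticleModel, H: float) -> float:
    """Field-dependent Neel time from Brown's rate expression (s).

    1/tau_N = (1/tau0) (1-h^2) [ (1+h) exp(-sigma (1+h)^2)
                                + (1-h) exp(-sigma (1-h)^2) ],
    h = H/H_k. Singular at h = 1 (domain error); derived for a static
    field and only accurate for h < 0.4, so larger h warns.
    """
    h = H / anisotropy_field(p)
    if h < 0:
        raise ValueError("field amplitude must be nonnegative")
    if h >= 1.0:
        raise ValueError(
            f"h = {h:.3f} >= 1: the expression has a singularity at h = 1 "
            "and no physical meaning beyond it")
    if h > 0.4:
        warnings.warn(
            f"h = {h:.3f} > 0.4: outside the validated range of the "
            "field-dependent Neel expression", RuntimeWarning, stacklevel=2)
    s = p.sigma_a
    a_plus = s * (1.0 + h) ** 2
    a_minus = s * (1.0 - h) ** 2
    rate = (1.0 / p.tau0) * (1.0 - h * h) * (
        (1.0 + h) * math.exp(-min(a_plus, 745.0))
        + (1.0 - h) * math.exp(-min(a_minus, 745.0)))
    if rate <= 0.0:
        return float("inf")
    return 1.0 / rate


def brown_time_field(p: ParticleModel, H: float) -> float:
    """Field-dependent Brownian time tau_B0 / sqrt(1 + 0.07 xi^2) (s).

    xi is evaluated with the particle's *magnetic* volume. Stated validity
    xi < 20; beyond that a warning is issued but the value returned.
    """
    tb0 = brown_time_zero_field(p)
    if math.isinf(tb0):
        return tb0
    xi = langevin_argument(p.Ms_vol, p.D, H, p.T)
    if xi >= 20.0:
        warnings.warn(f"xi = {xi:.1f} >= 20: outside the stated validity of "
                      "the field-dependent Brownian time", RuntimeWarning,
                      stacklevel=2)
    return tb0 / math.sqrt(1.0 + 0.07 * xi * xi)


def neel_time_field_empirical(tau_N0: float, xi, A: float = 2.0,
                              C: float = 3.0, form: str = "decreasing"):
    """Empirical field-dependent Neel time (s).

    The default ``decreasing`` form tau_N0 / sqrt(1 + A xi^C) mirrors the
    Brownian expression and gives the asymptote tau_N ~ H^(-C/2); the
    ``literal`` form tau_N0 * (1 + A xi^C) is kept for comparison, although
    it *increases* with field and contradicts the observed steep decay.
    """
    if A < 0 or C <= 0:
        raise ValueError("require A >= 0 and C > 0")
    xi = np.asarray(xi, dtype=float)
    term = 1.0 + A * xi ** C
    if form == "decreasing":
        out = tau_N0 / np.sqrt(term)
    elif form == "literal":
        out = tau_N0 * term
    else:
        raise ValueError(f"unknown form {form!r}")
    return out if out.ndim else float(out)


def effective_time(tau_N: float, tau_B: float) -> float:
    """Parallel (harmonic) combination 1/tau = 1/tau_N + 1/tau_B."""
    if tau_N < 0 or tau_B < 0:
        raise ValueError("relaxation times must be positive")
    if math.isinf(tau_N):
        return tau_B
    if math.isinf(tau_B):
        return tau_N
    return tau_N * tau_B / (tau_N + tau_B)


def relaxation_map(p: ParticleModel, D_grid, H_grid,
                   neel_form: str = "brown") -> pd.DataFrame:
    """Relaxation times over a (D, H) grid, long format.

    Per cell: tau_N, tau_B (field dependent), tau_eff and the dominant
    regime ('neel' / 'brown' / 'mixed' when within a factor 2). The Neel
    time uses Brown's field-dependent expression by default (the form the
    regime surfaces are drawn with); ``neel_form='empirical'`` switches to
    the tau_N0 / sqrt(1 + A xi^C) analogue with A=2, C=3. Cells with
    h >= 1 under the 'brown' form are reported with tau_N = +inf.
    """
    D_grid = np.atleast_1d(np.asarray(D_grid, dtype=float))
    H_grid = np.atleast_1d(np.asarray(H_grid, dtype=float))
    if D_grid.size == 0 or H_grid.size == 0:
        raise ValueError("grids must be nonempty")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for D in D_grid:
            q = ParticleModel(D=float(D), Ms_vol=p.Ms_vol, K=p.K,
                              shell=p.shell, tau0=p.tau0, T=p.T, eta=p.eta,
                              brown_disabled=p.brown_disabled)
            tn0 = neel_time_zero_field(q)
            for H in H_grid:
                if neel_form == "brown":
                    h = H / anisotropy_field(q)
                    tn = neel_time_field_brown(q, H) if h < 1.0 else float("inf")
                elif neel_form == "empirical":
                    xi = langevin_argument(q.Ms_vol, q.D, H, q.T)
                    tn = neel_time_field_empirical(tn0, xi)
                else:
                    raise ValueError(f"unknown neel_form {neel_form!r}")
                tb = brown_time_field(q, float(H))
                te = effective_time(tn, tb)
                if tn < tb / 2.0:
                    regime = "neel"
                elif tb < tn / 2.0:
                    regime = "brown"
                else:
                    regime = "mixed"
                rows.append((float(D), float(H), tn, tb, te, regime))
    return pd.DataFrame(rows, columns=["D_m", "H_A_per_m", "tau_N_s",
                                       "tau_B_s", "tau_eff_s", "regime"])
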
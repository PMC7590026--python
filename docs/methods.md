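# Methods

This note documents the models implemented in `magnetherm`, the parameter
choices that matter, the numerical decisions, and what the synthetic-data
generators do and do not emulate.

## Physical constants and shared defaults

All internal computation is SI; unit conversion happens only at the I/O
boundary (CSV column names carry units, temperatures enter in °C and are
used as differences only). μ0 = 4π×10⁻⁷ H/m and kB = 1.380649×10⁻²³ J/K are
fixed. Shared defaults (`magnetherm.config`):

| parameter | default | why |
|---|---|---|
| particle density ρ | 5180 kg/m³ | bulk magnetite; converts mass ↔ volume magnetization and reproduces the published K_eff from mass-magnetization loop data |
| attempt time τ0 | 10⁻⁹ s | upper end of the customary 10⁻⁹–10⁻¹⁰ s range |
| coating shell (aqueous SAR fits) | 10 nm | hydrodynamic size that best conditions the Brownian branch for citrate-coated particles |
| shell (relaxation maps) | 2 nm | thin citrate layer, the convention for regime surfaces |
| viscosity η (water / solid) | 10⁻³ / 10¹⁰⁰ Pa·s | the absurdly large value is a device to switch Brownian rotation off; an explicit `brown_disabled` flag is equivalent and unit-tested to agree |
| temperature | 300 K magnetometry / 310 K heating | room-temperature SQUID branch; physiological bath for hyperthermia |
| AMF | f = 355 kHz, H ≤ 65 kA/m | the coil parameters of the emulated campaign |
| calorimetry | m = 0.5 g water (c = 4186.8) or 0.5426 g PEG 8k (c = 2135.27 J/(kg·K)); 10 s initial-slope window | standard 0.5 mL aliquot of the two media |

## Composition

Iron mass fraction of Zn_x Fe_(3−x) O_4 is (3−x)·m_Fe / (x·m_Zn +
(3−x)·m_Fe + 4·m_O) with IUPAC 2021 atomic masses (overridable). For x = 0,
0.1, 0.3, 0.5 this gives 0.7236, 0.6966, 0.6433, 0.5908 mg of iron per mg of
particles; tables in the literature print these rounded at 3 decimals and
occasionally carry ±0.001 of additional rounding. EDX inversion is
x = 3·Zn% / (Fe% + Zn%) — only the cation ratio matters. The Scherrer helper
uses K = 0.9 (near-spherical crystallites) by default with the FWHM supplied
in degrees; the cubic lattice parameter comes from Bragg's law,
a = λ√(h²+k²+l²)/(2 sin θ). Peak fitting of raw diffractograms is out of
scope — peak parameters are inputs.

## Magnetization-curve inversion

The log-normal Langevin integral is evaluated by 160-node Gauss–Legendre
quadrature in u = ln D over ±6σ around ln D0 (captures > 1−10⁻⁸ of the
log-normal mass; σ = 0 short-circuits to the single-size Langevin). The
Langevin function switches to its series ξ/3 − ξ³/45 for |ξ| < 10⁻⁴ to avoid
cancellation. ξ uses the *volume* magnetization Ms·ρ; the fitted Ms itself
is a mass magnetization, matching how SQUID data are reported.

`LogNormalLangevinFit` does bounded trust-region least squares over
(Ms, D0, σ, χ). Langevin fits are notorious for local minima, so D0 is
seeded from the closed-form low-field susceptibility
dM/dH|₀ = μ0 Ms Ms_vol π⟨D³⟩/(18 kB T) with ⟨D³⟩ = D0³ e^{4.5σ²}, σ starts
at 0.1 and χ at 0. Only one monotone branch is fitted (the room-temperature
superparamagnetic regime, where hysteresis is negligible);
low-temperature loops are summarized by Ms, Mr, Hc and the derived
K_eff = μ0·Hc·Ms_vol/0.96 (valid for randomly oriented uniaxial ensembles,
squareness ≤ 0.5) rather than fitted.

## Relaxation times

Zero field: τ_B0 = 3ηV_h/kB T and τ_N0 = τ0·e^{σ_a}/2 with
σ_a = K·V_m/kB T; σ_a > 700 overflows and returns +inf with a warning (the
particle is blocked on any laboratory timescale). Field dependence:

* Brown's barrier expression for τ_N(h), h = H/H_k — singular at h = 1
  (domain error), accurate only for h < 0.4 (warning beyond). The
  anisotropy field is implemented as H_k = 2K/(μ0·Ms_vol), the only
  dimensionally consistent form.
* Yoshida–Enpuku τ_B = τ_B0/√(1 + 0.07ξ²), stated validity ξ < 20
  (warning, still computed — the asymptote is what matters at large ξ).
* The empirical Néel analogue is implemented as τ_N0/√(1 + Aξ^C). The
  literal transcription τ_N0·(1+Aξ^C) found in print *increases* with field,
  contradicting both the observed steep decay and the quoted H^{−1.5}
  asymptote for C = 3; it is kept behind `form="literal"` for comparison
  only. Defaults A = 2, C = 3.

Relaxation-regime maps over (D, H) use Brown's field-dependent expression
for the Néel branch by default — the form the regime surfaces in the
literature are drawn with — because the empirical form inherits the
Arrhenius prefactor e^{σ_a} (≈ e^{108} at D = 35 nm for K = 2×10⁴ J/m³),
which no power-law field decay can overcome; cells with h ≥ 1 report
τ_N = +inf. With the standard map parameters (Ms = 450 kA/m, K = 2×10⁴
J/m³, 2 nm shell, water, 300 K) the zero-field column shows the classical
size crossover (Néel below ~15–20 nm, Brown above), and at D = 35 nm the
Néel branch overtakes the Brownian one near ~58 kA/m, inside the
experimental ≤ 65 kA/m range. A regime label is `mixed` when the two times
are within a factor of two.

## SAR models

Γ of the saturation model carries one power of H (Γ = πμ0 f H Ms_vol/ρ), so
the model is parametrized internally by the per-field coefficient
γ = Γ/H: SAR(H) = γ·H·L(ξ)·ωτ/(1+(ωτ)²). This makes the low-field limit
exactly quadratic and identical (to machine precision, verified at relative
10⁻⁶ in tests) to the LRT power per unit mass built independently from
χ0 and χ″ — the cross-model consistency oracle. Reported Γ values are
γ·H_max at the top of the fitted field range, which is the per-curve Γ that
enters the SAR–Γ correlation. ξ uses the AMF amplitude (not RMS), because ξ
is defined once with H the field intensity and the fitting conventions treat
ξ as amplitude-dependent.

## SAR(H) fitting

Free parameters: D, C, τ_N0, γ; A is fixed at 2 to avoid
overparametrization; Ms_vol is fixed from magnetometry; the Brownian branch
is suppressed for solid-matrix conditions. Two conventions for the
field-dependent Néel term:

* `fixed_h3` — A·k0^C·H³ (k0 = ξ/H): the exponent of H is pinned to 3 and
  the non-field factors of ξ carry the free exponent. This mirrors the
  published convention, but note that C then enters only through the
  amplitude k0^C and is nearly degenerate with τ_N0 away from the ωτ ≈ 1
  crossover.
* `strict` — A·ξ^C: C applies to the whole of ξ and is identified by the
  high-field log-log slope. The two agree at C = 3. The parameter-recovery
  study uses this better-conditioned variant.

Numerics: trust-region reflective least squares with bounds
(D ∈ [5, 50] nm, C ∈ [1, 6], τ_N0 and γ in log10), multi-started from five
deterministic points (seeded RNG) to guard against local minima; boundary-
pinned parameters are flagged. Residuals are *relative* (fractional) by
default: the synthetic noise is multiplicative, for which fractional
residuals are the maximum-likelihood weighting, and they keep the low-field
points — which pin D through the Langevin curvature — informative.
Unweighted residuals concentrate all weight on the plateau and open a flat
degeneracy valley (a D ≈ 10 nm branch trading against γ) that smears Γ by
tens of percent; `weighting="absolute"` retains that convention for
comparison. γ may alternatively be fixed to its physical value
(`gamma_free=False`), which removes the valley entirely and is the natural
mode when the absolute SAR scale is trusted.

Fitting is per-curve; no parameters are shared across curves or conditions.
Parameter uncertainties come from the Gauss–Newton covariance at the
optimum.

Derived statistics: the plateau SAR estimator averages the points with
H ≥ 50 kA/m (the fitted model's value at top field is available as an
alternative); the quadratic-region coefficient is the no-intercept
least-squares a in SAR = aH² over H ≤ 35 kA/m; condition comparisons are
percentage changes of plateau SAR (immobilized vs aqueous, pre-aligned vs
immobilized); the SAR–Γ and SAR–Ms relationships are ordinary least-squares
lines with Pearson r.

## Synthetic data

Generators are pure functions of a `SyntheticSpec` (seed, noise model,
noise level): identical specs give bit-identical output, and every dataset
carries its generating parameters. Default noise is multiplicative Gaussian;
3% emulates typical calorimetry scatter, 0.5% typical SQUID scatter.

The study-like dataset emulates the structure of the emulated campaign:
four zinc levels (x = 0, 0.1, 0.3, 0.5) with room-temperature Ms of 65.9,
78.5, 93.4, 82.1 A·m²/kg and magnetic sizes of 8.69, 8.51, 7.76, 8.19 nm
(dispersivities 0.16, 0.15, 0.08, 0.07); three dispersion conditions on a
5–65 kA/m grid (13 points) at 355 kHz. Forward SAR curves use D = 18 nm,
C = 3, τ_N0 = 3×10⁻⁵ s — the parameter regime the constrained fits occupy,
chosen so ωτ crosses unity near 40 kA/m and the curves rise
quadratically before flattening above ~35–40 kA/m. Within each condition the
amplitude is rescaled (acting on γ, so each curve remains an exact model
curve with known parameters) to make the high-field plateau exactly
proportional to Ms; the solid-matrix plateau is 70% of the aqueous one, and
pre-alignment multiplies it by 1.2 (zinc-doped) or 1.4 (undoped). Because
the immobilization factor is multiplicative, the per-condition SAR-vs-Ms
lines share r = 1 but have slopes in ratio 0.70 — proportional, not
offset-parallel. The heating-curve generator is a single Newton-cooling
term, T(t) = T_env + (P/k)(1 − e^{−kt/mc}) at 1 Hz; it produces the mild
downward bias of the 10 s initial-slope estimate that motivates the short
window, but no probe lag, field inhomogeneity, or convection.

What passing tests on these data do *not* show: robustness to
interparticle interactions (dipolar chains, aggregation), to non-log-normal
size distributions, to field-dependent anisotropy, or to calorimetric
artefacts beyond single-exponential loss. The alignment effect is treated
as a purely multiplicative gain, not modelled microscopically.

## Problem sizes

The recovery studies use 50 noise seeds per fitter (13-point SAR curves at
3% noise; 50-point magnetization curves at 0.5% noise); the end-to-end
pipeline fits 12 curves. The acceptance script runs all of this in well
under a minute on one CPU; the structure metrics (condition ratios,
ordering, SAR–Γ correlation) are computed on the noiseless dataset, where
they are exact by construction, and fit quality is additionally reported at
1% noise.

## Known limitations

* The empirical field-dependent Néel time is a phenomenological bridge; it
  is not derived from stochastic Landau–Lifshitz–Gilbert dynamics, and its
  τ_N0 in SAR fits is an effective parameter, not the Arrhenius value.
* LRT-family models underestimate hysteretic losses for thermally blocked
  or strongly anisotropic particles; no Stoner–Wohlfarth/dynamic-loop model
  is included.
* The m_Fe normalization of calorimetric SAR follows the per-mg-of-particles
  convention; `iron_mass_conventions` also reports the
  concentration×volume reading, which differs by the particle mass actually
  present (a factor 2 for a 0.5 mL, 1 mg/mL sample), affecting absolute SAR
  only.
* Mass ↔ volume magnetization conversion assumes the bulk magnetite
  density for all compositions; zinc substitution changes ρ by ~1%, well
  below the other systematic uncertainties.
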
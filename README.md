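# magnetherm

Quantitative modelling of magnetic-nanoparticle hyperthermia for
zinc-substituted magnetite (Zn_x Fe_(3-x) O_4) and similar superparamagnetic
systems. The package is aimed at researchers who characterize heating agents
for hyperthermia: it turns the raw observables of such a campaign —
magnetization curves M(H), calorimetric heating curves T(t), and
SAR-versus-field tables SAR(H) — into physical parameters (magnetic size,
anisotropy, relaxation times, heating coefficients) under one consistent set
of models, and ships synthetic-data generators with known ground truth so
every analysis step is testable end to end.

## Models

**Magnetic size from M(H).** A superparamagnetic ensemble with log-normally
distributed core diameters has mass magnetization

    M(H) = Ms ∫ p(D) L(ξ) dD + χH,     L(ξ) = coth ξ − 1/ξ,
    ξ = μ0 Ms_vol V_m H / (kB T),      V_m = πD³/6,

where p(D) is log-normal with median D0 and dispersivity σ, and the χ-term
absorbs paramagnetic impurities. Inverting a measured branch for
(Ms, D0, σ, χ) yields the magnetic diameter D_mean = D0·exp(σ²/2), typically
below the TEM/XRD size because of the magnetically dead surface layer.

**Relaxation.** The moment follows an alternating field by internal reversal
(Néel) or rigid rotation (Brown, τ_B0 = 3ηV_h/kB T), combined in parallel:
1/τ = 1/τ_N + 1/τ_B. Both times fall with field amplitude: the Brownian time
as τ_B0/√(1 + 0.07ξ²) (asymptotically H⁻¹), the Néel time via either Brown's
barrier expression in h = H/H_k or an empirical analogue
τ_N0/√(1 + Aξ^C) (asymptotically H^(−C/2), steeper than Brownian for C = 3).
At high amplitude the Néel channel can therefore dominate even for large
particles whose zero-field behaviour is Brownian.

**Heating.** Linear response theory gives the volumetric power
P = μ0 π χ″ f Hmax² with χ″ = χ0·ωτ/(1+(ωτ)²) — quadratic in field, maximal
at ωτ = 1, valid only while ξ < 1. Replacing the static susceptibility by
the Langevin function and letting τ depend on the field yields the
saturating specific absorption rate

    SAR(H) = Γ (coth ξ − 1/ξ) ωτ(H)/(1 + (ωτ(H))²),   Γ = πμ0 f H Ms/ρ,

which reduces exactly to LRT at low field and flattens above the amplitude
where ωτ crosses unity. Calorimetric SAR comes from the initial slope of
T(t): SAR = m·c·(dT/dt)|₀ / m_Fe.

**The fitting pipeline** fits each measured SAR(H) curve with this model
(free: diameter D, Néel exponent C, zero-field Néel time τ_N0, amplitude Γ;
fixed: A = 2; Brownian branch suppressed for solid-matrix samples), then
derives the comparative statistics across zinc levels and dispersion
conditions: saturation-SAR ordering, immobilization drop, pre-alignment
gain, and the SAR–Γ and SAR–Ms regressions.

## Worked example

Simulate a SAR(H) curve for the x = 0.3 composition (Ms = 93.4 A·m²/kg,
D = 18 nm, C = 3, τ_N0 = 3×10⁻⁵ s) and fit it back:

```sh
$ magnetherm simulate --what sar --seed 1 --out demo
$ magnetherm fit-sar --input demo/sar.csv --condition water --ms 93.4
{
  "D_nm": 17.99999999991234,
  "C": 3.000000000051231,
  "Gamma_W_per_kg": 8508408.301309811,
  "tau_N0_s": 2.9999999993357853e-05,
  "r_squared": 1.0
}
```

All four generating parameters are recovered; Γ ≈ 8.5×10⁶ W/kg is the fitted
amplitude at the top field (65 kA/m). The same analysis over the full
synthetic study (4 compositions × 3 dispersion conditions):

```python
from magnetherm import SyntheticSpec, run_pipeline

report = run_pipeline(SyntheticSpec(seed=1))
fit03 = next(e for e in report["sar_fits"]
             if e["composition_x"] == 0.3 and e["condition"] == "water")
print(f"fitted D = {fit03['D_nm']:.2f} nm, C = {fit03['C']:.2f}, "
      f"Gamma = {fit03['Gamma']:.3g} W/kg, R^2 = {fit03['r_squared']:.4f}")
print("SAR ranking by zinc level:", report["sar_ordering_water"])
comp = report["condition_comparisons"]["0.3"]
print(f"immobilization change: {comp['immobilization_change_pct']:+.1f} %")
print(f"pre-alignment change:  {comp['alignment_change_pct']:+.1f} %")
print(f"SAR-Gamma correlation: r = {report['sar_gamma_correlation']['r']:.3f}")
```

prints

```
fitted D = 18.00 nm, C = 3.00, Gamma = 8.51e+06 W/kg, R^2 = 1.0000
SAR ranking by zinc level: [0.3, 0.5, 0.1, 0.0]
immobilization change: -30.0 %
pre-alignment change:  +20.0 %
SAR-Gamma correlation: r = 0.955
```

The ranking tracks Ms (maximal at x = 0.3), immobilization in a solid matrix
costs 30% of the saturation SAR, pre-alignment in a static field recovers
20% (40% for undoped magnetite), and saturation SAR correlates linearly with
the fitted Γ coefficient.

Other entry points: `magnetherm composition`, `fit-magnetization`,
`compute-sar`, `relaxation-map`, `run-pipeline` (see `--help`).

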
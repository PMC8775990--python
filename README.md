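# mpbleach

Multiphoton photobleaching of red fluorescent proteins (mCherry, mPlum,
tdTomato, jREX-GECO1 and relatives) under two-photon excitation: forward
rate models, rate extraction, parameter inference, safe-operating-point
prediction, and figure-of-merit ranking.

## The problem

Red FPs are attractive for two-photon laser microscopy (deeper imaging in
the tissue transparency window), but at the photon fluxes a femtosecond
laser delivers at the focus (10^27–10^29 photons cm⁻² s⁻¹) they can bleach
extremely fast, especially at 700–800 nm. The bleaching rate *K* follows
*K* ∝ *P*^α, where the exponent α switches from 2 (intrinsic two-photon
photochemistry) to 3–4 and beyond once the average power *P* passes a
threshold *P\**: after the initial two-photon excitation the chromophore
climbs a ladder of one-photon steps ending in electron photodetachment.
Because the fluorescence signal only grows as *P*², operating above *P\**
wastes fluorophore; operating at *P\** maximizes signal-to-background.
This package implements the quantitative model of that physics and the
analysis pipeline that extracts its molecular parameters from data.

## The model

A focused beam is described by a Gaussian–Lorentzian focal field
(waist *w*₀, in-medium Rayleigh length *z_R* = *n*₀π*w*₀²/λ) with a
rectangular pulse train (duration Δτ, repetition rate *f*), so that the
average power *P* = (π/2) *f* hν Δτ *w*₀² *I*₀ sets the peak photon flux
*I*₀. The observed rate is the *I*²-weighted volume average of the local
level-scheme bleaching rate over the sample slab (thickness *l*); all
geometry enters through Γ_i(η) factors depending only on η = *l*/2*z_R*.
The closed-form rate laws are

- order 2: K⁽²⁾ = (1/π²) σ₂ φ₁,ₘ Γ₃(η) / (Δτ f (hν)² w₀⁴) · P²
- order 3 (2+1): K⁽³⁾ = 4/(5π³) σ₂ σₘₙ φₙ Γ₄(η) / (Δτ f² (hν)³ w₀⁶) · P³,
  with a slight-saturation variant quadratic in P/P_s
- order 4 (2+1+1): K⁽⁴⁾ = 4/(9π⁴) σ₂ σₘₙσₙ꜀ Γ₅(η) / (Δτ f³ (hν)⁴ w₀⁸) · P⁴,
  with a strong-saturation variant whose log–log slope tends to 3

where σ₂ is the two-photon absorption cross section (GM), σₘₙ the
one-photon cross section of the intermediate m→n step, σₙ꜀ the
photoionization cross section, φ the reaction quantum yields, and
P_s = (π/4) f hν w₀²/σₘₙ the saturation power. Setting K⁽²⁾ = K⁽⁴⁾ gives the
recommended operating point

P\* = (3π/2) √(φₘ/(σₘₙσₙ꜀)) √(Γ₃/Γ₅) · f hν w₀².

Every closed form is validated against a brute-force oracle that solves the
within-pulse level-scheme kinetics locally and performs the volume and
pulse-train averaging by numerical quadrature. The energy budget *n*hν ≥ VDE (vertical
electron detachment energy) predicts the photon count *n* of the
detachment mechanism and the critical wavelength above which it shuts off
(≈900 nm for mCherry, VDE = 5.52 eV).

## Worked example

Predict the operating threshold for mCherry at 800 nm, then simulate a
noisy power series from the same forward model and run the inference
pipeline on it:

```python
import numpy as np
from mpbleach import (BeamGeometry, LaserConfig, LevelScheme,
                      MolecularPhotophysics, NoiseModel, SimulationSpec,
                      figure_of_merit, infer_pipeline,
                      predict_threshold_power, simulate_power_series)

laser = LaserConfig(lambda_nm=800, f=80e6, dtau=109e-15)
geometry = BeamGeometry.from_units(w0_um=3.78, lambda_nm=800, n0=1.33, l_um=200)
mcherry = MolecularPhotophysics(sigma2_gm=22, phim=1.0e-4,
                                product_mn_nc_explicit=5.0e-36, phiF=0.24)

pstar = predict_threshold_power(mcherry, laser, geometry)
print(f"predicted threshold P* = {pstar*1e3:.1f} mW")
print(f"FOM(4) = {figure_of_merit(4, mcherry):.2e}")

spec = SimulationSpec(molecule=mcherry, laser=laser, geometry=geometry,
                      scheme=[LevelScheme(2), LevelScheme(4, saturated=False)],
                      seed=1, noise=NoiseModel(sigma_rel=0.1))
series = simulate_power_series(spec, np.logspace(-2, np.log10(0.2), 14))
result = infer_pipeline(series, seed=1)
print(f"alpha = {result.alpha.value:.2f} +/- {result.alpha.se:.2f}")
print(f"detected P* = {result.Pstar.value*1e3:.1f} +/- {result.Pstar.se*1e3:.1f} mW")
print(f"recovered phi_m = {result.phi.value:.2e}")
print(f"recovered sigma_mn*sigma_nc = {result.product_mn_nc.value:.2e} cm^4")
```

prints

```
predicted threshold P* = 69.1 mW
FOM(4) = 5.03e-08
alpha = 2.69 +/- 0.08
detected P* = 70.2 +/- 2.0 mW
recovered phi_m = 1.18e-04
recovered sigma_mn*sigma_nc = 4.68e-36 cm^4
```

The predicted threshold (~69 mW — keep the laser at or below this power at
800 nm) is recovered by the fit of the noisy series to within its error
bar; the global exponent 2.69 reflects a series straddling the bend between
the quadratic and quartic regimes; the recovered quantum yield and
cross-section product agree with the generating values (1.0e-4 and
5.0e-36 cm⁴) at the 10%-noise level. FOM(4) ≈ 5×10⁻⁸ is the relative
number of fluorescence photons obtainable before bleaching in the
fourth-order regime, used to rank proteins and wavelengths.

A thin CLI mirrors the library (`mpbleach simulate`, `extract-rates`,
`fit-power-series`, `predict-threshold`, `photons-required`, `fom`,
`calibrate-beam`, `correct-spectrum`).

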
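# Methods

This note documents the physical model implemented in `mpbleach`, the
numerical and statistical choices made where the design was open, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.

## Focal field and observables

The excitation field is the paraxial Gaussian–Lorentzian (GL) distribution

    I(r, z) = I0 · w0²/w(z)² · exp(−2r²/w(z)²),
    w(z)²  = w0² (1 + ((z−z0)/zR)²),   zR = n0 π w0² / λ,

with a rectangular temporal pulse of width Δτ at repetition rate f. The
rectangular profile is the default because the closed-form rate laws are
derived for it; the simplification affects only O(1) numerical factors
absorbed consistently throughout. Average power and peak photon flux are
related by P = (π/2) f hν Δτ w0² I0 (photon energy from hc = 1239.841984
eV·nm). The sample is a uniform fluorophore slab of thickness l centred on
the focal plane (the experimental protocol focuses to maximum signal,
which is the slab-centred configuration); all geometry dependence reduces
to η = l/(2 zR).

The observable is the initial decay rate K of the two-photon-excited
fluorescence signal normalized to its starting value. Because detection
weight is ∝ I², every volume average of a local rate ∝ I^(2(i−1)) reduces
to the axial moments

    J_i(η) = ∫_{−η}^{η} (1+ζ²)^(−i) dζ,     Γ_i(η) = J_i(η) / J_1(η).

The J_i are evaluated by the exact arctangent reduction formula and are
cross-checked against adaptive quadrature at import time and in the test
suite (≤1e−8 relative over η ∈ [0.05, 50]). Γ_i(0) = 1 and Γ_i decreases
monotonically to a finite thick-sample limit; the ratios Γ_i/Γ_j that enter
threshold prediction are O(1) and weakly geometry dependent (Γ₃/Γ₅ ≈ 1.34
for a 200 µm colony at ~760 nm).

## Level schemes and rate laws

Bleaching pathways are modelled as a two-photon excitation event rate
g = σ₂ I²/2 followed by zero, one, or two one-photon steps:

* **order 2** — reaction directly from the two-photon-populated state with
  yield φ₁ (lowest state; Kasha regime) or φₘ (higher state; the yield can
  exceed φ₁ when the excess vibronic energy lowers the reaction barrier).
* **order 3 (2+1)** — a one-photon m→n step with cross section σₘₙ, then
  reaction from n with yield φₙ. The m↔n step is treated as a two-level
  system pumped at rate σₘₙI with equal stimulated-emission rate, so the
  within-pulse n population is (1/2)(1 − e^(−2σₘₙI t)).
* **order 4 (2+1+1)** — as order 3 plus a perturbative ionization branch
  σₙ꜀I from n into the detachment continuum (σₙ꜀ ≪ σₘₙ, so depletion of
  the two-level pair by ionization is neglected).

Integrating these per-pulse solutions over entry times, the slab and the
radial profile yields the closed-form laws exposed in
`mpbleach.rate_models`, including the slight-saturation (bracket quadratic
in P/Ps) and strong-saturation (slope → 3) variants, the uniform-beam rate
k₁ = (1/32)(σ₂σₙ꜀/σₘₙ³)(f/Δτ)[X³/2 − X² + X − Xe^(−X)] with
X = 2σₘₙ·(photons per cm² per pulse) = P/Ps, and the threshold
P* = (3π/2)√(φₘ/(σₘₙσₙ꜀))√(Γ₃/Γ₅)·f hν w0². Every prefactor is derived
here from the level-scheme model itself and locked by internal
consistency: the slight-saturation bracket reproduces the cubic law
term-for-term as P/Ps → 0, the strong-saturation prefactor is
dimensionally forced, and the uniform-beam bracket has the X⁴/6 small-X
limit that reproduces the unsaturated quartic law.

**Brute-force oracle.** `brute_force_observed_rate` integrates the exact
per-pulse bleaching probability over the slab with Gauss–Legendre nodes in
z (default 201) and in the substituted radial variable v = e^(−2r²/w²)
(default 96), which maps the radial Gaussian onto [0, 1] and makes the
integrand polynomial-like. Convergence is checked by grid doubling on
request. The closed forms agree with the oracle to machine precision in
their exact regimes; the saturation approximations agree to ≤0.5% (slight
saturation at P/Ps = 0.3) and ≤5% (strong saturation at X ≳ 5).

## Initial-rate extraction

Traces are block-averaged (the instrument's native 2.5 kHz stream is
binned 100:1), normalized to the mean of the first 3 samples, and fit by
ordinary least squares over an initial window. The window rule — stop when
a 5-point moving average of the signal first drops below 1 − d, capped at
the first 20% of the trace, with d = 0.1 by default — is a package choice
(the experimental fits show only the fitted lines, not the rule) selected
to bound the curvature bias of the linear approximation at ≈ d/2 for
exponential-like decays. The moving average prevents single noisy samples
from truncating the window. The reported uncertainty adds this documented
curvature bound (d·K/2) in quadrature to the least-squares slope error, so
coverage of the true rate at 2·K_se is ≈95% in simulation. A
Poisson-weighted option exists for photon-count traces; rising traces
(photoactivation artifacts) are flagged, not silently fit.

## Inference pipeline

Fits of K vs Pⁿ are zero-intercept (no bleaching at zero power) and
weighted by 1/K_se² when uncertainties are available. The stages:

1. **Exponent** α from a weighted log–log fit.
2. **Threshold**: weighted linear fit of K = a₂P² + a₄P⁴ (a linear model
   in the (P², P⁴) basis); P* ≡ √(a₂/a₄), with the uncertainty by the
   delta method. "No threshold" is returned when the 95% CI of a₄ includes
   zero — the package's reproducible replacement for reading bending
   points off a log–log plot — or when the design is ill-conditioned.
3. **Segment fits**: quadratic below P* (slope → φ₁ or φₘ), quartic excess
   K − a₂P² above P* (slope → σₘₙσₙ꜀), cubic for three-photon regimes
   (slope → σₘₙφₙ). Each inversion uses the laser/geometry context and the
   independently known σ₂ at that wavelength.
4. **Saturated fits**: the slight/strong saturation laws depend
   nonlinearly on σₘₙ only; the second parameter (φₙ or σₙ꜀) enters
   linearly and is concentrated out exactly, leaving a 1-D profile
   objective over σₘₙ scanned on [1e−18, 1e−15] cm² with a bounded
   refinement. A flat profile (relative spread < 1e−3) or P/Ps < 0.02
   everywhere raises a non-identifiability error instead of returning an
   arbitrary point on the ridge.
5. **Regime diagnosis**: exponents within ±0.2 of 2, 3, 4 select the
   unsaturated branch of that order; intermediate exponents trigger the
   saturated fits; exponents above 4.5 (the α ≈ 8 regime seen in tdTomato
   at 970–1000 nm) are reported without mechanistic extraction, since no
   order-2..4 law applies and the high-order regime is represented only
   phenomenologically.

Uncertainties of the nonlinear fits are nonparametric bootstrap over
points (default 1000 resamples, seeded); linear-fit uncertainties come
from the weighted least-squares covariance. The published parameter
uncertainties' provenance is unstated, so bootstrap is a package choice.
The pipeline is deterministic given a seed.

## Calibration

* **Knife edge**: cumulative-Gaussian (erf) fit per z position; widths at
  several z fit to the Gaussian-beam hyperbola for (w0, z0). Waists
  outside the instrument's plausible 3.5–5.5 µm band produce a warning.
* **Colony z-profile**: the per-slice two-photon signal of the GL field is
  the area integral of I², a Lorentzian 1/(1+(z/zR)²); a uniform slab
  therefore produces a rect⊗Lorentzian profile with the closed form
  (arctan((z−z_c+l/2)/zR) − arctan((z−z_c−l/2)/zR))/π. Fitting it yields
  l, the in-medium zR (larger than the in-air value by the factor n0) and
  w0 = √(λ zR/(n0π)). The Lorentzian form of the per-slice kernel is
  derived here from the area-integrated I² of the GL field.
* **Pulse duration vs wavelength**: for a reference-dye cuvette much
  thicker than zR, the two-photon signal at constant power obeys
  F₂ ∝ σ₂(λ)·λ/Δτ(λ) (the axial extent zR ∝ w0²/λ cancels the waist and
  the two hν factors contribute λ²), inverted and anchored to the
  transform-limited 109 fs at 1100 nm. The packaged reference-dye 2PA
  table is a synthetic stand-in (labelled as such); substitute a measured
  spectrum for quantitative work.
* **2PE spectrum correction**: pointwise sample/reference signal ratio
  times the corrected reference spectrum, with interpolation (warned) on
  mismatched grids and refusal to extrapolate.

## Synthetic data

The generator produces decay traces, power series, knife-edge scans,
z-profiles and reference signals from the same forward model the analysis
assumes, with seeded noise. Decay traces are true volume-averaged
mixtures: every (r, z) shell decays at its own rate f·p(I(r, z)), so the
traces are non-monoexponential (slower than e^(−Kt) at long times) exactly
as spatially averaged kinetics are. Default observation noise is
multiplicative lognormal with σ_rel = 0.1 (the instrument's detector
statistics are not characterized; 10% is a realistic optical-experiment
scatter and is the level used in the recovery studies); a Poisson
photon-count mode exists. The α ≈ 8 regime is generated phenomenologically
(K = k_ref(P/P_ref)^n) and clearly typed as such, because no mechanistic
equation of order 2–4 covers it.

What passing the generator-fitter round trips does **not** show: the
generator shares the GL field, the level schemes and the noise family with
the analysis, so recovery tests validate internal consistency and
estimator calibration, not the adequacy of the GL/level-scheme model for a
real microscope (aberrations, scattering, fluorophore diffusion, triplet
and dark-state kinetics are all outside the model).

## Study conditions and fixed parameter choices

Simulated recovery studies use the experimental conditions of the colony
assay: f = 80 MHz, Δτ = 109 fs, n0 = 1.33, l = 200 µm, per-wavelength
waists from the calibration tables where published (w0 = 3.63/3.70/3.78 µm
at 760/780/800 nm) and the mid-band 4.5 µm where not, powers spanning
5–120 mW, 10% lognormal noise, 200 seeded replicates. These sizes keep the
full suite under a minute while giving medians stable to ~2%.

The uniform-beam worked example uses the 1 kHz amplifier setting. The
amplifier's pulse duration at the sample is not published with the rest of
the parameters; the package fixes an effective rectangular width of 350 fs
(a regenerative amplifier's ~100–150 fs output stretched by uncompensated
material dispersion in the beam-delivery optics and cuvette is plausibly a
few hundred fs, and the rectangular-equivalent width of a chirped pulse
exceeds its FWHM). The saturation parameter X is independent of this
choice; the absolute rate k₁ scales as 1/Δτ, and the resulting
k₁ ≈ 3.0×10⁻³ s⁻¹ lies inside the independently measured band for this
system.

## Numerical details

* Γ factors: exact reduction formulas, `lru_cache`d per (i, η); quadrature
  validation at import.
* Cancellation-prone brackets (X²/2 − X + 1 − e^(−X) and
  X³/2 − X² + X − Xe^(−X)) switch to alternating series below X = 1e−3 /
  1e−2 respectively.
* Saturated-branch evaluation warns (DomainWarning) instead of silently
  returning negative rates where the bracket leaves its validity domain.
* Degenerate inputs raise typed errors: unsupported orders, nonpositive
  powers, windows shorter than 5 points, colonies thinner than the axial
  resolution, scans that miss the beam edge.
* Critical wavelengths are reported at full precision; published
  comparisons are made at 2 significant figures.

## Known limitations

* Paraxial GL field only: no vector/diffraction-accurate focus, no
  aberrations, no group-velocity-dispersion modelling.
* No fluorophore diffusion (the beam is much larger than an E. coli
  cell), no triplet/dark-state or repetition-rate-dependent kinetics.
* The method of initial rates deliberately ignores the full multi-step
  decay; no global kinetic modelling of whole traces is attempted.
* The two-chromophore-species interpretation of the α ≈ 8 regime is not an
  inference target; the pipeline only reports the exponent there.
* Individual σₘₙ and σₙ꜀ from the strong-saturation fit are weakly
  identified (the product is the robust quantity); bootstrap intervals for
  the factors are correspondingly wide.
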
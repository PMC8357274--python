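# Methods

This note documents the models implemented in `matprofiler`, the
conventions and defaults they use, the numerical choices behind them, and
what the synthetic generators do and do not emulate.

## Conventions and units

Depth is stored in millimetres, increasing downward, with the mat surface
at 0 mm; the salt crust occupies negative depths in spectral stacks (the
interface is the natural optical reference, and the crust has no defined
"surface" once it starts dissolving). Concentrations are mol m⁻³
(numerically mmol L⁻¹), diffusivities m² s⁻¹, fluxes mol m⁻² s⁻¹ positive
downward, volumetric rates mol m⁻³ s⁻¹ with production positive,
wavelengths nm, activities kBq, times s. Each physical operation converts
mm → m internally; files carry exactly one canonical unit per column so
unit errors surface at the I/O boundary, not inside the physics.

## Steady-state profile inversion

The model is 1-D diffusion with a source term at steady state,
`d/dz(D_eff dC/dz) + R(z) = 0`. Advection, bioirrigation and lateral
transport are assumed negligible — reasonable in a cohesive mat matrix,
not in the permeable sand below it. Continuity then gives `R = dJ/dz`
with `J = -D_eff dC/dz`: a depth where flux diverges is a source.

- `diffusive_flux` differences the measured profile once (interval
  midpoints) or fits a moving line (`fitted_slope`, window default 3
  points) when sensor noise matters.
- `local_rates` differences the flux profile once more. Both operators
  are plain first differences, so the discrete rate integral over any
  sub-interval telescopes exactly to the flux difference across it;
  `areal_rate` integrates rates with cell-overlap weights chosen to keep
  that identity exact to floating point, and therefore conserves mass by
  construction.
- Smoothing before differentiation is available but off by default:
  double differencing amplifies noise, but any default smoothing would
  silently bias the analytic identities the tests rely on.

**Effective diffusivity.** The default correction is `D_eff = φ·D₀` with
porosity φ = 0.3 for microsensor work (the value used for flux
calculations in salt-flat mats of this type) and a registered alternative
`D₀/(1+3(1−φ))` for users who prefer a tortuosity-style correction. The
correction choice cancels in forward–inverse round trips, which is why the
simple product is the default. Total sulfide diffuses at
`D_Stot = 0.64 × D_O2`; with `D_O2 = 1.5×10⁻⁹ m² s⁻¹` this gives
`9.6×10⁻¹⁰ ≈ 1×10⁻⁹ m² s⁻¹`.

**Sulfide speciation.** `S_tot = [H₂S]·(1 + 10^(pH−pK₁))` with pK₁ = 7.0
by default. Activity corrections for saturated brines are out of scope;
profiles computed this way carry a warning record saying so, because at
ionic strengths of several molal the apparent pK₁ shifts appreciably.

**Respiration in light vs dark.** Dark respiration is the integrated O₂
consumption of dark steady-state profiles; light respiration is the
integrated consumption zones of light profiles (net-rate partitioning by
sign). This is an approximation — it cannot separate gross photosynthesis
from respiration within one depth interval; light–dark shift transients,
which could, are not implemented (everything here is steady state).

**Pools and turnover.** `pool` offers both a depth-averaged (mol m⁻³) and
a depth-integrated (mol m⁻²) standing stock because budget statements in
the literature are often ambiguous between the two; turnover time is
pool/rate, with a day-based helper (86,400 s).

**Sulfide flux at the oxic boundary.** Supported on either total-sulfide
or H₂S gradients, with a configurable fit window (default 1 mm below the
stated oxic lower bound); which gradient a given study used is typically
not recoverable from its text, so neither is asserted as canonical.

## Light and pigment stratification

Spectral smoothing is a linear (order-1) Savitzky–Golay filter with a
15-nm window applied twice. Evaluated at the centre of a symmetric window
this filter equals a centred moving average; endpoint windows shrink
symmetrically rather than padding by reflection, so constant and linear
spectra are reproduced exactly everywhere — a property the attenuation
identities rely on.

Attenuation is the negative depth gradient of log-irradiance between
consecutive spectra, in mm⁻¹ on interval midpoints. Pigment abundance in
a 10-nm window around a band's peak is operationalized as the *positive*
area between the attenuation curve and the chord connecting the window's
endpoints; windows with non-positive enclosed area score zero. The chord
construction removes any spectrally linear matrix attenuation and keeps
the score nonnegative; it slightly undercounts broad bands whose tails
extend past ±5 nm, consistently across depths, so depth *profiles* of a
pigment remain comparable. Default band centres follow the
methods-grade values (674/624/745/845/902 nm); band definitions are
overridable where instruments calibrate a nanometre differently.

Channel profiles integrate UV (200–400), PAR (400–700) and NIR
(750–950 nm) by the trapezoid rule, on normalized irradiance by default
(normalized-vs-raw is exposed because both conventions exist; normalized
makes the interface value exactly 1 in every channel). Attenuation depth
(e.g. the PAR 1% level) is the first crossing of the target fraction with
log-linear interpolation; a profile that never reaches the fraction
returns `inf` rather than extrapolating.

The hyperspectral mapper is deliberately simplified: smooth, take the
second derivative along wavelength, report the maximum positive curvature
inside the band window per pixel (absorption dips have positive curvature
in reflectance). It ranks pigment abundance monotonically but is not a
calibrated concentration estimate. The ~60 μm/pixel spatial-resolution
metadata is carried through I/O but unused in computation.

## Radiotracer sulfate reduction

The single-step rate equation `SRR = [SO₄²⁻]·φ·a/(a+A)·1.06/t` is used
with [SO₄²⁻] as a porewater concentration and the porosity factor
converting to a whole-sediment-volume basis; 1.06 is the isotope
fractionation correction for ³⁵S. The porosity placement is documented
here rather than asserted as universal, because published usage varies;
homogeneity in φ makes the conversion transparent. Back-reaction
(re-oxidation of labelled sulfide during incubation) is neglected, which
is standard for incubations of a few hours.

Blanks are modelled as instantaneous-kill backgrounds; the MDL is the
mean + 3 SD (sample SD, multiplier configurable) of blank apparent rates
computed with the same equation and context parameters. Censoring flags
rates below the MDL but never zeroes them. Depth aggregation validates
that sections tile [0, horizon] without gaps or overlaps (canonical
layout: a 3.2-mm top slice then 8-mm slices; any tiling is accepted),
weights by overlap length, and averages cores with an unweighted mean.

## Community stratification

Absolute densities are the elementwise product of relative abundances and
total cell counts per layer; abundance vectors must sum to 1 within 10⁻³
(renormalization only on an explicit flag, so silent compositional drift
cannot hide). Guild summaries average replicate layers after scaling by
default; average-then-scale is exposed because the order matters when
replicates differ in total counts. Missing replicates (failed
extractions) are simply absent rows — never imputed. Taxonomy strings are
opaque labels; no database lookups. Layer contrasts compare midpoint of
the min–max range (default) or group means, rendered with the same
nearest-integer "n-fold" formatter used for rate ratios.

## Synthetic scenarios

A `MatScenario` is the ground truth the analysis is tested against:
layered piecewise-constant rates in a diffusive matrix, exponential
spectral attenuation with Gaussian pigment bands (Gaussian in wavelength
*and* in depth, depth integrals evaluated exactly with the error
function), a weakly and uniformly absorbing salt crust, tracer cores
whose section activities are set by inverting the SRR equation, and
multinomially sampled communities.

The solver is a conservative finite-volume scheme on a uniform grid with
exact cell-averaged sources, solved as one tridiagonal system
(`scipy.linalg.solve_banded`). For rate layers whose boundaries fall on
grid nodes the scheme reproduces the piecewise-quadratic closed form to
linear-solve roundoff; boundaries off the grid introduce an O(h) local
error confined to the straddling cells. Dirichlet conditions fix a
concentration; Neumann conditions impose zero flux through a half-cell
balance. Two zero-flux ends are rejected: with a nonzero net source the
problem violates mass balance, and with a zero net source it is determined
only up to a constant. Negative concentrations (possible because the
linear model has no uptake kinetics) are returned as-is with a warning
record, or clipped on request — clipping is opt-in because it destroys
the analytic identities.

Noise models match the error character of each instrument: additive
Gaussian for concentrations and spectra (spectra truncated just above
zero to keep logs finite), multiplicative log-normal for counting
statistics on activities, multinomial sampling for reads. Every stochastic
path is seeded through `numpy.random.default_rng([seed, stream])`; zero
noise plus a fixed seed is bit-reproducible, and the full pipeline writes
byte-identical outputs for a fixed seed.

**The bundled scenario** (`matprofiler.scenarios.default_scenario`)
encodes a five-layer (orange/green/brown/black/gray) inundated mat,
6 mm thick under a 2.5-mm salt crust, and was calibrated once to the
field conditions it emulates: two O₂ production zones near 2 and 4 mm
with realistic volumetric rates (~3×10⁻⁴ mol m⁻³ s⁻¹ photosynthesis,
~10⁻⁴ respiration); sulfide supplied from below with a standing pool of
≈0.2 mol m⁻³; matrix attenuation tuned so PAR falls to 1% of the surface
level ≈3.5 mm into the mat; ≈1% spectrally flat light loss across the
salt crust; pigment bands at the five diagnostic wavelengths at the
depths where the corresponding phototrophs live; a ground-truth SRR
profile peaking near 7 mm at the mat–sediment transition; tracer defaults
of 200 kBq per core, 6.5 h incubation, 300 mol m⁻³ porewater sulfate
(mid-range for these brines), bulk porosity 0.35; and a blank TRIS
fraction of 7×10⁻⁶ with log-normal scatter σ = 0.15, whose expected
mean + 3 SD apparent rate is ≈0.05 μmol m⁻³ s⁻¹ — the intended detection
limit (with a handful of blanks the realized MDL scatters around that
value, which is faithful to how blank-based limits behave). The
overlying-water diffusive boundary layer is exposed as a parameter rather
than fixed, since no field value is asserted.

What the generators do **not** emulate: O₂-limited (nonlinear) uptake
kinetics, transient salinity dynamics, coupled photosynthesis–irradiance
feedback, 2-D/3-D heterogeneity, instrument drift and calibration error,
compositional biases of amplicon PCR, and chromatography-grade pigment
concentrations. Passing tests therefore demonstrate that the *inversion
machinery* is exact and stable under the stated physics — not that real
mats obey that physics everywhere.

## Problem sizes

Defaults keep everything interactive: profiles on a 0.05-mm grid
(~120 nodes over 6 mm), spectra at 1-nm × 0.4-mm resolution
(751 × ~22), tracer cores of 5 sections × 3 replicates, communities of
~10 taxa × 5 layers at 5×10⁴ reads. The property suites run ~100
randomized scenarios in a few seconds.

## Known limitations

- The steady-state assumption is the whole method; applying the inversion
  to a transient profile gives biased rates with no warning.
- Rate recovery degrades within ~2 grid steps of a layer boundary (the
  discrete second difference mixes adjacent layers there).
- Hypersaline activity corrections (speciation, O₂ solubility) are not
  implemented; outputs that depend on them carry warning records.
- The second-derivative HSI mapper is uncalibrated and shares none of the
  radiative-transfer sophistication of imaging-spectroscopy pipelines.
- `fitted_slope` windows shrink at profile ends, so endpoint fluxes lean
  on fewer points than interior ones.
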
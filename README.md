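# matprofiler

Quantitative analysis of depth-stratified biogeochemistry in hypersaline
microbial mats: the kind of laminated, salt-crust-covered mats found on
coastal sabkhas, where oxygenic photosynthesis, aerobic respiration and a
full sulfur cycle are compressed into a few millimetres of depth.

The package is written for microbial ecologists and biogeochemists who
work with microsensor depth profiles (O₂, H₂S, pH), depth-resolved scalar
irradiance spectra, ³⁵S radiotracer cores, and per-layer amplicon + cell
count data, and want to turn those raw measurements into fluxes, rates,
pigment stratification and absolute community profiles — with every step
testable against synthetic ground truth.

## What it computes

**Microprofile inversion.** At steady state a 1-D diffusive system obeys

    J(z) = -D_eff · dC/dz          (Fick's first law)
    R(z) = dJ/dz                   (continuity; production positive)

with depth z positive downward and `D_eff = φ·D₀` (porosity-corrected
molecular diffusivity; the correction is pluggable). Differencing a
measured concentration profile once gives local diffusive fluxes;
differencing the fluxes gives local volumetric conversion rates. On top of
this sit areal rates (`∫R dz` over a depth zone, by selected sign),
oxic-zone average volumetric rates, total sulfide speciation
`S_tot = [H₂S]·(1 + 10^(pH−pK₁))`, interfacial sulfide fluxes, standing
pools, turnover times (`pool / rate`) and fold changes. The discrete
operators satisfy the telescoping mass balance exactly: the rate integral
over any sub-interval equals the flux difference across it.

**Light and pigments.** Depth-resolved irradiance spectra E(λ, z) are
smoothed with a linear Savitzky–Golay filter (15-nm window, two passes),
normalized to the mat–salt interface, and converted to attenuation spectra
`α(λ, z) = -Δln E / Δz`. Pigment abundances (Chl-*a* 674 nm, phycocyanin
624 nm, BChl-*c* 745 nm, BChl-*a* 845/902 nm) are the positive
chord-subtracted areas under the attenuation curve in a 10-nm window
around each absorption peak; channel profiles integrate UV (200–400 nm),
PAR (400–700 nm) and NIR (750–950 nm), and attenuation depths (e.g. the
1%-of-surface PAR depth) are found by log-linear interpolation. A
simplified second-derivative mapper locates pigment absorption in
hyperspectral image cubes.

**Sulfate reduction.** The standard ³⁵S radiotracer rate equation

    SRR = [SO₄²⁻] · φ · a/(a+A) · 1.06 / t

converts the TRIS-recovered tracer fraction of each core section into a
rate per sediment volume, with blank-based minimum detection limits
(mean + 3 SD of blank apparent rates), censoring flags, and
overlap-weighted depth aggregation over the mat and a 3-cm horizon.

**Community stratification.** Per-layer relative amplicon abundances are
scaled to absolute densities,
`(cells/g)_taxon = rel. abundance_taxon × total cells/g`, summarized into
functional guilds (cyanobacteria, sulfate reducers, sulfur oxidizers), and
contrasted between layer groups.

**Synthetic mats.** `matprofiler.synthetic` generates all of the above
from a declarative `MatScenario` with known ground truth: an exact
finite-volume steady-state reaction–diffusion solver for layered
piecewise-constant rates, spectral stacks with Gaussian pigment bands
(in λ and z) in an exponentially attenuating matrix under a weakly
absorbing salt crust, tracer cores whose activities invert exactly to a
prescribed SRR profile, and multinomially sampled layered communities.
All noise is seeded; a zero-noise scenario is bit-reproducible.

## Worked example

```python
from matprofiler import (DiffusionSpec, diffusive_flux, local_rates, areal_rate,
                         avg_volumetric, solve_steady_state, turnover_days,
                         fold_change, format_fold)
from matprofiler.scenarios import default_scenario

scenario = default_scenario(seed=0)
o2 = solve_steady_state(scenario, "O2_light")          # mol m-3 on a 0.05 mm grid
spec = DiffusionSpec("O2", d0=1.5e-9, porosity=0.35)   # D_eff = phi * D0
rates = local_rates(diffusive_flux(o2, spec))          # mol m-3 s-1, production > 0

print(f"gross photosynthesis: {areal_rate(rates, sign='production'):.2e} mol m-2 s-1")
print(f"areal respiration:    {areal_rate(rates, sign='consumption'):.2e} mol m-2 s-1")
print(f"oxic-zone average:    {avg_volumetric(rates, o2):.2e} mol m-3 s-1")

print(f"sulfide turnover: {turnover_days(0.2, 2.4e-6):.2f} days")
print(f"SRR increase on inundation: {format_fold(fold_change(1.1e-6, 6.2e-8))}")
```

prints

```
gross photosynthesis: 4.83e-07 mol m-2 s-1
areal respiration:    3.39e-07 mol m-2 s-1
oxic-zone average:    2.43e-05 mol m-3 s-1
sulfide turnover: 0.96 days
SRR increase on inundation: 18-fold
```

The first three lines invert the bundled inundated-mat scenario: gross
areal O₂ production of ~5×10⁻⁷ mol m⁻² s⁻¹ from the two photosynthesis
zones, the respiration consumed alongside it, and the average volumetric
net rate over the depths where O₂ is present. The last two lines are the
sulfide budget: a standing pool of 0.2 mol m⁻³ turned over by a sulfate
reduction rate of 2.4×10⁻⁶ mol m⁻³ s⁻¹ in about one day, and the ~18-fold
stimulation of mat sulfate reduction when the salt crust dissolves.

A command-line interface mirrors the library
(`matprofiler simulate|rates|spectra|hsi|srr|community|run`); `matprofiler
run --out out/ --seed 0` executes the full pipeline on the bundled
scenario and writes profile/flux/rate/pigment/SRR/community tables plus a
JSON summary. Two runs with the same seed produce byte-identical outputs.

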
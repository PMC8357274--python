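"""Synthetic mat scenarios with known ground truth.

A :class:`MatScenario` describes a layered 1-D mat: piecewise-constant
volumetric production/consumption rates per solute in a diffusive matrix,
exponential spectral attenuation with Gaussian pigment absorption bands,
a salt crust with weak uniform attenuation, and seeded noise models.  The
generators in this module produce steady-state solute profiles, spectral
stacks, radiotracer cores and layered community tables from a scenario, so
every analysis stage can be tested against exact ground truth.

Noise models: additive Gaussian for concentrations, additive Gaussian
truncated at zero for irradiance, multiplicative log-normal for tracer
activities, multinomial counting for community reads.  With all noise
parameters at zero and a fixed seed, outputs are bit-identical across runs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.special import erf

from .profiles import MM_PER_M, DepthProfile, RateDepthProfile, _CORRECTIONS
from .spectra import SpectralStack
from .srr import ISOTOPE_FRACTIONATION, TracerSample

#: boundary condition: fixed concentration (mol m^-3) or the string "zero_flux"
BoundaryCondition = Union[float, str]
ZERO_FLUX = "zero_flux"


@dataclass(frozen=True)
class PigmentBand:
    """A Gaussian pigment absorption band in wavelength and in depth."""

    name: str
    center_wavelength_nm: float
    bandwidth_sigma_nm: float
    peak_attenuation_per_mm: float
    depth_center_mm: float
    depth_sigma_mm: float

    def __post_init__(self) -> None:
        if not (200.0 <= self.center_wavelength_nm <= 950.0):
            raise ValueError("center_wavelength_nm must lie in the instrument range [200, 950]")
        if self.bandwidth_sigma_nm <= 0 or self.depth_sigma_mm <= 0:
            raise ValueError("sigma values must be > 0")
        if self.peak_attenuation_per_mm < 0:
            raise ValueError("peak_attenuation_per_mm must be >= 0")


@dataclass
class MatScenario:
    """Ground-truth description of a synthetic layered mat.

    ``true_rates`` and ``boundary_conditions`` are keyed by profile label
    (e.g. ``"O2_light"``, ``"O2_dark"``, ``"Stot_light"``); the solute for
    diffusivity lookup is the part before the first underscore.  Rates are
    per layer, production positive, in mol m^-3 s^-1.
    """

    layer_boundaries_mm: Sequence[float]
    true_rates: Mapping[str, Sequence[float]]
    diffusivity: Mapping[str, float]
    boundary_conditions: Mapping[str, tuple[BoundaryCondition, BoundaryCondition]]
    porosity: float = 0.35
    correction: str = "linear"
    pigment_bands: Sequence[PigmentBand] = ()
    matrix_attenuation_per_mm: Sequence[float] = ()
    salt_thickness_mm: float = 2.5
    salt_attenuation_per_mm: float = 0.00402
    noise_sd: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.layer_boundaries_mm, dtype=float)
        if len(b) < 2 or not np.all(np.diff(b) > 0):
            raise ValueError("layer_boundaries_mm must be strictly increasing with >= 2 entries")
        if b[0] != 0.0:
            raise ValueError("the first layer boundary must be 0 (mat surface)")
        self.layer_boundaries_mm = b
        n_layers = len(b) - 1
        for key, rates in self.true_rates.items():
            if len(rates) != n_layers:
                raise ValueError(
                    f"true_rates[{key!r}] has {len(rates)} entries for {n_layers} layers"
                )
        if not (0 < self.porosity <= 1):
            raise ValueError("porosity must lie in (0, 1]")
        if any(d <= 0 for d in self.diffusivity.values()):
            raise ValueError("diffusivities must be > 0")
        att = np.asarray(self.matrix_attenuation_per_mm, dtype=float)
        if att.size and (len(att) != n_layers or np.any(att < 0)):
            raise ValueError("matrix_attenuation_per_mm needs one value >= 0 per layer")
        if self.salt_attenuation_per_mm < 0 or self.salt_thickness_mm < 0:
            raise ValueError("salt parameters must be >= 0")
        if any(s < 0 for s in self.noise_sd.values()):
            raise ValueError("noise standard deviations must be >= 0")
        if self.correction not in _CORRECTIONS:
            raise ValueError(f"unknown porosity correction {self.correction!r}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_boundaries_mm) - 1

    @property
    def mat_bottom_mm(self) -> float:
        return float(self.layer_boundaries_mm[-1])

    def solute_of(self, key: str) -> str:
        return key.split("_")[0]

    def d_eff(self, key: str) -> float:
        d0 = self.diffusivity.get(key, self.diffusivity.get(self.solute_of(key)))
        if d0 is None:
            raise KeyError(f"no diffusivity defined for {key!r}")
        return _CORRECTIONS[self.correction](d0, self.porosity)

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-purpose random generator derived from the seed."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


def _cumulative_rate(boundaries_mm: np.ndarray, rates: np.ndarray):
    """Cumulative depth integral of a piecewise-constant rate, in SI units.

    Returns a callable I(z_m) with I(0) = 0; outside [0, L] the integral is
    clamped (no sources outside the layered domain).
    """
    b_m = boundaries_mm / MM_PER_M
    cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(b_m))])
    return lambda z_m: np.interp(z_m, b_m, cum)


def solve_steady_state(
    scenario: MatScenario,
    solute: str,
    grid_step_mm: float = 0.05,
    clip_negative: bool = False,
) -> DepthProfile:
    """Steady-state concentration profile C(z) of one solute.

    Solves ``d/dz(D_eff dC/dz) + R(z) = 0`` on a uniform grid over the
    layered domain with the scenario's boundary conditions, using a
    conservative finite-volume discretization with exact cell-averaged
    sources (for rate layers whose boundaries fall on grid nodes the
    discrete solution matches the piecewise-quadratic closed form to
    linear-solve roundoff).  Concentrations are in mol m^-3.

    Negative concentrations are clipped to 0 only when ``clip_negative``
    is set; otherwise they are returned as-is with a warning record.
    """
    if grid_step_mm <= 0:
        raise ValueError("grid_step_mm must be > 0")
    if solute not in scenario.true_rates:
        raise KeyError(f"no rates defined for {solute!r}")
    if solute not in scenario.boundary_conditions:
        raise KeyError(f"no boundary conditions defined for {solute!r}")
    top, bottom = scenario.boundary_conditions[solute]
    rates = np.asarray(scenario.true_rates[solute], dtype=float)
    L_mm = scenario.mat_bottom_mm
    n = max(int(round(L_mm / grid_step_mm)), 1) + 1
    depth_mm = np.linspace(0.0, L_mm, n)
    h = (L_mm / (n - 1)) / MM_PER_M
    d_eff = scenario.d_eff(solute)

    if top == ZERO_FLUX and bottom == ZERO_FLUX:
        net = float(np.sum(rates * np.diff(scenario.layer_boundaries_mm) / MM_PER_M))
        if abs(net) > 0:
            raise ValueError(
                f"inconsistent boundary conditions for {solute!r}: both ends are zero-flux "
                f"but the net source is {net:.3e} mol m-2 s-1 (mass balance violated)"
            )
        raise ValueError(
            f"boundary conditions for {solute!r} leave the profile determined only up to "
            "a constant (both ends zero-flux); fix a concentration at one boundary"
        )

    cum = _cumulative_rate(scenario.layer_boundaries_mm, rates)
    z_m = depth_mm / MM_PER_M
    edges = np.concatenate([[z_m[0]], 0.5 * (z_m[1:] + z_m[:-1]), [z_m[-1]]])
    cell_src = cum(edges[1:]) - cum(edges[:-1])  # integral of R over each cell

    # tridiagonal system in banded form for scipy.linalg.solve_banded
    ab = np.zeros((3, n))
    rhs = np.zeros(n)
    c = d_eff / h
    # interior mass balance: F_{i+1/2} - F_{i-1/2} = integral of R over cell i
    ab[0, 2:] = -c
    ab[1, 1:-1] = 2 * c
    ab[2, :-2] = -c
    rhs[1:-1] = cell_src[1:-1]
    if top == ZERO_FLUX:
        ab[1, 0] = c
        ab[0, 1] = -c
        rhs[0] = cell_src[0]
    else:
        ab[1, 0] = 1.0
        ab[0, 1] = 0.0
        rhs[0] = float(top)
    if bottom == ZERO_FLUX:
        ab[1, -1] = c
        ab[2, -2] = -c
        rhs[-1] = cell_src[-1]
    else:
        ab[1, -1] = 1.0
        ab[2, -2] = 0.0
        rhs[-1] = float(bottom)

    conc = solve_banded((1, 1), ab, rhs)

    warnings: list[str] = []
    sd = scenario.noise_sd.get(solute, scenario.noise_sd.get(scenario.solute_of(solute), 0.0))
    if sd > 0:
        conc = conc + scenario.rng(f"profile:{solute}").normal(0.0, sd, size=n)
        warnings.append(f"additive Gaussian noise, sd={sd} mol m-3")
    if np.any(conc < 0):
        if clip_negative:
            conc = np.clip(conc, 0.0, None)
            warnings.append("negative concentrations clipped to 0")
        else:
            warnings.append("negative concentrations returned un-clipped")

    condition = None
    for tag in ("light", "dark"):
        if solute.endswith("_" + tag):
            condition = tag
    return DepthProfile(
        depth_mm=depth_mm,
        value=conc,
        quantity=scenario.solute_of(solute),
        condition=condition,
        warnings=warnings,
        validate=False,
    )


def true_rate_profile(scenario: MatScenario, solute: str, grid_step_mm: float = 0.05) -> RateDepthProfile:
    """The scenario's piecewise-constant ground-truth rates sampled on a grid."""
    rates = np.asarray(scenario.true_rates[solute], dtype=float)
    b = scenario.layer_boundaries_mm
    n = max(int(round(scenario.mat_bottom_mm / grid_step_mm)), 1) + 1
    depth = np.linspace(0.0, scenario.mat_bottom_mm, n)
    idx = np.clip(np.searchsorted(b, depth, side="right") - 1, 0, scenario.n_layers - 1)
    condition = "light" if solute.endswith("_light") else ("dark" if solute.endswith("_dark") else None)
    return RateDepthProfile(depth, rates[idx], scenario.solute_of(solute), condition)


def _default_incident_spectrum(wavelength_nm: np.ndarray) -> np.ndarray:
    """Smooth halogen-lamp-like incident spectrum (3200 K Planck shape, peak 1)."""
    wl_m = wavelength_nm * 1e-9
    h, c, kb, T = 6.626e-34, 2.998e8, 1.381e-23, 3200.0
    planck = 1.0 / (wl_m**5 * np.expm1(h * c / (wl_m * kb * T)))
    return planck / planck.max()


def generate_spectral_stack(
    scenario: MatScenario,
    wavelengths_nm: np.ndarray | None = None,
    depth_step_mm: float = 0.4,
    incident: np.ndarray | None = None,
    include_salt: bool = True,
) -> SpectralStack:
    """Synthetic scalar-irradiance stack E(lambda, z) for a scenario.

    ``E(l, z) = E(l, top) * exp(-tau(l, z))`` where the optical depth tau
    accumulates the salt crust's uniform attenuation (negative depths), the
    per-layer matrix attenuation and the Gaussian pigment bands (Gaussian
    both in wavelength and in depth; the depth integral is evaluated
    exactly with the error function).  The default depth step of 0.4 mm
    matches the optical microsensor profiling interval.
    """
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(200.0, 951.0, 1.0)
    wl = np.asarray(wavelengths_nm, dtype=float)
    if wl.size == 0:
        raise ValueError("wavelength grid is empty")
    if depth_step_mm <= 0:
        raise ValueError("depth_step_mm must be > 0")
    if include_salt and scenario.salt_thickness_mm > 0:
        n_salt = int(np.ceil(scenario.salt_thickness_mm / depth_step_mm - 1e-9))
    else:
        n_salt = 0
    n_mat = int(np.ceil(scenario.mat_bottom_mm / depth_step_mm - 1e-9))
    depth = np.round(np.arange(-n_salt, n_mat + 1) * depth_step_mm, 9)

    att = np.asarray(scenario.matrix_attenuation_per_mm, dtype=float)
    if att.size == 0:
        att = np.zeros(scenario.n_layers)
    cum_matrix = _cumulative_rate(scenario.layer_boundaries_mm, att * MM_PER_M)

    salt_top = -scenario.salt_thickness_mm
    salt_path = np.clip(np.minimum(depth, 0.0) - salt_top, 0.0, scenario.salt_thickness_mm)
    tau = scenario.salt_attenuation_per_mm * salt_path  # (n_depths,)
    tau = tau + cum_matrix(np.clip(depth, 0.0, None) / MM_PER_M)
    tau = np.broadcast_to(tau, (len(wl), len(depth))).copy()

    z = np.clip(depth, 0.0, None)
    for band in scenario.pigment_bands:
        g_wl = np.exp(-0.5 * ((wl - band.center_wavelength_nm) / band.bandwidth_sigma_nm) ** 2)
        s = band.depth_sigma_mm
        zc = band.depth_center_mm
        # exact integral of the depth Gaussian from the interface to z (mm)
        g_z_int = s * np.sqrt(np.pi / 2.0) * (
            erf((z - zc) / (np.sqrt(2.0) * s)) - erf((0.0 - zc) / (np.sqrt(2.0) * s))
        )
        tau += band.peak_attenuation_per_mm * g_wl[:, None] * g_z_int[None, :]

    e0 = _default_incident_spectrum(wl) if incident is None else np.asarray(incident, dtype=float)
    if e0.shape != wl.shape:
        raise ValueError("incident spectrum must match the wavelength grid")
    irr = e0[:, None] * np.exp(-tau)

    sd = scenario.noise_sd.get("irradiance", 0.0)
    if sd > 0:
        irr = irr + scenario.rng("spectral_stack").normal(0.0, sd, size=irr.shape)
        irr = np.clip(irr, 1e-12, None)  # truncated at zero (positivity floor)

    return SpectralStack(
        wavelength_nm=wl,
        depth_mm=depth,
        irradiance=irr,
        metadata={"seed": scenario.seed, "pixel_size_um": 60.0},
    )


def _interval_mean(profile: RateDepthProfile, lo_mm: float, hi_mm: float) -> float:
    """Trapezoidal mean of a rate profile over [lo, hi] mm (end values clamped)."""
    inner = profile.depth_mm[(profile.depth_mm > lo_mm) & (profile.depth_mm < hi_mm)]
    grid = np.concatenate([[lo_mm], inner, [hi_mm]])
    vals = np.interp(grid, profile.depth_mm, profile.rate)
    return float(np.trapezoid(vals, grid) / (hi_mm - lo_mm))


def generate_tracer_cores(
    scenario: MatScenario,
    true_srr: RateDepthProfile,
    incubation_time_s: float = 23_400.0,
    total_activity_kbq: float = 200.0,
    n_replicates: int = 3,
    seed: int | None = None,
    sulfate_mol_m3: float = 300.0,
    horizon_mm: float = 30.0,
    top_section_mm: float = 3.2,
    section_mm: float = 8.0,
    top_volume_ml: float = 0.4,
    section_volume_ml: float = 1.0,
    n_blanks: int = 0,
    blank_tris_fraction: float = 7.0e-6,
    blank_spread_sigma: float = 0.15,
) -> list[TracerSample]:
    """Synthetic 35S syringe cores consistent with a known SRR depth profile.

    Cores are sectioned into a ``top_section_mm`` top slice followed by
    ``section_mm`` slices until the horizon is covered (the canonical
    3.2 mm + 8 mm layout).  The tracer partitions over sections in
    proportion to section volume; within each section the TRIS activity is
    set by inverting the radiotracer rate equation, so that
    :func:`matprofiler.srr.compute_srr` recovers the section-mean true rate
    exactly at zero noise.  Replicate noise is multiplicative log-normal
    (sd from ``scenario.noise_sd['tracer']``).  Optional blanks carry a
    small apparent TRIS fraction (log-normal scatter around
    ``blank_tris_fraction``) for detection-limit estimation.
    """
    if incubation_time_s <= 0:
        raise ValueError("incubation_time_s must be > 0")
    if total_activity_kbq <= 0:
        raise ValueError("total_activity_kbq must be > 0")
    edges = [0.0, top_section_mm]
    while edges[-1] < horizon_mm - 1e-9:
        edges.append(edges[-1] + section_mm)
    volumes = [top_volume_ml] + [section_volume_ml] * (len(edges) - 2)
    total_volume = float(sum(volumes))

    sd = scenario.noise_sd.get("tracer", 0.0)
    rng = scenario.rng("tracer_cores") if seed is None else np.random.default_rng([seed, 0])
    phi = scenario.porosity
    denom = sulfate_mol_m3 * phi * ISOTOPE_FRACTIONATION

    samples: list[TracerSample] = []
    for rep in range(1, n_replicates + 1):
        for (lo, hi), vol in zip(zip(edges[:-1], edges[1:]), volumes):
            rate = _interval_mean(true_srr, lo, hi)
            if rate < 0:
                raise ValueError("true SRR must be >= 0 everywhere")
            frac = rate * incubation_time_s / denom
            if frac > 1.0:
                raise ValueError(
                    f"true rate {rate:.3e} mol m-3 s-1 in section [{lo}, {hi}] mm would "
                    "require more TRIS activity than the injected tracer (tracer exhaustion)"
                )
            activity = total_activity_kbq * vol / total_volume
            a = frac * activity
            residual = activity - a
            if sd > 0:
                a *= np.exp(rng.normal(0.0, sd) - 0.5 * sd**2)
                residual *= np.exp(rng.normal(0.0, sd) - 0.5 * sd**2)
            samples.append(
                TracerSample(
                    core_id=f"core{rep}",
                    section_top_mm=lo,
                    section_bottom_mm=hi,
                    section_volume_ml=vol,
                    tris_activity_kbq=a,
                    residual_sulfate_activity_kbq=residual,
                    sulfate_mol_m3=sulfate_mol_m3,
                    porosity=phi,
                    incubation_time_s=incubation_time_s,
                )
            )
    for k in range(1, n_blanks + 1):
        frac = blank_tris_fraction * np.exp(
            rng.normal(0.0, blank_spread_sigma) - 0.5 * blank_spread_sigma**2
        )
        samples.append(
            TracerSample(
                core_id=f"blank{k}",
                section_top_mm=0.0,
                section_bottom_mm=edges[-1],
                section_volume_ml=total_volume,
                tris_activity_kbq=frac * total_activity_kbq,
                residual_sulfate_activity_kbq=(1.0 - frac) * total_activity_kbq,
                sulfate_mol_m3=sulfate_mol_m3,
                porosity=phi,
                incubation_time_s=incubation_time_s,
                is_blank=True,
            )
        )
    return samples


def generate_community(
    layer_labels: Sequence[str],
    taxon_profiles: pd.DataFrame | Mapping[str, Mapping[str, float]],
    total_counts_per_layer: Mapping[str, float],
    seed: int = 0,
    read_depth: int = 50_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial amplicon read sampling from per-layer taxon proportions.

    ``taxon_profiles`` is a taxa x layers table of true proportions (each
    layer column sums to 1 within 1e-9).  Returns ``(relative_abundances,
    read_counts)`` as taxa x layers DataFrames; relative abundances sum to
    1 per layer.  A non-positive ``read_depth`` is an error.
    """
    profiles = pd.DataFrame(taxon_profiles).astype(float).fillna(0.0)
    missing = [l for l in layer_labels if l not in profiles.columns]
    if missing:
        raise ValueError(f"taxon_profiles lacks columns for layers {missing}")
    profiles = profiles[list(layer_labels)]
    if (profiles.values < 0).any():
        raise ValueError("taxon proportions must be >= 0")
    sums = profiles.sum(axis=0)
    if not np.allclose(sums.values, 1.0, atol=1e-9):
        bad = sums[~np.isclose(sums, 1.0, atol=1e-9)]
        raise ValueError(f"per-layer proportions must sum to 1 within 1e-9; got {dict(bad)}")
    if read_depth <= 0:
        raise ValueError("read_depth must be a positive number of reads")
    for layer in layer_labels:
        if layer not in total_counts_per_layer:
            raise ValueError(f"no total cell count for layer {layer!r}")

    counts = pd.DataFrame(index=profiles.index, columns=list(layer_labels), dtype=float)
    for i, layer in enumerate(layer_labels):
        rng = np.random.default_rng([seed, i])
        counts[layer] = rng.multinomial(read_depth, profiles[layer].values)
    rel = counts / read_depth
    return rel, counts
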
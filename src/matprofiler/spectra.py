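"""Depth-resolved scalar-irradiance spectra and pigment stratification.

A spectral stack holds scalar irradiance E(lambda, z) measured every few
hundred micrometres through salt crust, mat and sediment.  Attenuation
spectra are the negative depth gradient of the log-transformed spectra;
photopigment abundances are estimated as the convex area under the
attenuation curve inside a 10-nm window around each pigment's absorption
peak, after removing the end-point chord (which rejects spectrally sloping
matrix attenuation).  Channel profiles integrate irradiance over UV, PAR
and NIR wavebands; a simplified second-derivative mapper locates pigment
absorption in hyperspectral image cubes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._filters import centered_moving_mean
from .profiles import DepthProfile, _as_1d_float, _check_strictly_increasing

#: default wavebands in nm: UV, photosynthetically active radiation, near-IR
CHANNELS: dict[str, tuple[float, float]] = {
    "UV": (200.0, 400.0),
    "PAR": (400.0, 700.0),
    "NIR": (750.0, 950.0),
}


@dataclass
class SpectralStack:
    """Scalar irradiance E(lambda, z) on a wavelength x depth grid.

    Depth 0 mm is the mat-salt interface; negative depths address the salt
    crust.  Irradiance is in arbitrary linear units and must be strictly
    positive wherever defined.
    """

    wavelength_nm: np.ndarray
    depth_mm: np.ndarray
    irradiance: np.ndarray  # shape (n_wavelengths, n_depths)
    normalized: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength_nm = _as_1d_float(self.wavelength_nm, "wavelength_nm")
        self.depth_mm = _as_1d_float(self.depth_mm, "depth_mm")
        self.irradiance = np.asarray(self.irradiance, dtype=float)
        if len(self.wavelength_nm) == 0:
            raise ValueError("wavelength grid is empty")
        _check_strictly_increasing(self.wavelength_nm, "wavelength_nm")
        _check_strictly_increasing(self.depth_mm, "depth_mm")
        if self.irradiance.shape != (len(self.wavelength_nm), len(self.depth_mm)):
            raise ValueError(
                f"irradiance shape {self.irradiance.shape} does not match "
                f"(n_wavelengths={len(self.wavelength_nm)}, n_depths={len(self.depth_mm)})"
            )
        if np.any(self.irradiance <= 0):
            raise ValueError("irradiance must be strictly positive everywhere")


@dataclass
class AttenuationStack:
    """Spectral attenuation alpha(lambda, z) in mm^-1 on depth-interval midpoints."""

    wavelength_nm: np.ndarray
    depth_mm: np.ndarray
    attenuation: np.ndarray  # shape (n_wavelengths, n_depths)

    def __post_init__(self) -> None:
        self.wavelength_nm = _as_1d_float(self.wavelength_nm, "wavelength_nm")
        self.depth_mm = _as_1d_float(self.depth_mm, "depth_mm")
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        if self.attenuation.shape != (len(self.wavelength_nm), len(self.depth_mm)):
            raise ValueError("attenuation shape does not match the wavelength/depth grids")


@dataclass(frozen=True)
class BandDefinition:
    """A pigment absorption band: peak wavelength plus integration half-window."""

    name: str
    peak_nm: float
    window_half_width_nm: float = 5.0  # 10-nm total window


#: diagnostic photopigment bands (peak absorption wavelengths in nm)
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("chlorophyll_a", 674.0),
    BandDefinition("phycocyanin", 624.0),
    BandDefinition("bacteriochlorophyll_c", 745.0),
    BandDefinition("bacteriochlorophyll_a_845", 845.0),
    BandDefinition("bacteriochlorophyll_a_902", 902.0),
)


def _window_points(wavelength_nm: np.ndarray, window_nm: float) -> int:
    steps = np.diff(wavelength_nm)
    if len(steps) and not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("smoothing requires a uniform wavelength grid")
    step = steps[0] if len(steps) else window_nm
    npts = int(round(window_nm / step))
    if npts % 2 == 0:
        npts += 1
    return max(npts, 3)


def smooth_spectrum(
    wavelength_nm: np.ndarray,
    values: np.ndarray,
    window_nm: float = 15.0,
    passes: int = 2,
) -> np.ndarray:
    """Linear Savitzky-Golay smoothing (15-nm window, two passes by default).

    The window is converted from nm to an odd number of grid points.  An
    order-1 filter evaluated at the window centre equals a centred moving
    average; endpoint windows shrink symmetrically so constant and linear
    spectra are preserved exactly.  ``values`` may be n-d with wavelength
    on the last axis.
    """
    wavelength_nm = _as_1d_float(wavelength_nm, "wavelength_nm")
    arr = np.asarray(values, dtype=float)
    npts = _window_points(wavelength_nm, window_nm)
    if npts > arr.shape[-1]:
        raise ValueError(
            f"smoothing window ({npts} points) is wider than the spectrum ({arr.shape[-1]})"
        )
    half = npts // 2
    for _ in range(passes):
        arr = centered_moving_mean(arr, half, axis=-1)
    return arr


def normalize_stack(stack: SpectralStack, reference_depth_mm: float = 0.0) -> SpectralStack:
    """Normalize every spectrum to the spectrum at the reference depth.

    After normalization the values represent the fraction of light at the
    mat-salt interface (the reference row becomes exactly 1).  The nearest
    grid depth within half a depth step of ``reference_depth_mm`` is used.
    """
    idx = int(np.argmin(np.abs(stack.depth_mm - reference_depth_mm)))
    step = np.median(np.diff(stack.depth_mm)) if len(stack.depth_mm) > 1 else np.inf
    if abs(stack.depth_mm[idx] - reference_depth_mm) > 0.5 * step + 1e-12:
        raise ValueError(
            f"no grid depth within half a depth step of the reference "
            f"({reference_depth_mm} mm); nearest is {stack.depth_mm[idx]} mm"
        )
    ref = stack.irradiance[:, idx]
    if np.any(ref <= 0):
        raise ValueError("zero or negative irradiance at the reference depth")
    return SpectralStack(
        wavelength_nm=stack.wavelength_nm.copy(),
        depth_mm=stack.depth_mm.copy(),
        irradiance=stack.irradiance / ref[:, None],
        normalized=True,
        metadata=dict(stack.metadata, reference_depth_mm=float(stack.depth_mm[idx])),
    )


def attenuation_spectra(stack: SpectralStack) -> AttenuationStack:
    """Attenuation as the negative gradient of consecutive log-spectra.

    ``alpha(lambda, z_mid) = -[ln E(l, z_{i+1}) - ln E(l, z_i)] / (z_{i+1} - z_i)``
    in mm^-1, on the midpoints of the depth intervals.
    """
    if len(stack.depth_mm) < 2:
        raise ValueError("at least 2 depths are required to compute attenuation")
    log_e = np.log(stack.irradiance)
    dz = np.diff(stack.depth_mm)
    alpha = -np.diff(log_e, axis=1) / dz[None, :]
    mid = 0.5 * (stack.depth_mm[1:] + stack.depth_mm[:-1])
    return AttenuationStack(stack.wavelength_nm.copy(), mid, alpha)


def pigment_abundance(att: AttenuationStack, band: BandDefinition) -> DepthProfile:
    """Per-depth pigment abundance from the band's attenuation peak area.

    For each depth the attenuation curve inside the band window (peak
    +/- half-width) is reduced by the chord connecting the window's
    endpoints; the enclosed area (trapezoidal, in mm^-1 nm) is the
    abundance if positive, else 0.  The chord construction removes any
    spectrally linear matrix attenuation and keeps the score nonnegative.
    """
    lo = band.peak_nm - band.window_half_width_nm
    hi = band.peak_nm + band.window_half_width_nm
    wl = att.wavelength_nm
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(
            f"band window [{lo}, {hi}] nm extends outside the wavelength grid "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    mask = (wl >= lo) & (wl <= hi)
    if np.count_nonzero(mask) < 3:
        raise ValueError("band window covers fewer than 3 wavelength samples")
    wl_w = wl[mask]
    curve = att.attenuation[mask, :]
    frac = (wl_w - wl_w[0]) / (wl_w[-1] - wl_w[0])
    chord = curve[0, :] + frac[:, None] * (curve[-1, :] - curve[0, :])
    area = np.trapezoid(curve - chord, wl_w, axis=0)
    return DepthProfile(
        depth_mm=att.depth_mm,
        value=np.clip(area, 0.0, None),
        quantity=band.name,
        unit="mm-1 nm",
    )


def channel_profiles(
    stack: SpectralStack,
    channels: dict[str, tuple[float, float]] | None = None,
    normalize: bool = True,
) -> dict[str, DepthProfile]:
    """Integrated irradiance depth profiles per waveband (UV, PAR, NIR).

    Channels without wavelength coverage are omitted from the result
    rather than fabricated; an error is raised only if no channel overlaps
    the grid.  With ``normalize=True`` each profile is divided by its
    value at the depth closest to the interface (0 mm).
    """
    if channels is None:
        channels = CHANNELS
    out: dict[str, DepthProfile] = {}
    for name, (lo, hi) in channels.items():
        mask = (stack.wavelength_nm >= lo) & (stack.wavelength_nm <= hi)
        if np.count_nonzero(mask) < 2:
            continue
        integral = np.trapezoid(stack.irradiance[mask, :], stack.wavelength_nm[mask], axis=0)
        if normalize:
            ref = integral[int(np.argmin(np.abs(stack.depth_mm)))]
            integral = integral / ref
            unit = "fraction of interface"
        else:
            unit = "a.u. nm"
        out[name] = DepthProfile(stack.depth_mm.copy(), integral, quantity=name, unit=unit)
    if not out:
        raise ValueError("wavelength grid overlaps none of the requested channels")
    return out


def attenuation_depth(profile: DepthProfile, fraction: float) -> float:
    """Depth (mm) at which relative intensity first falls to ``fraction``.

    The profile must be normalized to the surface value.  Log-linear
    interpolation is used between the bracketing points.  If the profile
    never reaches the fraction within its depth range, ``float('inf')`` is
    returned as a sentinel (no silent extrapolation).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    mask = profile.depth_mm >= 0
    z = profile.depth_mm[mask]
    v = profile.value[mask]
    if len(z) == 0 or np.any(v <= 0):
        raise ValueError("profile must have positive values at depths >= 0")
    rel = v / np.interp(0.0, z, v)
    if fraction == 1.0:
        return 0.0
    below = np.nonzero(rel <= fraction)[0]
    if len(below) == 0:
        return float("inf")
    j = below[0]
    if j == 0:
        return float(z[0])
    # log-linear interpolation between the bracketing samples
    r1, r2 = rel[j - 1], rel[j]
    t = (np.log(fraction) - np.log(r1)) / (np.log(r2) - np.log(r1))
    return float(z[j - 1] + t * (z[j] - z[j - 1]))


def hyperspectral_pigment_map(
    cube: np.ndarray,
    wavelength_nm: np.ndarray,
    band: BandDefinition,
    window_nm: float = 15.0,
    passes: int = 2,
) -> np.ndarray:
    """Simplified second-derivative pigment abundance map from an HSI cube.

    ``cube`` has shape (rows, cols, wavelengths) with rows typically the
    depth axis of a vertically sliced core.  Per pixel the spectrum is
    smoothed (linear Savitzky-Golay) and differentiated twice with respect
    to wavelength; the map reports the maximum of the second derivative
    inside the band window.  Absorption dips in reflectance or irradiance
    have positive curvature, so larger values mean more pigment.
    """
    cube = np.asarray(cube, dtype=float)
    wavelength_nm = _as_1d_float(wavelength_nm, "wavelength_nm")
    if cube.ndim != 3 or cube.shape[-1] != len(wavelength_nm):
        raise ValueError("cube must have shape (rows, cols, n_wavelengths)")
    if np.any(cube <= 0):
        raise ValueError("cube values must be strictly positive")
    lo = band.peak_nm - band.window_half_width_nm
    hi = band.peak_nm + band.window_half_width_nm
    if lo < wavelength_nm[0] or hi > wavelength_nm[-1]:
        raise ValueError("band window extends outside the cube's wavelength grid")
    smoothed = smooth_spectrum(wavelength_nm, cube, window_nm=window_nm, passes=passes)
    d1 = np.gradient(smoothed, wavelength_nm, axis=-1)
    d2 = np.gradient(d1, wavelength_nm, axis=-1)
    mask = (wavelength_nm >= lo) & (wavelength_nm <= hi)
    return np.max(d2[..., mask], axis=-1)
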
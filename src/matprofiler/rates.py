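"""Inversion of steady-state microsensor profiles into fluxes and rates.

At steady state a 1-D diffusive system obeys ``dJ/dz = R(z)`` with
``J = -D_eff dC/dz`` (depth z positive downward, flux positive downward,
production positive).  Differencing a measured concentration profile once
gives the local diffusive flux, differencing the flux again gives the local
volumetric conversion rate.  Integrating the rates over depth zones yields
areal rates; the same machinery provides average volumetric rates over the
oxic zone, sulfide speciation, interfacial sulfide fluxes, standing pools,
turnover times and fold changes.

The discrete operators are constructed so that the telescoping identity

    sum_i R_i * dz_i over any sub-interval  ==  J(right face) - J(left face)

holds exactly (to floating point), i.e. mass balance is preserved by the
inversion.
"""

from __future__ import annotations

import numpy as np

from ._filters import centered_moving_mean
from .profiles import (
    MM_PER_M,
    SECONDS_PER_DAY,
    DepthProfile,
    DiffusionSpec,
    FluxProfile,
    RateDepthProfile,
)

#: D_Stot = 0.64 x D_O2 (total sulfide diffuses slower than O2)
STOT_TO_O2_DIFFUSIVITY_RATIO = 0.64


def stot_diffusivity(d_o2: float) -> float:
    """Molecular diffusivity of total sulfide from that of O2 (m^2 s^-1)."""
    if d_o2 <= 0:
        raise ValueError("d_o2 must be > 0")
    return STOT_TO_O2_DIFFUSIVITY_RATIO * d_o2


def total_sulfide(
    h2s: DepthProfile,
    ph: DepthProfile,
    pk1: float = 7.0,
    interpolate: bool = False,
) -> DepthProfile:
    """Total sulfide S_tot = H2S + HS^- from measured H2S and pH.

    Uses the first dissociation equilibrium:
    ``S_tot(z) = H2S(z) * (1 + 10**(pH(z) - pk1))``.

    Activity corrections for hypersaline brines are out of scope; the
    returned profile carries a warning note to that effect.

    Parameters
    ----------
    pk1 : float
        First dissociation constant of H2S; default 7.0, configurable.
    interpolate : bool
        If True, both profiles are linearly interpolated onto the union of
        their depth grids; otherwise mismatched grids raise.
    """
    if len(h2s.depth_mm) == len(ph.depth_mm) and np.allclose(h2s.depth_mm, ph.depth_mm):
        depth = h2s.depth_mm
        h, p = h2s.value, ph.value
    elif interpolate:
        depth = np.union1d(h2s.depth_mm, ph.depth_mm)
        h, p = h2s.interpolated(depth), ph.interpolated(depth)
    else:
        raise ValueError(
            "H2S and pH profiles are on different depth grids; "
            "pass interpolate=True to resample onto the union grid"
        )
    stot = h * (1.0 + 10.0 ** (p - pk1))
    return DepthProfile(
        depth_mm=depth,
        value=stot,
        quantity="Stot",
        unit=h2s.unit,
        condition=h2s.condition,
        salinity_pct=h2s.salinity_pct,
        replicate_id=h2s.replicate_id,
        warnings=["speciation without hypersaline activity corrections"],
    )


def smooth_profile(profile: DepthProfile, window: int = 3) -> DepthProfile:
    """Moving linear fit (centred, shrink-to-fit) of the profile values.

    Optional pre-smoothing before differentiation; double differencing
    amplifies sensor noise.  Off by default in all operations so analytic
    tests stay exact.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd number of points")
    smoothed = centered_moving_mean(profile.value, window // 2)
    return DepthProfile(
        depth_mm=profile.depth_mm,
        value=smoothed,
        quantity=profile.quantity,
        unit=profile.unit,
        condition=profile.condition,
        salinity_pct=profile.salinity_pct,
        replicate_id=profile.replicate_id,
        warnings=profile.warnings + [f"smoothed (moving linear fit, {window} points)"],
        validate=False,
    )


def diffusive_flux(
    profile: DepthProfile,
    spec: DiffusionSpec,
    mode: str = "finite_difference",
    window: int = 3,
) -> FluxProfile:
    """Local diffusive flux J = -D_eff dC/dz from a steady-state profile.

    ``finite_difference`` evaluates Fick's first law on consecutive depth
    intervals and reports fluxes on interval midpoints (length n-1).
    ``fitted_slope`` fits a centred moving line of ``window`` points and
    reports the flux on the original depth grid (shrunk windows at the
    ends).  Positive flux is downward transport.
    """
    if len(profile) < 2:
        raise ValueError("at least 2 depth points are required to compute a flux")
    z_m = profile.depth_mm / MM_PER_M
    d_eff = spec.d_eff
    if mode == "finite_difference":
        mid = 0.5 * (profile.depth_mm[1:] + profile.depth_mm[:-1])
        flux = -d_eff * np.diff(profile.value) / np.diff(z_m)
        return FluxProfile(mid, flux, profile.quantity, profile.condition)
    if mode == "fitted_slope":
        if window < 2:
            raise ValueError("fitted_slope window must span at least 2 points")
        half = max(1, window // 2)
        n = len(profile)
        flux = np.empty(n)
        for i in range(n):
            hw = min(half, i, n - 1 - i)
            hw = max(hw, 1)
            lo, hi = max(0, i - hw), min(n, i + hw + 1)
            slope = np.polyfit(z_m[lo:hi], profile.value[lo:hi], 1)[0]
            flux[i] = -d_eff * slope
        return FluxProfile(profile.depth_mm.copy(), flux, profile.quantity, profile.condition)
    raise ValueError(f"unknown mode {mode!r}; use 'finite_difference' or 'fitted_slope'")


def local_rates(flux: FluxProfile) -> RateDepthProfile:
    """Local volumetric conversion rates from the change in flux with depth.

    At steady state the 1-D continuity equation gives ``R(z) = dJ/dz``
    (production positive: flux diverging away from a depth means a source
    there).  Rates are reported on the midpoints of the flux grid.
    """
    if len(flux) < 2:
        raise ValueError("at least 2 flux points are required to compute rates")
    z_m = flux.depth_mm / MM_PER_M
    mid = 0.5 * (flux.depth_mm[1:] + flux.depth_mm[:-1])
    rate = np.diff(flux.flux) / np.diff(z_m)
    return RateDepthProfile(mid, rate, flux.quantity, flux.condition)


def _cell_edges_mm(depth_mm: np.ndarray) -> np.ndarray:
    """Integration-cell edges for point rates: midpoints between samples,
    extended by half the end spacings, so that on a uniform grid each cell
    is [z - h/2, z + h/2] and rate sums telescope to flux differences."""
    mid = 0.5 * (depth_mm[1:] + depth_mm[:-1])
    first = depth_mm[0] - (mid[0] - depth_mm[0]) if len(mid) else depth_mm[0]
    last = depth_mm[-1] + (depth_mm[-1] - mid[-1]) if len(mid) else depth_mm[-1]
    return np.concatenate([[first], mid, [last]])


def _overlap_weights_mm(edges: np.ndarray, zone: tuple[float, float]) -> np.ndarray:
    lo, hi = zone
    if hi <= lo:
        raise ValueError(f"empty depth zone ({lo}, {hi}) mm")
    return np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)


def areal_rate(
    rates: RateDepthProfile,
    zone: tuple[float, float] | None = None,
    sign: str = "net",
) -> float:
    """Depth-integrated (areal) rate over a zone, in mol m^-2 s^-1.

    ``sign`` selects which rates enter the integral: ``"production"``
    (positive rates), ``"consumption"`` (negative rates, reported as a
    positive magnitude), or ``"net"`` (signed sum).  Each rate sample is
    weighted by the overlap of its grid cell with the zone, so that the net
    integral over the full profile equals the boundary-flux difference
    exactly.
    """
    edges = _cell_edges_mm(rates.depth_mm)
    if zone is None:
        zone = (edges[0], edges[-1])
    w_mm = _overlap_weights_mm(edges, zone)
    if not np.any(w_mm > 0):
        raise ValueError(f"zone {zone} mm does not overlap the rate profile")
    w_m = w_mm / MM_PER_M
    r = rates.rate
    if sign == "net":
        selected = r
    elif sign == "production":
        selected = np.clip(r, 0.0, None)
    elif sign == "consumption":
        selected = np.clip(-r, 0.0, None)
    else:
        raise ValueError(f"unknown sign {sign!r}; use 'production', 'consumption' or 'net'")
    return float(np.sum(selected * w_m))


def avg_volumetric(
    rates: RateDepthProfile,
    o2: DepthProfile,
    threshold: float = 0.0,
) -> float:
    """Average volumetric rate across mat depth where O2 exceeds a threshold.

    The default threshold of 0 mol m^-3 restricts the average to the oxic
    zone; set it to the sensor detection limit to be stricter.  Returns
    mol m^-3 s^-1 (cell-width-weighted mean over the masked depths).
    """
    o2_on_rates = o2.interpolated(rates.depth_mm)
    mask = o2_on_rates > threshold
    if not np.any(mask):
        raise ValueError(
            f"no depth in the rate profile has O2 above the threshold ({threshold} mol m-3)"
        )
    edges = _cell_edges_mm(rates.depth_mm)
    w = edges[1:] - edges[:-1]
    return float(np.sum(rates.rate[mask] * w[mask]) / np.sum(w[mask]))


def interfacial_sulfide_flux(
    stot: DepthProfile,
    spec: DiffusionSpec,
    oxic_lower_bound_mm: float,
    window_mm: float = 1.0,
) -> float:
    """Upward sulfide flux magnitude at the top of the sulfide gradient.

    Fits a line to the S_tot profile in the window just below the oxic zone
    (``[oxic_lower_bound, oxic_lower_bound + window_mm]``) and evaluates
    Fick's first law on the fitted slope.  Reported as a positive magnitude
    (direction: upward, toward the oxic zone).
    """
    lo, hi = oxic_lower_bound_mm, oxic_lower_bound_mm + window_mm
    mask = (stot.depth_mm >= lo) & (stot.depth_mm <= hi)
    if np.count_nonzero(mask) < 2:
        raise ValueError(
            f"fit window [{lo}, {hi}] mm contains fewer than 2 points of the S_tot profile"
        )
    z_m = stot.depth_mm[mask] / MM_PER_M
    slope = np.polyfit(z_m, stot.value[mask], 1)[0]
    return float(spec.d_eff * abs(slope))


def pool(
    profile: DepthProfile,
    zone: tuple[float, float] | None = None,
    mode: str = "depth_averaged",
) -> float:
    """Standing stock of a solute over a depth zone.

    ``depth_averaged`` returns the trapezoidal mean concentration
    (mol m^-3); ``depth_integrated`` returns the depth integral
    (mol m^-2).  Zone endpoints are interpolated into the profile.
    """
    if zone is None:
        zone = (float(profile.depth_mm[0]), float(profile.depth_mm[-1]))
    lo, hi = zone
    if hi <= lo:
        raise ValueError(f"empty depth zone ({lo}, {hi}) mm")
    if hi < profile.depth_mm[0] or lo > profile.depth_mm[-1]:
        raise ValueError(f"zone {zone} mm lies outside the profile span")
    inner = profile.depth_mm[(profile.depth_mm > lo) & (profile.depth_mm < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = profile.interpolated(grid)
    integral_m = np.trapezoid(vals, grid / MM_PER_M)
    if mode == "depth_integrated":
        return float(integral_m)
    if mode == "depth_averaged":
        return float(integral_m / ((hi - lo) / MM_PER_M))
    raise ValueError(f"unknown mode {mode!r}; use 'depth_averaged' or 'depth_integrated'")


def turnover_time(pool_value: float, rate: float) -> float:
    """Turnover time in seconds: standing pool divided by its turnover rate."""
    if rate <= 0:
        raise ValueError("turnover is undefined for rate <= 0")
    if pool_value < 0:
        raise ValueError("pool must be >= 0")
    return pool_value / rate


def turnover_days(pool_value: float, rate: float) -> float:
    """Turnover time in days (86,400 s per day)."""
    return turnover_time(pool_value, rate) / SECONDS_PER_DAY


def fold_change(numerator: float, denominator: float) -> float:
    """Plain ratio of two rates (e.g. inundated over salt-crust conditions)."""
    if denominator <= 0:
        raise ValueError("fold change is undefined for denominator <= 0")
    return numerator / denominator


def format_fold(ratio: float) -> str:
    """Round a ratio to the nearest integer and render it as ``"n-fold"``."""
    return f"{round(ratio):d}-fold"
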
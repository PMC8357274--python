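"""Depth-indexed containers for microsensor profile analysis.

Conventions used throughout the package:

* depth is stored in millimetres, increasing downward, mat surface at 0 mm
  (negative depths are allowed only in spectral stacks, where they address
  the overlying salt crust);
* concentrations are stored in mol m^-3 (numerically equal to mmol L^-1);
* every physics operation converts depths to metres internally;
* diffusive flux is positive downward; volumetric rates are positive for
  production and negative for consumption.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field
from typing import Callable

import numpy as np

MM_PER_M = 1000.0
SECONDS_PER_DAY = 86_400.0

#: quantities whose concentrations cannot physically be negative
_NONNEGATIVE_QUANTITIES = {"O2", "H2S", "Stot", "SRR"}


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _check_strictly_increasing(depth: np.ndarray, name: str = "depth_mm") -> None:
    if len(depth) > 1 and not np.all(np.diff(depth) > 0):
        raise ValueError(f"{name} must be strictly increasing (duplicate or unsorted depths)")


@dataclass
class DepthProfile:
    """One measured or simulated quantity on a depth grid.

    Parameters
    ----------
    depth_mm : array
        Strictly increasing depths in mm.
    value : array
        Quantity values; mol m^-3 for concentrations, unitless for pH.
    quantity : str
        One of ``"O2" | "H2S" | "pH" | "Stot"`` (other labels are accepted
        for derived quantities such as channel-integrated irradiance).
    condition : str, optional
        ``"light"`` or ``"dark"``.
    validate : bool
        When False, physical range checks are skipped (used by the forward
        solver when returning unclipped negative concentrations together
        with a warning record).
    """

    depth_mm: np.ndarray
    value: np.ndarray
    quantity: str
    unit: str = "mol m-3"
    condition: str | None = None
    salinity_pct: float | None = None
    replicate_id: str | None = None
    warnings: list[str] = field(default_factory=list)
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        self.depth_mm = _as_1d_float(self.depth_mm, "depth_mm")
        self.value = _as_1d_float(self.value, "value")
        if len(self.depth_mm) != len(self.value):
            raise ValueError("depth_mm and value must have equal length")
        _check_strictly_increasing(self.depth_mm)
        if validate:
            if self.quantity in _NONNEGATIVE_QUANTITIES and np.any(self.value < 0):
                raise ValueError(f"{self.quantity} concentrations must be >= 0")
            if self.quantity == "pH" and (np.any(self.value < 0) or np.any(self.value > 14)):
                raise ValueError("pH values must lie in [0, 14]")

    def __len__(self) -> int:
        return len(self.depth_mm)

    def interpolated(self, depth_mm) -> np.ndarray:
        """Linear interpolation of the profile onto new depths (mm)."""
        return np.interp(np.asarray(depth_mm, dtype=float), self.depth_mm, self.value)


@dataclass
class FluxProfile:
    """Diffusive flux J (mol m^-2 s^-1, positive downward) on interval midpoints."""

    depth_mm: np.ndarray
    flux: np.ndarray
    quantity: str
    condition: str | None = None

    def __post_init__(self) -> None:
        self.depth_mm = _as_1d_float(self.depth_mm, "depth_mm")
        self.flux = _as_1d_float(self.flux, "flux")
        if len(self.depth_mm) != len(self.flux):
            raise ValueError("depth_mm and flux must have equal length")
        _check_strictly_increasing(self.depth_mm)
        if not np.all(np.isfinite(self.flux)):
            raise ValueError("flux values must be finite")

    def __len__(self) -> int:
        return len(self.depth_mm)


@dataclass
class RateDepthProfile:
    """Local volumetric conversion rates R(z) (mol m^-3 s^-1, production positive)."""

    depth_mm: np.ndarray
    rate: np.ndarray
    quantity: str
    condition: str | None = None

    def __post_init__(self) -> None:
        self.depth_mm = _as_1d_float(self.depth_mm, "depth_mm")
        self.rate = _as_1d_float(self.rate, "rate")
        if len(self.depth_mm) != len(self.rate):
            raise ValueError("depth_mm and rate must have equal length")
        _check_strictly_increasing(self.depth_mm)
        if not np.all(np.isfinite(self.rate)):
            raise ValueError("rate values must be finite")

    def __len__(self) -> int:
        return len(self.depth_mm)


# -- porosity corrections -----------------------------------------------------
#
# The molecular diffusivity D0 of a solute in free solution is reduced inside
# the mat matrix.  The default correction is the simple porosity scaling
# D_eff = phi * D0; an alternative tortuosity-style correction
# D_eff = D0 / (1 + 3 (1 - phi)) is registered as "tortuosity".

_CORRECTIONS: dict[str, Callable[[float, float], float]] = {
    "linear": lambda d0, phi: phi * d0,
    "tortuosity": lambda d0, phi: d0 / (1.0 + 3.0 * (1.0 - phi)),
}


def register_correction(name: str, func: Callable[[float, float], float]) -> None:
    """Register a custom porosity-correction function ``func(d0, porosity)``."""
    _CORRECTIONS[name] = func


@dataclass(frozen=True)
class DiffusionSpec:
    """Molecular diffusivity plus the porosity correction applied to it.

    Defaults carry the values used for the mat flux calculations:
    D_O2 = 1.5e-9 m^2 s^-1 corrected for a porosity of 0.3.
    """

    solute: str
    d0: float
    porosity: float = 0.3
    correction: str = "linear"

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("molecular diffusivity d0 must be > 0")
        if not (0 < self.porosity <= 1):
            raise ValueError("porosity must lie in (0, 1]")
        if self.correction not in _CORRECTIONS:
            raise ValueError(
                f"unknown porosity correction {self.correction!r}; "
                f"registered: {sorted(_CORRECTIONS)}"
            )

    @property
    def d_eff(self) -> float:
        """Effective diffusivity in the matrix (m^2 s^-1)."""
        return _CORRECTIONS[self.correction](self.d0, self.porosity)
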
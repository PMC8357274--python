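"""Independent analytic oracles used by the test suite.

These deliberately do not share code with the package: the steady-state
reaction-diffusion solution for piecewise-constant rates is built here by
direct analytic integration (flux is piecewise linear, concentration
piecewise quadratic), so it can serve as an oracle for the package's
numerical solver.
"""

from __future__ import annotations

import numpy as np

MM = 1e-3  # mm -> m


def piecewise_quadratic_solution(boundaries_mm, rates, d_eff, top, bottom):
    """Exact steady-state solution of D C'' + R(z) = 0 with layered R.

    ``top``/``bottom`` are fixed concentrations (floats) or "zero_flux".
    Returns a callable C(z_mm).  Built from J(z) = J0 + int_0^z R and
    C(z) = C0 - (1/D) int_0^z J, with the two constants fixed by the
    boundary conditions.
    """
    b = np.asarray(boundaries_mm, dtype=float) * MM
    r = np.asarray(rates, dtype=float)
    L = b[-1]
    # cumulative integral of R at the layer boundaries
    cum = np.concatenate([[0.0], np.cumsum(r * np.diff(b))])
    # integral of the cumulative at the boundaries
    icum = np.zeros_like(cum)
    for k in range(len(r)):
        dz = b[k + 1] - b[k]
        icum[k + 1] = icum[k] + cum[k] * dz + 0.5 * r[k] * dz**2

    def cum_at(z):
        k = np.clip(np.searchsorted(b, z, side="right") - 1, 0, len(r) - 1)
        return cum[k] + r[k] * (z - b[k])

    def icum_at(z):
        k = np.clip(np.searchsorted(b, z, side="right") - 1, 0, len(r) - 1)
        dz = z - b[k]
        return icum[k] + cum[k] * dz + 0.5 * r[k] * dz**2

    if top == "zero_flux" and bottom == "zero_flux":
        raise ValueError("under-determined boundary conditions")
    if top == "zero_flux":
        j0 = 0.0
        c0 = float(bottom) + (j0 * L + icum_at(L)) / d_eff
    elif bottom == "zero_flux":
        c0 = float(top)
        j0 = -cum_at(L)
    else:
        c0 = float(top)
        j0 = d_eff * (c0 - float(bottom)) / L - icum_at(L) / L

    def c_of(z_mm):
        z = np.asarray(z_mm, dtype=float) * MM
        return c0 - (j0 * z + icum_at(z)) / d_eff

    return c_of
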
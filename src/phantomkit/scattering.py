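"""Mie-Rayleigh reduced-scattering power law.

Tissue and white-pigment reduced scattering is modelled as the standard
two-term decomposition

    musp(lambda) = a * [ f * (lambda/lambda0)^-4 + (1 - f) * (lambda/lambda0)^-b ]

with amplitude ``a`` (mm^-1 at the reference wavelength, default 500 nm),
Rayleigh fraction ``f`` in [0, 1] and Mie scattering power ``b`` in [0, 4].
The second stage of the integrating-sphere inversion constrains scattering
to this model to suppress absorption/scattering crosstalk; here the same
model also generates synthetic white-pigment bases and skin-like scattering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .spectra import Spectrum, WavelengthGrid

__all__ = ["PowerLawParams", "power_law_eval", "power_law_fit", "MieRayleighModel"]


@dataclass(frozen=True)
class PowerLawParams:
    a: float
    f_ray: float
    b_mie: float
    lambda0_nm: float = 500.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("amplitude a must be >= 0")
        if not 0.0 <= self.f_ray <= 1.0:
            raise ValueError("Rayleigh fraction must be in [0, 1]")
        if not 0.0 <= self.b_mie <= 4.0:
            raise ValueError("Mie power must be in [0, 4]")


def power_law_eval(p: PowerLawParams, grid: WavelengthGrid) -> Spectrum:
    """Evaluate the Mie-Rayleigh power law on a grid."""
    r = grid.wavelengths / p.lambda0_nm
    vals = p.a * (p.f_ray * r**-4.0 + (1.0 - p.f_ray) * r**-p.b_mie)
    return Spectrum(grid, vals, units="mm^-1")


class MieRayleighModel(BaseEstimator):
    """Bounded least-squares fit of the Mie-Rayleigh power law to a spectrum.

    Parameters
    ----------
    lambda0_nm : reference wavelength for the amplitude, default 500 nm.
    n_starts : number of Rayleigh-fraction starting points; the model surface
        can trade ``f_ray`` against ``b_mie`` near the b = 4 degeneracy, so a
        few restarts are used and the best residual kept.

    Attributes
    ----------
    params_ : PowerLawParams of the best fit.
    residual_ : sum of squared residuals at the solution.
    """

    def __init__(self, lambda0_nm: float = 500.0, n_starts: int = 3):
        self.lambda0_nm = lambda0_nm
        self.n_starts = n_starts

    def fit(self, spectrum: Spectrum, y=None) -> "MieRayleighModel":
        vals = spectrum.values
        if np.any(vals <= 0):
            raise ValueError("power-law fit requires a strictly positive spectrum")
        r = spectrum.wavelengths / self.lambda0_nm

        def model(theta):
            a, f, b = theta
            return a * (f * r**-4.0 + (1.0 - f) * r**-b)

        def resid(theta):
            return model(theta) - vals

        a0 = float(np.interp(1.0, r, vals))
        # crude slope estimate from the log-log endpoints, clipped to bounds
        b0 = float(np.clip(-np.log(vals[-1] / vals[0]) / np.log(r[-1] / r[0]), 0.0, 4.0))
        best = None
        f_starts = np.linspace(0.1, 0.9, max(1, self.n_starts))
        for f0 in f_starts:
            sol = least_squares(
                resid, x0=[a0, f0, b0],
                bounds=([0.0, 0.0, 0.0], [np.inf, 1.0, 4.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        a, f, b = best.x
        # at b = 4 the Mie term coincides with the Rayleigh term and f is
        # unidentifiable; report the canonical pure-Rayleigh form
        if b > 4.0 - 1e-8:
            f = 1.0
        self.params_ = PowerLawParams(float(a), float(f), float(b), self.lambda0_nm)
        self.residual_ = float(2.0 * best.cost)
        return self

    def predict(self, grid: WavelengthGrid) -> Spectrum:
        return power_law_eval(self.params_, grid)


def power_law_fit(spec: Spectrum, lambda0_nm: float = 500.0) -> PowerLawParams:
    """Functional wrapper around :class:`MieRayleighModel`."""
    return MieRayleighModel(lambda0_nm=lambda0_nm).fit(spec).params_
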
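"""Wavelength grids, spectra, resampling, blending, and similarity metrics.

The universal currency of the package is a :class:`Spectrum`: a real-valued
curve sampled on a shared :class:`WavelengthGrid`.  Optical coefficients
(absorption ``mua`` and reduced scattering ``musp``) are in mm^-1; diffuse
reflectance is dimensionless in [0, 1].  The default working grid is
370-950 nm at 1 nm steps (582 samples, endpoints inclusive), the range over
which phantom recipes are designed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "DEFAULT_GRID",
    "resample",
    "sigmoid_blend",
    "mean_abs_error",
    "spectral_angle",
    "read_spectrum",
    "write_spectrum",
    "read_spectra_table",
    "write_spectra_table",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, endpoint-inclusive wavelength grid in nanometres."""

    start_nm: float = 370.0
    stop_nm: float = 950.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValueError("grid start must be below stop")
        if self.step_nm <= 0:
            raise ValueError("grid step must be positive")
        span = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(span - round(span)) > 1e-9:
            raise ValueError("grid span must be an integer number of steps")

    def __len__(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        n = len(self)
        return self.start_nm + self.step_nm * np.arange(n)

    def index_of(self, lambda_nm: float) -> int:
        """Index of the nearest grid sample; errors outside the grid."""
        if lambda_nm < self.start_nm - 1e-9 or lambda_nm > self.stop_nm + 1e-9:
            raise ValueError(f"{lambda_nm} nm lies outside the grid")
        return int(round((lambda_nm - self.start_nm) / self.step_nm))


DEFAULT_GRID = WavelengthGrid()


@dataclass
class Spectrum:
    """A sampled spectrum on a :class:`WavelengthGrid`.

    Parameters
    ----------
    grid : WavelengthGrid
    values : array-like, same length as the grid; NaNs are rejected.
    units : free-text unit declaration ("mm^-1", "1" for reflectance, ...).
    """

    grid: WavelengthGrid
    values: np.ndarray
    units: str = "mm^-1"
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.grid):
            raise ValueError(
                f"values length {self.values.size} does not match grid length {len(self.grid)}"
            )
        if np.any(np.isnan(self.values)):
            raise ValueError("spectrum contains NaN")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def at(self, lambda_nm: float) -> float:
        return float(self.values[self.grid.index_of(lambda_nm)])

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Spectrum":
        return Spectrum(self.grid, values, units=self.units,
                        name=self.name if name is None else name)

    def __add__(self, other: "Spectrum") -> "Spectrum":
        _require_same_grid(self, other)
        return self.with_values(self.values + other.values)

    def __mul__(self, c: float) -> "Spectrum":
        return self.with_values(self.values * float(c))

    __rmul__ = __mul__


def _require_same_grid(a: Spectrum, b: Spectrum) -> None:
    if a.grid != b.grid:
        raise ValueError("spectra are on different wavelength grids")


def resample(spec: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linear interpolation of ``spec`` onto ``grid``.

    Extrapolation is refused: the source range must cover the target grid.
    """
    src = spec.wavelengths
    tgt = grid.wavelengths
    if tgt[0] < src[0] - 1e-9 or tgt[-1] > src[-1] + 1e-9:
        raise ValueError(
            f"target grid [{tgt[0]}, {tgt[-1]}] nm exceeds source range "
            f"[{src[0]}, {src[-1]}] nm; extrapolation is not performed"
        )
    return Spectrum(grid, np.interp(tgt, src, spec.values), units=spec.units, name=spec.name)


def sigmoid_blend(thin: Spectrum, thick: Spectrum, lo_nm: float = 560.0,
                  hi_nm: float = 620.0, scale_nm: float = 10.0) -> Spectrum:
    """Blend two spectra with a logistic ramp over [lo_nm, hi_nm].

    The result equals ``thin`` exactly at and below ``lo_nm`` and ``thick``
    exactly at and above ``hi_nm``.  In between, the weight on ``thick`` is a
    logistic ramp centred at (lo+hi)/2, renormalized so it is exactly 0 at
    ``lo_nm``, 1 at ``hi_nm`` and 1/2 at the centre.  This is the composite
    used to join absorption measured on a thin sample (dominating the short
    wavelengths) with that of a thick sample (long wavelengths).
    """
    _require_same_grid(thin, thick)
    if not lo_nm < hi_nm:
        raise ValueError("lo_nm must be below hi_nm")
    lam = thin.wavelengths
    center = 0.5 * (lo_nm + hi_nm)

    def logistic(x):
        return 1.0 / (1.0 + np.exp(-(x - center) / scale_nm))

    w_lo, w_hi = logistic(lo_nm), logistic(hi_nm)
    w = (logistic(lam) - w_lo) / (w_hi - w_lo)
    w = np.clip(w, 0.0, 1.0)
    w[lam <= lo_nm] = 0.0
    w[lam >= hi_nm] = 1.0
    return thin.with_values((1.0 - w) * thin.values + w * thick.values)


def mean_abs_error(a: Spectrum, b: Spectrum, log10_transform: bool = False) -> float:
    """Mean absolute difference between two spectra on a shared grid.

    With ``log10_transform`` both spectra are log10-transformed first; this is
    the convention for absorption coefficients, which span several orders of
    magnitude.  Reflectance and scattering comparisons stay on a linear scale.
    """
    _require_same_grid(a, b)
    x, y = a.values, b.values
    if log10_transform:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log10 MAE requires strictly positive spectra")
        x, y = np.log10(x), np.log10(y)
    return float(np.mean(np.abs(x - y)))


def spectral_angle(a: Spectrum, b: Spectrum) -> float:
    """Spectral angle mapper (SAM) in degrees.

    The angle between the two spectra viewed as vectors:
    ``acos( a.b / (||a|| ||b||) )``.  Scale-invariant; 0 deg for identical
    shapes, approaching 90 deg for dissimilar non-negative spectra.
    """
    _require_same_grid(a, b)
    na, nb = np.linalg.norm(a.values), np.linalg.norm(b.values)
    if na == 0 or nb == 0:
        raise ValueError("SAM undefined for a zero spectrum")
    c = float(np.dot(a.values, b.values) / (na * nb))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# CSV dialect: header `wavelength_nm,value` (single) or
# `wavelength_nm,<name1>,<name2>,...` (multi-column table).

def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    df = pd.DataFrame({"wavelength_nm": spec.wavelengths, "value": spec.values})
    df.to_csv(path, index=False)


def read_spectrum(path: str | Path, units: str = "mm^-1") -> Spectrum:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["wavelength_nm", "value"]:
        raise ValueError(f"{path}: expected header 'wavelength_nm,value'")
    grid = _grid_from_wavelengths(df["wavelength_nm"].to_numpy(float))
    return Spectrum(grid, df["value"].to_numpy(float), units=units)


def write_spectra_table(grid: WavelengthGrid, columns: dict[str, np.ndarray],
                        path: str | Path) -> None:
    df = pd.DataFrame({"wavelength_nm": grid.wavelengths, **columns})
    df.to_csv(path, index=False)


def read_spectra_table(path: str | Path) -> tuple[WavelengthGrid, dict[str, np.ndarray]]:
    df = pd.read_csv(path, comment="#")
    if df.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be 'wavelength_nm'")
    grid = _grid_from_wavelengths(df["wavelength_nm"].to_numpy(float))
    cols = {c: df[c].to_numpy(float) for c in df.columns[1:]}
    return grid, cols


def _grid_from_wavelengths(lam: np.ndarray) -> WavelengthGrid:
    if lam.size < 2:
        raise ValueError("need at least two wavelength samples")
    steps = np.diff(lam)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], atol=1e-6):
        raise ValueError("wavelength column must be uniform and increasing")
    return WavelengthGrid(float(lam[0]), float(lam[-1]), float(steps[0]))
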
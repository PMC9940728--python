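"""Computational skin absorption model and its three-band inversion.

The skin absorption coefficient is a linear mixture of chromophores:

    mua(lambda) = StO2*B*H*mua_HbO2 + (1-StO2)*B*H*mua_Hb
                  + W*mua_water + F*mua_fat + M*mua_mel

with StO2 the hemoglobin oxygen saturation, B/W/F/M the blood, water, fat
and melanosome volume fractions, and H the hemoglobin concentration within
blood (mol/L; hemoglobin spectra are per-molar).  Given the band-averaged
absorption in three bands (defaults 540-560, 625-645, 820-840 nm) and fixed
W and F, the model is linear in (u1, u2, u3) = (StO2*B*H, (1-StO2)*B*H, M)
and inverts by a 3x3 solve; StO2 = u1/(u1+u2) is then independent of H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .fitting import BandSet, STO2_BANDS
from .spectra import Spectrum, WavelengthGrid

__all__ = [
    "SKIN_GRID",
    "ChromophoreSet",
    "SkinParams",
    "InversionResult",
    "synthetic_chromophores",
    "skin_mua",
    "total_hemoglobin",
    "band_mean",
    "invert_sto2",
    "SkinBandInverter",
    "percent_error",
    "mean_abs_percent_error",
]

#: the skin model is produced between 470 and 950 nm
SKIN_GRID = WavelengthGrid(470.0, 950.0, 1.0)


@dataclass
class ChromophoreSet:
    """Reference absorption spectra of the skin chromophores.

    Hemoglobin spectra are absorption per unit molar concentration
    (mm^-1 per mol/L); water, fat and melanosome spectra are the absorption
    of the pure substance (mm^-1), scaled by volume fractions in the model.
    """

    mua_hbo2: Spectrum
    mua_hb: Spectrum
    mua_water: Spectrum
    mua_fat: Spectrum
    mua_mel: Spectrum

    def __post_init__(self) -> None:
        specs = self.as_dict().values()
        grids = {s.grid for s in specs}
        if len(grids) != 1:
            raise ValueError("chromophore spectra must share one grid")
        for name, s in self.as_dict().items():
            if np.any(s.values < 0):
                raise ValueError(f"negative absorption in {name}")

    @property
    def grid(self) -> WavelengthGrid:
        return self.mua_hbo2.grid

    def as_dict(self) -> dict[str, Spectrum]:
        return {"hbo2": self.mua_hbo2, "hb": self.mua_hb,
                "water": self.mua_water, "fat": self.mua_fat,
                "mel": self.mua_mel}


def synthetic_chromophores(grid: WavelengthGrid = SKIN_GRID) -> ChromophoreSet:
    """Synthetic analytic chromophore spectra (not literature tabulations).

    Smooth Gaussian / power-law stand-ins whose shapes and magnitudes are
    scaled to the physiological ballpark: oxyhemoglobin with the 542/577 nm
    double peak and a gentle NIR rise, deoxyhemoglobin with the single
    555 nm peak and a 760 nm shoulder, water rising into the NIR, a fat
    feature near 930 nm, and melanin as a decreasing power law.  Hemoglobin
    amplitudes are per-molar (mm^-1 M^-1) so that B*H ~ 110 uM gives
    mua ~ 1 mm^-1 at the green peak.  The inversion machinery is exact for
    *any* nonsingular chromophore set, so nothing downstream depends on
    these being the true literature curves.
    """
    lam = grid.wavelengths

    def g(center, sigma):
        return np.exp(-0.5 * ((lam - center) / sigma) ** 2)

    # NIR magnitudes follow the pulse-oximetry geometry: deoxyhemoglobin
    # dominates in the red (strong ~630-760 nm tail), oxyhemoglobin rises
    # past the ~800 nm isosbestic crossover
    hbo2 = 12000.0 * (g(542, 11) + 0.95 * g(577, 10)) + 6000.0 * g(420, 25) \
        + 120.0 + 100.0 * np.clip((lam - 650) / 180.0, 0, None)
    hb = 12000.0 * g(556, 16) + 7000.0 * g(430, 25) + 180.0 * g(758, 20) \
        + 1400.0 * np.exp(-np.clip(lam - 600.0, 0, None) / 110.0)
    water = 5e-5 + 0.004 * g(740, 30) + 0.040 * g(970, 35) + 0.0015 * g(836, 25)
    fat = 2e-4 + 0.10 * g(930, 15) + 0.006 * g(760, 20)
    mel = 51.9 * (lam / 500.0) ** -3.33
    mk = lambda v, name: Spectrum(grid, v, units="mm^-1", name=name)
    return ChromophoreSet(mk(hbo2, "hbo2"), mk(hb, "hb"), mk(water, "water"),
                          mk(fat, "fat"), mk(mel, "mel"))


@dataclass
class SkinParams:
    """Parameters of the skin absorption model.

    Defaults follow the pale-skin oxygenation-phantom design: water fraction
    0.5, fat fraction 0.02, melanosome fraction 0.0255% and blood hemoglobin
    concentration 2.3 mmol/L; B = 4.78% gives a total hemoglobin
    concentration of ~110 uM.
    """

    StO2: float = 0.8
    B: float = 0.0478
    W: float = 0.5
    F: float = 0.02
    M: float = 2.55e-4
    H: float = 2.3e-3  # mol/L

    def __post_init__(self) -> None:
        for name in ("StO2", "B", "W", "F", "M"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.H < 0:
            raise ValueError("H must be nonnegative")
        if self.B + self.W + self.F + self.M > 1.0:
            import warnings
            warnings.warn("volume fractions sum above 1", stacklevel=2)


@dataclass
class InversionResult:
    StO2_hat: float
    B_hat: float
    M_hat: float
    band_mua: np.ndarray
    residual: float
    clamped: bool = False


def skin_mua(params: SkinParams, chromo: ChromophoreSet) -> Spectrum:
    """Evaluate the skin absorption model on the chromophore grid."""
    p, c = params, chromo
    vals = (p.StO2 * p.B * p.H * c.mua_hbo2.values
            + (1.0 - p.StO2) * p.B * p.H * c.mua_hb.values
            + p.W * c.mua_water.values
            + p.F * c.mua_fat.values
            + p.M * c.mua_mel.values)
    return Spectrum(c.grid, vals, units="mm^-1", name="skin_mua")


def total_hemoglobin(params: SkinParams) -> float:
    """Total tissue hemoglobin concentration B*H in mol/L."""
    return params.B * params.H


def band_mean(spec: Spectrum, band: tuple[float, float]) -> float:
    """Arithmetic mean of the samples with wavelength in [lo, hi] inclusive."""
    lo, hi = band
    lam = spec.wavelengths
    if lo < lam[0] - 1e-9 or hi > lam[-1] + 1e-9:
        raise ValueError(f"band ({lo}, {hi}) lies outside the spectrum grid")
    m = (lam >= lo - 1e-9) & (lam <= hi + 1e-9)
    if not np.any(m):
        raise ValueError(f"band ({lo}, {hi}) contains no grid samples")
    return float(np.mean(spec.values[m]))


class SkinBandInverter(BaseEstimator):
    """Recover (StO2, B, M) from band-averaged absorption coefficients.

    Subtracts the fixed water and fat contributions from each band mean,
    then solves the 3x3 linear system in (StO2*B*H, (1-StO2)*B*H, M) with
    band-averaged chromophore coefficients.  Negative components are clamped
    to zero and flagged.

    Attributes
    ----------
    StO2_, B_, M_ : recovered parameters.
    result_ : full InversionResult.
    """

    def __init__(self, chromo: ChromophoreSet, bands: BandSet = STO2_BANDS,
                 W: float = 0.5, F: float = 0.02, H: float = 2.3e-3,
                 cond_limit: float = 1e12):
        self.chromo = chromo
        self.bands = bands
        self.W = W
        self.F = F
        self.H = H
        self.cond_limit = cond_limit

    def fit(self, band_mua, y=None) -> "SkinBandInverter":
        """``band_mua``: a Spectrum (band means are taken) or three reals."""
        if isinstance(band_mua, Spectrum):
            vals = np.array([band_mean(band_mua, b) for b in self.bands.bands])
        else:
            vals = np.asarray(band_mua, dtype=float)
        if len(self.bands.bands) != 3 or vals.size != 3:
            raise ValueError("the inversion needs exactly three bands")

        c = self.chromo
        M_coef = np.array([
            [band_mean(c.mua_hbo2, b), band_mean(c.mua_hb, b), band_mean(c.mua_mel, b)]
            for b in self.bands.bands
        ])
        rhs = vals - np.array([
            self.W * band_mean(c.mua_water, b) + self.F * band_mean(c.mua_fat, b)
            for b in self.bands.bands
        ])
        cond = float(np.linalg.cond(M_coef))
        if cond > self.cond_limit:
            raise np.linalg.LinAlgError(
                f"band chromophore system is singular (cond={cond:.3g})")
        u = np.linalg.solve(M_coef, rhs)
        clamped = bool(np.any(u < 0))
        u_clamped = np.maximum(u, 0.0)
        tot = u_clamped[0] + u_clamped[1]
        # 1e-12 mol/L is far below any physiological hemoglobin signal and
        # absorbs round-off from the water/fat subtraction
        if tot <= 1e-12:
            raise ValueError("total hemoglobin signal is non-positive; StO2 undefined")
        self.StO2_ = float(u_clamped[0] / tot)
        self.B_ = float(tot / self.H)
        self.M_ = float(u_clamped[2])
        self.result_ = InversionResult(
            StO2_hat=self.StO2_, B_hat=self.B_, M_hat=self.M_,
            band_mua=vals,
            residual=float(np.linalg.norm(M_coef @ u_clamped - rhs)),
            clamped=clamped,
        )
        return self


def invert_sto2(band_mua, bands: BandSet = STO2_BANDS,
                chromo: ChromophoreSet | None = None, W: float = 0.5,
                F: float = 0.02, H: float = 2.3e-3) -> InversionResult:
    """Functional wrapper around :class:`SkinBandInverter`."""
    if chromo is None:
        chromo = synthetic_chromophores()
    return SkinBandInverter(chromo, bands, W=W, F=F, H=H).fit(band_mua).result_


def percent_error(expected: float, measured: float) -> float:
    """Signed percent error (measured - expected) / expected * 100."""
    if expected == 0:
        raise ValueError("percent error undefined for expected == 0")
    return (measured - expected) / expected * 100.0


def mean_abs_percent_error(errors) -> float:
    """Mean of the absolute values of signed percent errors."""
    e = np.asarray(list(errors), dtype=float)
    if e.size == 0:
        raise ValueError("no errors given")
    return float(np.mean(np.abs(e)))
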
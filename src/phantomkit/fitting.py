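"""Recipe design against target optical-property spectra.

Three nonnegative least-squares problems turn a target tissue's absorption
and reduced-scattering spectra into pigment concentrations:

1. *Absorption step* — NNLS over the non-white pigments with a relative
   weight w(lambda) = max(mua) / mua(lambda) applied inside the residual,
   so the 2-3 orders of magnitude between the blue peak and the NIR floor
   are treated equally.
2. *Scattering step* — NNLS over the white pigments against the target
   reduced scattering minus the scattering already contributed by the
   absorbers found in step 1 (negative residual clamped to zero).
3. *Band fit* — a single joint NNLS over all pigments, with strong per-band
   weights wa(lambda), ws(lambda) multiplying the squared absorption and
   scattering residuals inside chosen wavelength bands and weight 1 outside.

All solvers are Lawson-Hanson NNLS (scipy), so returned concentrations are
exactly nonnegative and KKT-optimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .pigments import PigmentBasis, Recipe, mix_properties
from .spectra import Spectrum, mean_abs_error, spectral_angle

__all__ = [
    "TissueTarget",
    "BandSet",
    "FitResult",
    "absorption_weights",
    "fit_absorption",
    "fit_scattering",
    "fit_broadband",
    "fit_bands",
    "BroadbandRecipeFitter",
    "BandRecipeFitter",
]

#: floor applied to target absorption before forming relative weights
WEIGHT_FLOOR = 1e-6
#: absorption floor used when computing log10 MAE diagnostics
LOG_FLOOR = 1e-6


@dataclass
class TissueTarget:
    """Target absorption and reduced-scattering spectra (mm^-1)."""

    mua: Spectrum
    musp: Spectrum
    label: str = ""

    def __post_init__(self) -> None:
        if self.mua.grid != self.musp.grid:
            raise ValueError("mua and musp grids differ")
        if np.any(self.mua.values < 0) or np.any(self.musp.values < 0):
            raise ValueError("target optical properties must be nonnegative")


@dataclass
class BandSet:
    """Non-overlapping inclusive wavelength bands with per-band weights.

    ``abs_weights``/``scat_weights`` are per-band multipliers on the default
    in-band weight; both default to 1 for every band.
    """

    bands: list[tuple[float, float]]
    abs_weights: list[float] | None = None
    scat_weights: list[float] | None = None

    def __post_init__(self) -> None:
        ordered = sorted(self.bands)
        for (lo, hi) in ordered:
            if lo > hi:
                raise ValueError(f"band ({lo}, {hi}) has lo > hi")
        for (_, hi), (lo2, _) in zip(ordered, ordered[1:]):
            if lo2 <= hi:
                raise ValueError("bands overlap")
        n = len(self.bands)
        if self.abs_weights is None:
            self.abs_weights = [1.0] * n
        if self.scat_weights is None:
            self.scat_weights = [1.0] * n
        if len(self.abs_weights) != n or len(self.scat_weights) != n:
            raise ValueError("per-band weight lists must match the band count")
        if any(w <= 0 for w in self.abs_weights + self.scat_weights):
            raise ValueError("band weights must be positive")

    def mask(self, lam: np.ndarray, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return (lam >= lo - 1e-9) & (lam <= hi + 1e-9)


#: default muscle-phantom design bands (blue, green, red, NIR)
MUSCLE_BANDS = BandSet([(385.0, 405.0), (530.0, 570.0), (615.0, 635.0), (825.0, 865.0)])
#: bands used for the oxygen-saturation phantoms and their inversion
STO2_BANDS = BandSet([(540.0, 560.0), (625.0, 645.0), (820.0, 840.0)])


@dataclass
class FitResult:
    """A fitted recipe plus residual diagnostics.

    ``metrics`` maps property name ("absorption"/"scattering") to
    ``(MAE, SAM_degrees)``; absorption MAE is log10-scale with values floored
    at 1e-6 mm^-1, scattering MAE is linear.
    """

    recipe: Recipe
    fitted_mua: Spectrum
    fitted_musp: Spectrum
    residual_abs: float
    residual_scat: float
    metrics: dict[str, tuple[float, float]]
    diagnostics: dict = field(default_factory=dict)


def absorption_weights(mua_target: Spectrum, floor: float = WEIGHT_FLOOR) -> Spectrum:
    """Relative weights w(lambda) = max(mua) / mua(lambda).

    Values below ``floor`` are clamped before dividing so the weights stay
    finite; the minimum weight is 1, attained at the absorption maximum.
    """
    v = mua_target.values
    if np.all(v <= 0):
        raise ValueError("cannot form weights for an all-zero absorption target")
    clamped = np.maximum(v, floor)
    return mua_target.with_values(np.max(clamped) / clamped, name="weights")


def _metrics(target: TissueTarget, mua: Spectrum, musp: Spectrum) -> dict:
    la = Spectrum(mua.grid, np.maximum(mua.values, LOG_FLOOR))
    lt = Spectrum(mua.grid, np.maximum(target.mua.values, LOG_FLOOR))
    out = {}
    try:
        out["absorption"] = (mean_abs_error(la, lt, log10_transform=True),
                             spectral_angle(mua, target.mua))
    except ValueError:
        out["absorption"] = (float("nan"), float("nan"))
    try:
        out["scattering"] = (mean_abs_error(musp, target.musp),
                             spectral_angle(musp, target.musp))
    except ValueError:
        out["scattering"] = (float("nan"), float("nan"))
    return out


def _check_condition(A: np.ndarray, diagnostics: dict) -> None:
    if A.size and min(A.shape) > 0:
        cond = float(np.linalg.cond(A))
        diagnostics["condition_number"] = cond
        diagnostics["collinearity_flag"] = bool(cond > 1e8)


def fit_absorption(basis: PigmentBasis, target: TissueTarget,
                   weighting: str = "relative") -> Recipe:
    """NNLS absorber concentrations matching the target absorption.

    Only non-white categories receive concentrations.  ``weighting`` is
    "relative" (the max/value rule) or "none" (uniform; required when the
    target absorption is identically zero).
    """
    nonwhite = basis.by_category("yellow", "magenta", "miscellaneous", "black")
    if not nonwhite.records:
        raise ValueError("basis contains no non-white pigments")
    b = target.mua.values
    if weighting == "relative":
        w = absorption_weights(target.mua).values
    elif weighting == "none":
        w = np.ones_like(b)
    else:
        raise ValueError(f"unknown weighting mode {weighting!r}")
    A = nonwhite.abs_matrix() * w[:, None]
    x, _ = nnls(A, w * b)
    return Recipe(dict(zip(nonwhite.names, map(float, x))), basis_id="nonwhite")


def fit_scattering(basis: PigmentBasis, target: TissueTarget,
                   absorber_recipe: Recipe | None = None) -> Recipe:
    """NNLS white-pigment concentrations against the residual scattering.

    The scattering already contributed by ``absorber_recipe`` is subtracted
    from the target first; a negative residual is clamped to zero.
    """
    whites = basis.by_category("white")
    resid = target.musp.values.copy()
    if absorber_recipe is not None and absorber_recipe.concentrations:
        _, scat_from_abs = mix_properties(basis, absorber_recipe)
        resid = resid - scat_from_abs.values
    resid = np.maximum(resid, 0.0)
    if not whites.records:
        return Recipe({}, basis_id="white")
    z, _ = nnls(whites.scat_matrix(), resid)
    return Recipe(dict(zip(whites.names, map(float, z))), basis_id="white")


class BroadbandRecipeFitter(BaseEstimator):
    """Two-step broadband recipe design (absorption then scattering NNLS).

    Parameters
    ----------
    basis : PigmentBasis to draw pigments from.
    weighting : "relative" (default) or "none", passed to the absorption step.

    Attributes
    ----------
    recipe_ : merged Recipe over absorbers and whites.
    result_ : full FitResult with fitted spectra and diagnostics.
    """

    def __init__(self, basis: PigmentBasis, weighting: str = "relative"):
        self.basis = basis
        self.weighting = weighting

    def fit(self, target: TissueTarget, y=None) -> "BroadbandRecipeFitter":
        mode = self.weighting
        if mode == "relative" and np.all(target.mua.values <= 0):
            mode = "none"
        absorbers = fit_absorption(self.basis, target, weighting=mode)
        whites = fit_scattering(self.basis, target, absorbers)
        recipe = absorbers.merged(whites)
        recipe.basis_id = "broadband"
        mua, musp = mix_properties(self.basis, recipe)
        diagnostics: dict = {"weighting": mode}
        _check_condition(self.basis.abs_matrix(), diagnostics)
        self.recipe_ = recipe
        self.result_ = FitResult(
            recipe=recipe, fitted_mua=mua, fitted_musp=musp,
            residual_abs=float(np.sum((mua.values - target.mua.values) ** 2)),
            residual_scat=float(np.sum((musp.values - target.musp.values) ** 2)),
            metrics=_metrics(target, mua, musp),
            diagnostics=diagnostics,
        )
        return self

    def predict(self) -> tuple[Spectrum, Spectrum]:
        return self.result_.fitted_mua, self.result_.fitted_musp


class BandRecipeFitter(BaseEstimator):
    """Joint NNLS over all pigments with strong in-band weights.

    In-band weight for band k of property p:
    ``K * band_weight_k / max(|target_p| within band k)`` (max-magnitude
    normalization, floored), weight 1 outside all bands.  ``K`` defaults to
    1000.  An empty band set falls back to uniform weights (a plain joint
    NNLS over both properties).

    Attributes
    ----------
    recipe_, result_ : as for :class:`BroadbandRecipeFitter`.
    """

    def __init__(self, basis: PigmentBasis, bands: BandSet | None = None,
                 K: float = 1000.0):
        self.basis = basis
        self.bands = bands
        self.K = K

    def _weights(self, target: TissueTarget) -> tuple[np.ndarray, np.ndarray]:
        lam = target.mua.wavelengths
        wa = np.ones(lam.size)
        ws = np.ones(lam.size)
        if self.bands is None or not self.bands.bands:
            return wa, ws
        for k, band in enumerate(self.bands.bands):
            m = self.bands.mask(lam, band)
            if not np.any(m):
                raise ValueError(f"band {band} lies outside the target grid")
            scale_a = max(float(np.max(target.mua.values[m])), WEIGHT_FLOOR)
            scale_s = max(float(np.max(target.musp.values[m])), WEIGHT_FLOOR)
            wa[m] = self.K * self.bands.abs_weights[k] / scale_a
            ws[m] = self.K * self.bands.scat_weights[k] / scale_s
        return wa, ws

    def fit(self, target: TissueTarget, y=None) -> "BandRecipeFitter":
        wa, ws = self._weights(target)
        # Eq: minimize sum wa*(mua - A q)^2 + ws*(musp - S q)^2
        # -> rows scaled by sqrt of the weights
        ra, rs = np.sqrt(wa), np.sqrt(ws)
        A = np.vstack([self.basis.abs_matrix() * ra[:, None],
                       self.basis.scat_matrix() * rs[:, None]])
        b = np.concatenate([target.mua.values * ra, target.musp.values * rs])
        q, _ = nnls(A, b, maxiter=50 * A.shape[1])
        recipe = Recipe(dict(zip(self.basis.names, map(float, q))), basis_id="bands")
        mua, musp = mix_properties(self.basis, recipe)
        diagnostics: dict = {"wa": wa, "ws": ws}
        _check_condition(A, diagnostics)
        self.recipe_ = recipe
        self.result_ = FitResult(
            recipe=recipe, fitted_mua=mua, fitted_musp=musp,
            residual_abs=float(np.sum(wa * (mua.values - target.mua.values) ** 2)),
            residual_scat=float(np.sum(ws * (musp.values - target.musp.values) ** 2)),
            metrics=_metrics(target, mua, musp),
            diagnostics=diagnostics,
        )
        return self

    def predict(self) -> tuple[Spectrum, Spectrum]:
        return self.result_.fitted_mua, self.result_.fitted_musp


def fit_broadband(basis: PigmentBasis, target: TissueTarget,
                  weighting: str = "relative") -> FitResult:
    return BroadbandRecipeFitter(basis, weighting=weighting).fit(target).result_


def fit_bands(basis: PigmentBasis, target: TissueTarget,
              bands: BandSet | None, K: float = 1000.0) -> FitResult:
    return BandRecipeFitter(basis, bands=bands, K=K).fit(target).result_
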
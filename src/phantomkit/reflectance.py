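"""Reflectance-matched recipe design.

Finds the nonnegative pigment concentrations q whose white-Monte-Carlo
predicted diffuse reflectance best matches a measured target spectrum:

    argmin_q  sum_lambda [ R(lambda) - wMC(Cabs(lambda) q, Cscat(lambda) q, n) ]^2

The forward model reuses one fixed PathRecord (common random numbers), so
the objective is deterministic and smooth in q.  The inner loop evaluates
the wMC through a monotone Rd(alpha) interpolant built once from the record;
the exact per-event summation is available as a cross-check.  Optimization
is bound-constrained trust-region nonlinear least squares with lower bounds
at zero and forward-difference Jacobians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .fitting import FitResult, TissueTarget, fit_broadband
from .montecarlo import PathRecord, RdInterpolator, TransportConfig, reflectance_spectrum
from .pigments import PigmentBasis, Recipe, mix_properties
from .scattering import PowerLawParams, power_law_eval
from .spectra import Spectrum, mean_abs_error, spectral_angle

__all__ = ["ReflectanceTarget", "ReflectanceRecipeFitter", "fit_reflectance"]


@dataclass
class ReflectanceTarget:
    """A target diffuse reflectance spectrum, values strictly in (0, 1)."""

    reflectance: Spectrum
    label: str = ""

    def __post_init__(self) -> None:
        v = self.reflectance.values
        if np.any(v <= 0) or np.any(v >= 1):
            raise ValueError("reflectance values must lie strictly in (0, 1)")


class ReflectanceRecipeFitter(BaseEstimator):
    """Nonlinear nonnegative least squares against a reflectance target.

    Parameters
    ----------
    basis : pigment basis supplying Cabs, Cscat.
    record : PathRecord from :func:`run_reference`, built with the medium's
        refractive index.
    subsample_nm : wavelength stride of the inner optimization grid (the
        final report is on the full grid); default 5 nm.
    musp_prior : Mie-Rayleigh parameters of the scattering assumed when
        inverting the target reflectance for the initial guess.
    diff_step, ftol, max_iter : optimizer controls (forward differences with
        relative step 1e-3; stop on relative objective decrease < 1e-8 or
        200 iterations).
    musp_reference : optional ``(lambda_nm, musp_mm1)`` anchor.  Semi-infinite
        diffuse reflectance depends on the optical properties only through
        mua/musp, so scaling a whole recipe leaves the objective exactly
        unchanged: the reflectance alone cannot set the concentration scale.
        When an anchor is given, the converged solution is rescaled along
        this null direction so the fitted reduced scattering equals
        ``musp_mm1`` at ``lambda_nm`` (the objective is unaffected).  Without
        an anchor the scale is whatever the optimizer's start implied.

    Attributes
    ----------
    recipe_ : fitted Recipe.
    result_ : FitResult (fitted reflectance stored in diagnostics).
    predicted_ : predicted reflectance Spectrum on the full grid.
    converged_ : False flags a fit stopped at the iteration cap.
    """

    def __init__(self, basis: PigmentBasis, record: PathRecord,
                 subsample_nm: float = 5.0,
                 musp_prior: PowerLawParams = PowerLawParams(1.5, 0.2, 1.0),
                 diff_step: float = 1e-3, ftol: float = 1e-8,
                 max_iter: int = 200, interpolator_nodes: int = 2000,
                 musp_reference: tuple[float, float] | None = None,
                 polish: bool = True):
        self.basis = basis
        self.record = record
        self.subsample_nm = subsample_nm
        self.musp_prior = musp_prior
        self.diff_step = diff_step
        self.ftol = ftol
        self.max_iter = max_iter
        self.interpolator_nodes = interpolator_nodes
        self.musp_reference = musp_reference
        self.polish = polish

    # -- forward model -----------------------------------------------------
    def _forward(self, q: np.ndarray, A: np.ndarray, S: np.ndarray,
                 interp: RdInterpolator) -> np.ndarray:
        mua = A @ q
        musp = np.maximum(S @ q, 1e-12)
        return interp.spectrum(mua, musp, self.record.config.g)

    def _initial_guess(self, target: ReflectanceTarget,
                       interp: RdInterpolator) -> np.ndarray:
        """Broadband property fit against a wMC inversion of the target.

        Assumes the prior scattering power law, inverts Rd(lambda) for the
        absorption that reproduces the target through the same record, and
        runs the two-step property fit on the implied (mua, musp) pair.
        Falls back to uniform small concentrations if the inversion is
        degenerate.
        """
        grid = target.reflectance.grid
        musp = power_law_eval(self.musp_prior, grid)
        g = self.record.config.g
        try:
            alphas = interp.invert(target.reflectance.values)
            mua = alphas * musp.values / (1.0 - g)
            prop_target = TissueTarget(Spectrum(grid, mua), musp, label="R-inversion")
            res = fit_broadband(self.basis, prop_target)
            q0 = res.recipe.vector(self.basis)
            if np.all(q0 <= 0) or not np.all(np.isfinite(q0)):
                raise ValueError
            return np.maximum(q0, 1e-6)
        except Exception:
            return np.full(len(self.basis.names), 1e-3)

    def fit(self, target: ReflectanceTarget, y=None) -> "ReflectanceRecipeFitter":
        grid = target.reflectance.grid
        lam = grid.wavelengths
        stride = max(1, int(round(self.subsample_nm / grid.step_nm)))
        idx = np.arange(0, lam.size, stride)
        if idx[-1] != lam.size - 1:
            idx = np.append(idx, lam.size - 1)

        A_full = self.basis.abs_matrix()
        S_full = self.basis.scat_matrix()
        A, S = A_full[idx], S_full[idx]
        r_target = target.reflectance.values[idx]
        interp = RdInterpolator(self.record, n_nodes=self.interpolator_nodes)

        cats = [r.category for r in self.basis.records]
        if all(c == "white" for c in cats) or all(c in ("black",) for c in cats):
            warn = "basis contains only whites or only blacks; fit may be unidentifiable"
        else:
            warn = None

        q0 = self._initial_guess(target, interp)

        def resid(q):
            return self._forward(q, A, S, interp) - r_target

        sol = least_squares(
            resid, x0=q0, bounds=(0.0, np.inf),
            diff_step=self.diff_step, ftol=self.ftol, xtol=1e-12, gtol=1e-12,
            max_nfev=self.max_iter * (len(q0) + 1),
        )
        nfev = sol.nfev
        if self.polish:
            # forward differences at the coarse step limit the attainable
            # residual (~sqrt(step) * curvature); a short second pass with a
            # fine step from the coarse solution removes that floor
            # lift exact zeros slightly off the bound: relative FD steps
            # degenerate at x = 0
            polish = least_squares(
                resid, x0=np.maximum(sol.x, 1e-8), bounds=(0.0, np.inf),
                diff_step=1e-6, ftol=self.ftol, xtol=1e-14, gtol=1e-14,
                max_nfev=50 * (len(q0) + 1),
            )
            nfev += polish.nfev
            if polish.cost < sol.cost:
                sol = polish
        q = np.maximum(sol.x, 0.0)
        if self.musp_reference is not None:
            lam_ref, musp_ref = self.musp_reference
            row = S_full[grid.index_of(lam_ref)]
            musp_fit = float(row @ q)
            if musp_fit > 0:
                q = q * (musp_ref / musp_fit)
        recipe = Recipe(dict(zip(self.basis.names, map(float, q))), basis_id="reflectance")
        mua, musp = mix_properties(self.basis, recipe)
        predicted = Spectrum(
            grid, interp.spectrum(mua.values, musp.values, self.record.config.g),
            units="1", name="Rd_fit")
        resid_full = predicted.values - target.reflectance.values
        metrics = {"reflectance": (mean_abs_error(predicted, target.reflectance),
                                   spectral_angle(predicted, target.reflectance))}
        diagnostics = {
            "objective": float(np.sum(resid_full ** 2)),
            "objective_subsampled": float(2.0 * sol.cost),
            "optimizer_status": int(sol.status),
            "n_evaluations": int(nfev),
            "predicted_reflectance": predicted,
        }
        if warn:
            diagnostics["warning"] = warn
        self.converged_ = bool(sol.status > 0)
        if not self.converged_:
            diagnostics["warning_convergence"] = "iteration cap reached"
        self.recipe_ = recipe
        self.predicted_ = predicted
        self.interpolator_ = interp
        self.result_ = FitResult(
            recipe=recipe, fitted_mua=mua, fitted_musp=musp,
            residual_abs=float("nan"), residual_scat=float("nan"),
            metrics=metrics, diagnostics=diagnostics,
        )
        return self

    def predict(self, recipe: Recipe | None = None) -> Spectrum:
        """Predicted reflectance for ``recipe`` (default: the fitted one)."""
        if recipe is None:
            return self.predicted_
        mua, musp = mix_properties(self.basis, recipe)
        vals = self.interpolator_.spectrum(mua.values, np.maximum(musp.values, 1e-12),
                                           self.record.config.g)
        return Spectrum(self.basis.grid, vals, units="1", name="Rd")


def fit_reflectance(basis: PigmentBasis, target: ReflectanceTarget,
                    rec: PathRecord, config: TransportConfig | None = None,
                    **kwargs) -> FitResult:
    """Functional wrapper around :class:`ReflectanceRecipeFitter`."""
    return ReflectanceRecipeFitter(basis, rec, **kwargs).fit(target).result_
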
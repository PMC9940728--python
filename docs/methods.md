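# Methods

This note records the models, parameter choices and numerical decisions
behind `phantomkit`, and what the synthetic data used by the test suite does
and does not establish about real measurements.

## Spectral conventions

All computation happens on a uniform, endpoint-inclusive wavelength grid;
the design default is 370–950 nm at 1 nm (581 samples). Absorption (μa) and
reduced scattering (μs′) are in mm⁻¹, diffuse reflectance is dimensionless
in [0, 1]. Inputs on other grids are linearly resampled; extrapolation is
refused rather than guessed. No unit autoconversion is performed (cm⁻¹
data must be converted by the caller) and no smoothing is applied to
measured spectra.

Two similarity metrics are used throughout. The mean absolute error (MAE)
is computed on a linear scale for scattering and reflectance and on a log10
scale for absorption, whose physiological dynamic range spans 2–3 decades;
for log-MAE diagnostics fitted absorption values are floored at 10⁻⁶ mm⁻¹
so exactly-zero fits remain comparable. The spectral angle mapper (SAM) is
the angle between two spectra viewed as vectors — a magnitude-blind shape
metric in [0°, 90°].

The composite-absorption helper blends a thin-sample spectrum (reliable at
the strongly absorbing blue end) with a thick-sample spectrum (reliable in
the NIR) using a logistic ramp over 560–620 nm, centred at 590 nm with a
10 nm scale. The ramp is renormalized so the output equals the thin input
*exactly* at and below 560 nm and the thick input exactly at and above
620 nm; a raw logistic would still carry ~5% of the other branch at the
region edges.

## Scattering model

Reduced scattering is modelled by the standard Mie–Rayleigh decomposition
μs′(λ) = a·[f·(λ/λ₀)⁻⁴ + (1−f)·(λ/λ₀)⁻ᵇ] with λ₀ = 500 nm, amplitude
a ≥ 0 (mm⁻¹ at λ₀), Rayleigh fraction f ∈ [0, 1] and Mie power b ∈ [0, 4].
Fitting uses bounded trust-region least squares with three Rayleigh-fraction
starts (the surface can trade f against b near the b → 4 degeneracy, where
the two terms coincide); when the fitted b reaches 4 the canonical
pure-Rayleigh form (f = 1) is reported. Tolerances are set to 10⁻¹⁴ so
noiseless round trips recover parameters to optimizer precision.

## Pigment bases and the synthetic generator

A pigment basis stores, per pigment, absorption and reduced-scattering
spectra normalized to mass fraction (mg pigment per g total phantom mass).
Mixing is assumed exactly concentration-linear — appropriate for
characterizations averaged over normalized replicate measurements — with no
saturation or inter-batch variability model.

The synthetic generator emulates a realistic 20-pigment characterization so
that every downstream fit is testable without laboratory data: six yellows
(single Gaussian peaks, centres stratified over 400–460 nm, broad
σ = 25–40 nm), six magentas (bimodal Gaussian pairs in 500–600 nm,
narrower σ = 12–20 nm, one variant with an extra ~625 nm peak), three
miscellaneous pigments (one ~500 nm peak, two with red/NIR absorption to
~750 nm), two blacks (one nearly flat, one monotone-decreasing ink-like
power law), and three whites with distinct Mie–Rayleigh scattering
parameters, two of which carry short-wavelength absorption edges (sigmoid
edges at 410 and 380 nm; the alumina-like white absorbs nowhere). Colored
and black pigments carry small power-law scattering, since real absorbers
scatter measurably. Amplitudes are drawn once per seed from ranges chosen
so that recipes of a few mg/g produce tissue-scale properties
(μa ~ 0.01–1 mm⁻¹, μs′ ~ 0.5–4 mm⁻¹). Stratified peak centres keep the
basis full-rank, so noiseless NNLS recoveries are identifiable — real
pigment sets may be more collinear, and the fitters flag condition numbers
above 10⁸.

What passing tests on this generator show: the optimizers recover exactly
representable targets to solver precision, orderings (multipigment versus
restricted bases) behave as theory requires, and all plumbing round-trips.
What they do not show: that any particular commercial pigment set spans a
given tissue's spectra — that depends on measured bases supplied by the
user.

## Property-fit optimizations

All linear fits use Lawson–Hanson NNLS (scipy), giving exactly nonnegative
concentrations satisfying the KKT conditions at termination.

*Broadband, step 1 (absorption)*: only non-white pigments participate. The
residual is weighted inside the square by w(λ) = max μa / μa(λ) so every
wavelength contributes comparably despite the decade-scale dynamic range;
target values below 10⁻⁶ mm⁻¹ are clamped before division. An identically
zero absorption target is fitted unweighted (yielding the zero recipe).

*Broadband, step 2 (scattering)*: whites are fitted to the target μs′ minus
the scattering contributed by the step-1 absorbers; negative residuals are
clamped to zero per wavelength (NNLS would otherwise chase unattainable
negative targets). Because step 1 sees the *total* target absorption, exact
recovery of a synthetic recipe is only possible when its whites contribute
no absorption — with UV-absorbing whites the same blue-end bias appears
that real broadband fits exhibit.

*Band fit*: a single joint NNLS over all pigments and both properties. The
squared residuals are multiplied by wa(λ), ws(λ): inside band k the weight
is K·(per-band multiplier)/max(target in band) — max-magnitude
normalization so bands of different magnitude compete fairly — with
K = 1000 by default and weight 1 outside all bands. An empty band set falls
back to uniform weights (a plain joint NNLS). Implementation scales design
rows by √w.

Default band sets: 385–405/530–570/615–635/825–865 nm for muscle-style
multiband phantoms, 540–560/625–645/820–840 nm for oxygenation phantoms.

## White Monte Carlo

Geometry is a semi-infinite homogeneous half-space (reflectance phantoms
are made optically thick), pencil beam at normal incidence, total-diffuse
detection over all exit angles (mirroring an integrating sphere; no
aperture model). Scattering is Henyey–Greenstein with g = 0.8 fixed for
all wavelengths — this is what makes a single reference run valid across
the spectrum via similarity scaling μs = μs′/(1−g). Defaults: n = 1.56
(epoxy) against air, 10⁵ photons for routine work (10⁶ for production
fits), pathlength cap 10⁵ mean free paths.

The reference walk is scattering-free-path sampling at unit μs with no
absorption. Specular reflection at entry ((n−1)²/(n+1)² at normal
incidence) reduces the launched weight and is excluded from the diffuse
tally. At each internal boundary hit the unpolarized Fresnel coefficient
splits the weight deterministically: the transmitted fraction is recorded
as an escape event (dimensionless pathlength, weight, photon index) and the
photon continues with the reflected fraction — lower variance than a
stochastic escape choice, at the cost of several escape events per photon.
Photons are terminated by an unbiased Russian roulette below weight 10⁻⁴
(survival probability 0.1) and by the pathlength cap, whose truncated
weight is tracked: its reweighted contribution is bounded by
trunc·exp(−μa·cap/μs), below 10⁻⁴ of the tally for μa ≥ 10⁻³ mm⁻¹ at the
default cap. Energy-conservation checks at μa = 0 use a raised cap
(4×10⁶) with fewer photons, since the return-time tail of a non-absorbing
half-space walk decays only as path⁻¹/².

Reflectance evaluation is the exact event sum Rd = N⁻¹·Σ wᵢ·exp(−α·pathᵢ),
α = μa/μs. Randomness comes from numba's seeded per-process generator;
identical (seed, config) gives bit-identical records. Standard errors are
estimated from per-photon aggregated contributions. An independent
absorbing-medium simulation (attenuation applied along each step) ships as
a cross-check oracle, as does the closed-form diffusion approximation for a
matched-boundary semi-infinite medium,
Rd = ½[exp(−μeff·z₀) + exp(−μeff·(z₀+2z_b))] with z₀ = 1/μt′,
z_b = 2D, μeff = √(3μa·μt′) — accurate to ~1% at transport albedo ≥ 0.99.

## Reflectance-matched recipes

The reflectance objective Σλ [R(λ) − wMC(μa(q), μs′(q), n)]² is minimized
by scipy's trust-region-reflective least squares with lower bounds 0,
forward-difference Jacobians (relative step 10⁻³), ftol 10⁻⁸ and an
iteration cap of 200 (a capped fit is flagged, not raised). The inner loop
runs on a 5 nm-subsampled grid; reports are on the full grid. The forward
model evaluates Rd through a monotone PCHIP interpolant of the exact
Rd(α) curve built once per record at 2000 log-spaced nodes over
α ∈ [10⁻⁹, 10³]; interpolation error is orders of magnitude below Monte
Carlo noise, and the fixed record (common random numbers) makes the
objective deterministic and smooth.

Initialization inverts the target reflectance through the same Rd(α) curve
under a prior scattering power law (a = 1.5 mm⁻¹, f = 0.2, b = 1 —
generic soft tissue), then runs the broadband property fit on the implied
(μa, μs′); if that degenerates the start falls back to uniform small
concentrations.

Because semi-infinite diffuse reflectance depends on the optical properties
only through μa/μs, scaling an entire recipe leaves the objective exactly
unchanged — the reflectance alone cannot set the concentration scale. The
fitter therefore accepts a reduced-scattering anchor (λ, μs′) and rescales
the converged solution along this exact null direction; without an anchor
the scale is whatever the initialization implied.

## Skin model and band inversion

μa(λ) = StO2·B·H·μaᴴᵇᴼ² + (1−StO2)·B·H·μaᴴᵇ + W·μaʷᵃᵗᵉʳ + F·μaᶠᵃᵗ +
M·μaᵐᵉˡ, evaluated on 470–950 nm. Hemoglobin spectra are per-molar
(mm⁻¹·M⁻¹); water, fat and melanosome spectra are pure-substance
absorption scaled by volume fractions. Defaults describe pale,
physiologically perfused skin: W = 0.5, F = 0.02, M = 2.55×10⁻⁴,
H = 2.3 mmol/L, and B = 4.78%, giving a total hemoglobin concentration
B·H ≈ 110 μM.

Inversion takes arithmetic band means (inclusive 1 nm samples) over
540–560, 625–645 and 820–840 nm, subtracts the fixed W and F terms, and
solves the 3×3 linear system for u = (StO2·B·H, (1−StO2)·B·H, M); then
StO2 = u₁/(u₁+u₂) (independent of H), B = (u₁+u₂)/H, M = u₃. Systems with
condition number above 10¹² are refused; negative components are clamped to
zero and flagged; a total hemoglobin signal below 10⁻¹² mol/L (round-off
from the subtraction) raises rather than returning an undefined StO2. The
inversion is algebraically exact for any nonsingular chromophore set, which
the tests exploit with randomized synthetic chromophores.

The packaged chromophore spectra are *synthetic analytic stand-ins*, not
literature tabulations: Gaussian/power-law shapes scaled to physiological
magnitudes (oxyhemoglobin's 542/577 nm double peak and post-800 nm rise,
deoxyhemoglobin's 556 nm peak, ~10³ mm⁻¹·M⁻¹ red tail and 760 nm shoulder,
water and fat NIR features, melanin as a λ⁻³·³ power law). They reproduce
the qualitative sensitivity structure of the three-band inversion — in
particular, small absolute red/NIR band errors cause small absolute but
large relative melanosome-fraction errors while StO2 stays accurate — but
quantitative results for real tissue require loading measured compilations
through the same `ChromophoreSet` interface.

## Problem sizes and determinism

Routine tests use 2×10⁴-photon reference records and a 5×10⁴-photon record
for diffusion comparisons; the reproduction script uses 10⁵ photons. These
sizes put Monte Carlo standard errors near 10⁻³ in Rd, sufficient for the
percent-level physics checks, and keep a full run in minutes. All
randomness is seeded (basis generation via numpy Generator, photon
transport via numba's seeded RNG); every CLI output embeds the seed and a
configuration hash, and identical configurations reproduce bit-identical
outputs, Monte Carlo included.

## Known limitations

- No layered media, finite-slab transmission, time-resolved or polarized
  transport; no adding–doubling/IAD radiative inversion (only the
  power-law constraint stage of that workflow is provided).
- Detection integrates all exit angles; instruments with restricted
  collection geometry will see shape differences the model ignores.
- Concentration linearity is assumed exact; pigment aging, batch
  variability and fabrication (settling, bubbles) are out of scope.
- Recipes are continuous mass fractions; no rounding to pipettable
  amounts and no propagation of characterization uncertainty.
- The reflectance fit's concentration scale must be anchored externally
  (see above); StO2 inversion fixes W and F by assumption rather than
  fitting them.
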
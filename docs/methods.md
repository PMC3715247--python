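# Methods

`skinspectra` implements a snapshot multispectral imaging chain for skin:
a single white-balanced RGB frame is expanded into a 25-band reflectance
image by Wiener estimation, and per-pixel chromophore quantities — melanin
concentration C_m, total blood concentration C_tb, and tissue oxygen
saturation StO2 — are read off the 6 green-region bands by a two-stage
regression whose conversion step is trained on two-layer Monte Carlo skin
simulations.  This note records the models, the defaults and why they were
chosen, and what the synthetic test harness does and does not demonstrate.

## Camera forward model

A trichromatic camera under a known illuminant is linear in the scene
reflectance spectrum:

    v = F r,    F = U E S,

where `r` (k = 25, 450–690 nm at 10 nm) is the per-pixel reflectance
normalized to a white standard, the rows of the 3 × k matrix `F` are the
channel filter transmittances multiplied elementwise by the illuminant
spectrum and sensor sensitivity, and `v` is the linear RGB triple.  Two
conventions matter:

* The discrete sum carries no Δλ factor.  Any constant rescaling of `F`
  cancels between Wiener training and reconstruction, so the quadrature
  constant is irrelevant.
* RGB values are treated as linear after white-standard normalization
  (channel divided by the white-diffuser channel).  Power-law decoding is
  available (`decode_gamma`) but off by default; the pipeline assumes a
  radiometrically linear sensor.

The bundled camera profile is synthetic: Gaussian passbands near
460/540/610 nm, an LED-like illuminant and a gently sloped sensitivity,
generated deterministically by `fixtures.make_camera_profiles(seed)`.  Real
vendor curves can be substituted through the CSV profile format at any
time; nothing in the estimators assumes the synthetic shapes.

## Wiener estimation

The reconstruction matrix is the linear MMSE estimator

    W = <r rᵀ> Fᵀ (F <r rᵀ> Fᵀ)⁻¹,

with `<r rᵀ>` the plain ensemble mean (1/N, not 1/(N−1): it is a second
moment, not a covariance) of outer products over a training set of skin
reflectance spectra — by default 341 synthetic spectra, mirroring the size
of a spectrometer-acquired ensemble.  Numerical choices:

* The 3 × 3 Gram matrix is solved directly; above condition number 1e12 the
  solve falls back to a Moore–Penrose pseudo-inverse (rcond 1e-12) with a
  warning.
* An optional scalar noise variance can be added to the Gram diagonal
  (ridge against camera noise); the default is 0, i.e. the noise-free
  estimator.
* Negative reconstructed reflectances are kept.  Clipping is available but
  off by default, because silently clipping before the absorbance step
  would bias the downstream regression; instead nonpositive values are
  floored (default 1e-4) at the absorbance step and the pixel is flagged.

Reconstruction quality is scored by the goodness-of-fit coefficient, the
absolute cosine similarity of measured and estimated spectra; 0.995 is the
conventional colorimetric-accuracy bound and 0.999 an excellent fit.

## Two-layer Monte Carlo transport

`montecarlo.transport` is a standard layered photon-packet simulator:
normal launch, specular loss at the ambient interface, steps
s = −ln ξ / (μ_a + μ_s), implicit-capture weighting w → w μ_s/(μ_a+μ_s),
Henyey–Greenstein scattering, Fresnel reflection/refraction (with total
internal reflection) at boundaries, Russian roulette termination.  Details:

* **Tally.** Total, angle-integrated diffuse reflectance per wavelength; the
  specular launch loss is excluded from the diffuse tally, matching a
  crossed-polarizer acquisition that rejects specular light.  Transmitted
  and absorbed weight are tallied too, and the energy book including
  explicit roulette compensation balances to 1 within float accumulation
  (asserted at 1e-6).
* **Roulette.** Trigger weight 1e-3, survival 0.1.  Roulette is unbiased for
  any trigger; the early trigger shortens packet histories in the weakly
  absorbing dermis considerably at negligible variance cost for the grid
  sizes used here.
* **RNG.** numba's MT19937-compatible generator, seeded per run; a fixed
  seed is bit-reproducible.  Index-matched internal boundaries consume no
  random draw, so splitting a slab into identical sublayers is bit-identical
  to the merged slab (tested).
* **Geometry and optics.** Epidermis 0.06 mm over dermis 4.94 mm, both
  n = 1.4, ambient n = 1.0 above, index-matched below.  Scattering defaults
  (mc_defaults.yaml): μ_s(λ) = μ_s(550) (550/λ)^1.3 with μ_s(550) = 25 mm⁻¹
  (epidermis) and 10 mm⁻¹ (dermis), g = 0.7 — i.e. reduced scattering of
  roughly 7.5 and 3 mm⁻¹ at 550 nm, at the lower end of literature-typical
  skin values.  These are package defaults, not measurements; swapping the
  YAML changes the model.

Chromophores enter through absorption only: μ_a,epi = (C_m/100) ε_mel(λ)
and μ_a,derm = (C_tb/100)[(StO2/100) ε_oxy + (1−StO2/100) ε_deoxy].  The
bundled extinction table is a smooth synthetic stand-in (see its header):
a melanosome power law 49.6 (550/λ)^3.33 mm⁻¹ and whole-blood curves with
the standard oxy double peak (542/577 nm), deoxy single peak (556 nm) and
isosbestic crossings.  It is an exchangeable input — the same pipeline
handles e.g. melanoidin phantoms by swapping the melanin column.

## Two-stage regression

Per pixel, on the 6 estimation bands (500–600 nm at 20 nm, taken from the
25-band reconstruction by exact index):

1. **MRA1.** Absorbance A(λ) = −log10 r(λ) is regressed by OLS onto
   [ε_mel, ε_oxy, ε_deoxy, 1], giving coefficients (a_m, a_ob, a_db, a_0).
   These absorb the unknown mean path lengths and scattering attenuation, so
   they are proportional to, not equal to, concentrations.  StO2 follows
   directly as 100 a_ob/(a_ob + a_db) — path length cancels in the ratio —
   clipped to [0, 100] for reporting with the raw ratio retained.  A zero
   blood total leaves StO2 undefined (NaN + pixel flag).
2. **MRA2.** (a_m, a_tb = a_ob + a_db, a_0) is expanded into z = 14
   monomials — all terms of total degree ≤ 2 (10), the three pure cubes, and
   the triple product — ordered (1, a_m, a_tb, a_0, a_m a_tb, a_m a_0, …).
   Conversion vectors b_m, b_tb are two separate OLS fits of the known grid
   concentrations on these features, trained on the 300-state Monte Carlo
   grid (C_m 1–10% step 1, C_tb 0.2–1.0% step 0.2, StO2 0–100% step 20).
   Prediction is then two dot products per pixel; no simulation at run time.

Open choices resolved here: the basis is configurable (only its size and
leading terms are canonical); the fits are per-response rather than joint
(identical results for OLS, simpler failure modes); the regression operates
on (a_m, a_tb, a_0) with a_ob/a_db entering only through StO2.  Negative
predicted concentrations are clipped at 0 for maps but kept raw, since
under/overshoot regimes are diagnostically meaningful.

Degenerate inputs are refused loudly: collinear extinction columns on the
6-band grid name the offending pair; a rank-deficient MRA2 design (e.g. a
training grid whose intercept never varies) suggests a smaller basis.

## Synthetic data and what the tests show

All test inputs are generated by `skinspectra.fixtures`, deterministically
from seeds:

* **Skin ensembles** sample (C_m, C_tb, StO2) uniformly over (1–10%,
  0.2–1.0%, 0–100%) — the Monte Carlo grid ranges — and apply a ±10%
  scattering-baseline jitter, then evaluate a forward model.
* **Forward models.**  The full Monte Carlo simulator, or a modified
  Beer–Lambert surrogate R(λ) = R0(λ) exp(−μ_a,epi l_e − μ_a,derm l_d) with
  fixed effective double-pass paths l_e = 0.12 mm, l_d = 1.2 mm and a
  gently sloped baseline R0 ≈ 0.55.  The surrogate is smooth, monotone in
  each chromophore and instantaneous; fast tests use it, physics tests use
  the Monte Carlo path.  Surrogate training grids carry a small seeded
  baseline jitter so the MRA1 intercept varies across records (otherwise
  the 14-term basis is degenerate on them).
* **Scenes and sequences.**  Flat patchworks with exact ground-truth maps,
  and a cuff-occlusion schedule (129 frames, 5 s apart, 640 s total:
  baseline to 40 s, occlusion to 340 s with exponential StO2 decay and
  slight C_tb creep, then release with reactive-hyperemia overshoot).

Problem sizes in the default suite were chosen to keep a full run at
desk scale: the Monte Carlo training grid uses 1e4 photons per wavelength
(the production default in mc_defaults.yaml is 1e5), physics checks use
1e4–1e5 packets, and image tests use ≤ 16 × 16 scenes.

What passing tests demonstrate — and what they do not:

* Reconstruction: on held-out synthetic skin spectra the median GFC
  exceeds 0.995 comfortably (~0.9999).  This shows the estimator is
  correct and that the synthetic family is low-dimensional and smooth; it
  does not certify accuracy on real skin under a real camera.
* Closed-loop concentration recovery on the Monte Carlo grid reaches
  in-sample R² ≥ 0.95 for both C_m and C_tb, with median interior-state
  StO2 error around 6 points.
* Known limitation, reproduced rather than hidden: pushing the estimation
  through the 3-channel bottleneck compresses StO2 badly away from the
  prior mean and couples deoxygenation into the melanin estimate.  In the
  synthetic occlusion experiment the estimated StO2 falls monotonically but
  by only a few points against a ~60-point true swing, and the C_m estimate
  wobbles by roughly a quarter of its mean over a full-range blood swing.
  This mirrors the method's reported weakness at low saturations; tests pin
  the qualitative behavior (monotone fall; C_m far more stable than the
  blood quantities), not chromophore accuracy through the camera.
* The Monte Carlo physics checks (energy balance, absorption monotonicity,
  merged-layer equivalence, seed reproducibility) validate the transport
  kernel independently of any regression.

## Other limitations

* No sensor noise model, demosaicing, or gamma estimation; RGB noise in
  fixtures is optional multiplicative Gaussian.
* Single fixed layer geometry and scattering; sensitivity of the conversion
  vectors to μ_s, g and epidermal thickness is out of scope.
* No spatial or angular resolution in the transport tally; no
  depth-resolved estimation.
* ROI analysis assumes registered frames and rectangular ROIs.
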
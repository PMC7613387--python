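# Methods

This note documents the models, the tunable parameters, the numerical
choices, and the limits of what the synthetic fixtures can show.

## The retrieval scheme

`toatrait` implements a hybrid retrieval: a physically-motivated forward
chain simulates pairs of (trait state, top-of-atmosphere band reflectance),
and a Gaussian-process regressor learns the inverse mapping. Because the
training data are simulated at TOA level — canopy reflectance coupled
through an atmosphere — the resulting models apply directly to L1C-style
imagery with no atmospheric-correction step.

## Forward canopy model (analytic surrogate)

The default forward model is not a full radiative-transfer code; it is an
analytic surrogate designed to preserve the monotone spectral sensitivities
a retrieval exploits, while keeping the package dependency-free. A real
PROSPECT/SAIL-class model can be registered behind the same contract
(`register_forward_model`).

Leaf reflectance is a green-leaf baseline (low visible, red-edge rise at
~718 nm, NIR plateau, SWIR roll-off) attenuated by Beer–Lambert absorption
features:

- chlorophyll `Cab` (µg/cm²): Gaussian absorptions at 665 and 490 nm;
- water `Cw` (cm EWT): absorptions at 970, 1200, 1450 and 1940 nm plus a
  SWIR continuum, so both 1610 and 2190 nm carry water sensitivity;
- dry matter `Cm` (g/cm²): a broad SWIR term with a small flat floor;
- leaf structure `N`: a multiplicative scattering factor spanning ~±11%
  over the 1.3–2.5 range, matching the modest NIR sensitivity of
  plate-type leaf models.

Canopy reflectance mixes the leaf signal toward an `alpha_soil`-scaled soil
line through an exponential closure term `1 − exp(−k(ALA)·LAI/μ_s)` with
`k(ALA) = 0.4 + 0.5·cos(ALA)`. A NIR multiple-scattering term
`1 + 0.3·w_NIR(λ)·(1 − exp(−0.35·LAI))` brightens the plateau as leaf
layers accumulate; without it, LAI would enter only through closure and be
perfectly confounded with leaf angle — an artificial ill-posedness real
canopies do not exhibit. At `LAI = 0` the output is exactly the scaled soil
line. The hot-spot and diffuse-fraction parameters enter as small scalar
factors; they are fixed at 0.01 and 0.05 in the default configuration.

`FVC` is not sampled independently: it is derived per sample as
`clip(1 − exp(−k(ALA)·LAI), 0.05, 1)` — the nadir gap-fraction estimate —
so every sample carries a self-consistent cover label.

## Surrogate atmosphere and Lambertian coupling

Five per-wavelength transfer functions describe the atmosphere: path
reflectance, at-surface total scattered irradiance `E_total`, total gas
transmittance `t_g`, upwelling scattering transmittance `T_up`, and
spherical albedo `S`. The surrogate builds them from:

- Rayleigh optical depth (Hansen–Travis λ⁻⁴ form) and an aerosol term
  following the Angstrom law `τ_a(λ) = AOT·(λ/550)^(−ALPHA)`;
- single-scattering path reflectance with the Rayleigh phase function and a
  Henyey–Greenstein aerosol phase function (asymmetry `G`);
- gas transmittance as products of Gaussian absorption windows: a Chappuis
  ozone band near 600 nm scaled by `O3C` and water-vapour bands at
  940/1130/1380/1870 nm scaled by `CWV` (monotone: more water vapour never
  increases transmittance).

Coupling assumes a Lambertian homogeneous surface:

    ρ_TOA = t_g · [ ρ_path + T_down·T_up·ρ_BOA / (1 − S·ρ_BOA) ]

where the geometric series in `S·ρ` is the multiple surface–atmosphere
scattering. `T_down` is carried inside `E_total = μ_s·E0(λ)·T_down`, with
`E0` the package's smooth reference solar irradiance; the transfer-table
text format stores `μ_s` in a comment header so files round-trip
self-contained. Coupling is applied on the 1 nm grid and band-convolved
afterwards, mimicking sensor integration. Tables exported from a real
atmospheric code can replace the surrogate via `load_transfer_table`.

Measured sanity check: across the default atmospheric ranges, the
atmosphere-induced variability of the ten band reflectances is 0.1–0.3× the
canopy-induced variability — the atmospheric state perturbs, but does not
dominate, the signal.

## Sampling and the training database

The default configuration samples leaf and canopy variables from uniform or
range-truncated Gaussian distributions (truncation by resampling, never
clipping), the five atmospheric variables by Latin hypercube (one draw per
equal-width stratum), and geometry with the sun at 20–30° zenith, nadir
view. A default run produces 1000 simulated rows; additive Gaussian noise
(sd 0.01 reflectance, configurable) is injected on the BOA spectra just
before coupling; 40 rows of non-vegetated spectra (dark blue-skewed water,
brightness-scaled soil lines, bright flat man-made surfaces) are appended
with all trait labels set to zero, so models return near-zero over
non-vegetated scene elements. Band convolution uses Gaussian response
functions at the ten retrieval band centers (493–2190 nm) with published
bandwidths; a tabulated SRF file overrides.

## Gaussian-process regressor

Inputs are z-scored per band and targets z-scored; statistics are stored in
the model. The kernel is the anisotropic squared exponential with one
length-scale per band; the predictive variance convention is
`c* = k(x*,x*) + σ_n²`, i.e. the noise variance is included. Numerical
choices:

- Cholesky factorization with adaptive jitter (1e-10 growing ×10 to 1e-4).
- L-BFGS-B on log-hyperparameters, bounded: `log σ_s² ∈ [−6, 3]` (for
  z-scored targets the signal variance is O(1); the cap removes the flat
  ridge where σ_s² and the length-scales grow jointly and ruin variance
  calibration), `log σ_b ∈ [−6, 5]`, `log σ_n² ∈ [−12, 1]`.
- Start points: the marginal likelihood has a mean-only basin (length
  scales irrelevant, σ_n² ≈ 1) that L-BFGS enters whenever the initial
  noise is far too small, so the deterministic starts cover a
  moderate-noise start (σ_n² = 0.1) at two length-scale regimes (1 and
  √D — with z-scored features typical distances are ~√(2D)) plus one
  near-interpolation start, before the seeded random restarts
  (5 by default).
- If no optimizer run improves on its start, the best evaluated start is
  returned, so the stored log marginal likelihood is never worse than any
  start point.
- Degenerate constant targets are flagged with a warning; the model then
  predicts the constant.

The portable export precomputes `α = (K+σ_n²I)⁻¹y` and the explicit inverse
`(K+σ_n²I)⁻¹`, serialized as JSON (floats round-trip exactly). The portable
predictor evaluates the kernel row and the quadratic form with fixed-order
(`einsum`) reductions, so results are bit-identical no matter how pixels
are batched — this is what makes tiled raster processing exactly
reproducible.

## Active learning (EBD)

Diversity distances are minimum squared Euclidean distances on z-scored
band reflectances (pool statistics); mean-distance aggregation is available
as an option. The loop starts from a seeded-random 5% of the pool, proposes
the most distant remaining candidate, tentatively rebuilds the linear
algebra with the incumbent hyperparameters, and accepts only on a strict
validation-RMSE improvement; every candidate is evaluated exactly once.
On acceptance, hyperparameters are re-optimized warm-started from the
incumbent (8 quasi-Newton iterations); if the re-fit worsens validation
RMSE it is discarded, which preserves the guarantee that the final model's
validation RMSE never exceeds the initial one. Non-vegetated rows are
ordinary candidates by default (`force_include_nonveg` switches this). For
FVC no in situ data exist, so its model is trained on the full pool.

The acceptance-event RMSE sequence is strictly decreasing by construction;
the distance sequence of selected candidates is not monotone and is not
asserted.

## Evaluation conventions

NRMSE is RMSE divided by the observed range, in percent. R² is
`1 − SS_res/SS_tot` against the 1:1 line and can be negative; it is not the
squared correlation. Canopy products are leaf value × LAI with unit
conversions to g/m²: ×1e−2 for `Cab` (µg/cm²), ×1e4 for `Cw` (cm EWT) and
`Cm` (g/cm²). CV is 100·SD/mean; at means ≤ 1e-12 it is the maximal-
uncertainty sentinel (infinite), which the 30% mask always removes — the
mechanism by which low retrievals with any absolute uncertainty are masked.

## Raster mapping

Rasters are multi-band TIFFs with the affine transform, CRS string, nodata
value and band names stored as JSON in the ImageDescription tag;
pixel-center registration, no reprojection. Integer imagery is interpreted
as scaled reflectance (divisor 1e4, the L1C convention, configurable).
Masked or nodata pixels propagate to nodata in all output bands.
CV masking removes pixels strictly above the threshold (default 30%).
Median compositing takes, per pixel, the median of the valid means across
scenes — the lower central value for even counts, so the composited SD is
the SD of a scene that actually contributed — and leaves pixels invalid
everywhere as nodata.

## Synthetic fixtures: what they emulate and what they do not

The campaign generator draws per-plot traits from range-truncated Gaussians
(defaults: `Cab` 38.5–60.8 µg/cm² mean 52.8 SD 6, `Cw` 0.012–0.025 cm mean
0.019 SD 0.003, `Cm` 2.62–7.58 mg/cm² mean 5.03 SD 1.38, `LAI` 0.2–3.9
mean 2.9 SD 1.2; 52 plots split over two crops), pushes one joint state per
plot through the forward chain, and records:

- band reflectances with additive measurement noise (sd 0.005) and a
  per-crop systematic spectral mismatch (flat bias + spectral tilt,
  SD 0.05) emulating the structural model–data discrepancy (row geometry,
  clumping, non-leaf organs) that no amount of training data can fit;
- trait values with 10% relative error (instrument and sampling error of
  gap-fraction LAI meters, SPAD-calibrated chlorophyll, gravimetric water
  and dry matter), with canopy products recomputed from the erroneous leaf
  values as a real campaign would.

The truth table keeps the exact values. These two error components are what
make the active-learning validation RMSE floor, as it does against real
field data; with them, per-trait validation NRMSEs land at roughly
13–24% — the same order as published TOA validation results. What the
fixtures do **not** emulate: real sensor PSF/resampling, BRDF and
directional effects, clouds and cirrus, phenology-dependent mismatch, or
crop-specific architecture. Passing tests therefore demonstrate the
correctness and internal consistency of the chain, not field-ready
accuracy.

Scenes are rectangular fields plus a river strip and bare-soil background,
simulated with one atmosphere per scene (one acquisition). Per-pixel
recovery statistics on a single scene depend on the layout: a scene holds
only a handful of fields, each with its own structural nuisance draw, so
per-pixel R² against truth ranges roughly 0.8–0.97 across layouts.

## Problem sizes

Default experiment sizes were chosen so the full workflow runs on a
laptop-class single core: 1000-sample pools (plus 40 non-vegetated),
52-plot campaigns, 32×32 scenes, and full active-learning sweeps over all
seven traits with in situ data (a few hundred candidate evaluations per
trait after the 5% initialization). The acceptance script executes the
entire chain in minutes; all sizes are configurable upward.

## Known limitations

- The surrogate forward models reproduce qualitative sensitivities, not
  radiometric truth; absolute trait accuracies against real imagery require
  plugging in a real RTM and atmosphere tables.
- The GP scales as O(N³) in training-set size; pools beyond a few thousand
  samples are impractical, which is precisely why the active-learning
  reduction matters.
- Under the strict RMSE-decrease gate, the loop accepts many negligible
  improvements when validation data lie close to the training manifold, so
  the achieved pool reduction on synthetic campaigns (~60–78% per trait) is
  somewhat below what heavily mismatched real campaigns yield.
- The CV of near-zero retrievals is undefined/huge by construction;
  relative-uncertainty masks are informative over vegetated surfaces only.
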
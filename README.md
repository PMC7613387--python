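# toatrait

Hybrid retrieval of crop traits from top-of-atmosphere (TOA) multispectral
imagery.

Most machine-learning retrieval of vegetation traits works on
surface (bottom-of-atmosphere, BOA) reflectance, which requires an
atmospheric-correction step that adds its own uncertainty. The alternative
implemented here couples the canopy radiative-transfer simulation with an
atmospheric model, trains the regression directly at TOA level, and applies
it straight to L1C-style imagery. `toatrait` packages that workflow for
people building crop-monitoring pipelines from Sentinel-2-like data:

1. **Training-database simulation** (`toatrait.lut`, `toatrait.pipeline`) —
   sample leaf/canopy/atmosphere/geometry states from configurable
   distributions, run a forward canopy model (a documented analytic
   surrogate by default; a PROSAIL-style code can be registered), inject
   noise, couple to TOA under the Lambertian assumption, convolve to the ten
   retrieval bands (493–2190 nm), and append non-vegetated spectra with
   zero trait labels.
2. **Gaussian-process regression** (`toatrait.gpr`) — anisotropic
   squared-exponential kernel

   ```
   k(x_i, x_j) = σ_s² exp( −½ Σ_b [(x_i(b) − x_j(b)) / σ_b]² )
   ```

   trained by marginal-likelihood maximization; predictions carry both a
   mean and a variance,

   ```
   f(x*)    = k*ᵀ (K + σ_n² I)⁻¹ y
   σ_f²(x*) = c* − k*ᵀ (K + σ_n² I)⁻¹ k*,   c* = k(x*, x*) + σ_n²
   ```

   The factorized `PortableModel` export precomputes `(K + σ_n² I)⁻¹` and
   `α = (K + σ_n² I)⁻¹ y` into a self-contained JSON document so per-pixel
   mapping needs only small matrix products.
3. **Active learning** (`toatrait.al`) — Euclidean-distance-based diversity
   (EBD): iteratively propose the pool candidate with the largest minimum
   squared Euclidean distance `d_E = ‖x_u − x_l‖₂²` to the current training
   set, and keep it only when validation RMSE against an in situ table
   strictly improves. This shrinks the training set (and hence the exported
   model) severalfold at equal or better accuracy.
4. **Evaluation** (`toatrait.evaluation`) — RMSE, NRMSE (% of observed
   range), R² = 1 − SS_res/SS_tot, leaf-to-canopy upscaling
   (trait × LAI, in g/m²), and the relative uncertainty CV = 100·SD/mean.
5. **Raster mapping** (`toatrait.rasters`) — apply a portable model per
   pixel over multi-band TIFF rasters; write (mean, SD, CV) maps; mask
   pixels above a CV threshold (default 30%); median-composite time series.
6. **Synthetic fixtures** (`toatrait.fixtures`) — generate field-campaign
   validation tables (trait statistics emulating a two-crop temperate
   campaign) and small multi-band scenes with per-pixel truth, so the whole
   chain runs and is testable without any satellite download.

Retrieved traits: leaf chlorophyll `Cab` (µg/cm²), leaf water `Cw` (cm EWT),
leaf dry matter `Cm` (g/cm²), `LAI` (m²/m²), fractional cover `FVC`, and the
canopy-level products `laiCab`, `laiCw`, `laiCm` (g/m²).

## Worked example

```python
import toatrait as tt

pool = tt.build_training_set(n=300, n_nonveg=20, seed=1)
model = tt.train(pool.X, pool.traits["LAI"].to_numpy(),
                 tt.TrainConfig(n_restarts=3), seed=0,
                 trait="LAI", units="m^2/m^2")

held = tt.build_training_set(n=100, n_nonveg=0, seed=9)
report = tt.goodness_of_fit(held.traits["LAI"],
                            tt.predict(model, held.X).mean)
print(report)
```

Running `examples/02_train_and_predict.py` (which is this example plus the
portable export) prints:

```
trained on 320 samples; log marginal likelihood -155.5
held-out fit: RMSE 0.610 m2/m2, NRMSE 10.1%, R2 0.839 (n=100)
portable vs full model, max |mean difference|: 1.11e-13
first held-out predictions (mean +/- sd, truth):
   0.93 +/- 0.64   truth  0.97
   2.31 +/- 0.62   truth  2.15
```

The held-out RMSE of ~0.6 m²/m² (10% of the observed LAI range) is the
retrieval error of a 320-sample TOA model on samples from the same forward
chain; the per-prediction SD is the GP's own uncertainty estimate, which
the mapping module converts to CV for masking. The portable model
reproduces the full model to floating-point noise.

The other scripts in `examples/` walk through database simulation, the
active-learning loop (printing the acceptance history), and per-pixel scene
mapping with uncertainty masking and median compositing. A thin CLI mirrors
the same steps (`toatrait simulate|train|al|predict|validate|map|composite|fixtures`).

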
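"""Train a Gaussian-process LAI model and predict with uncertainty.

The anisotropic squared-exponential GP learns the mapping from ten
top-of-atmosphere band reflectances to leaf area index, returning a
predictive mean and standard deviation per query.  The factorized portable
export precomputes every term that depends on hyperparameters and training
data, so prediction needs only small matrix products.
"""

import numpy as np

import toatrait as tt

pool = tt.build_training_set(n=300, n_nonveg=20, seed=1)
model = tt.train(pool.X, pool.traits["LAI"].to_numpy(),
                 tt.TrainConfig(n_restarts=3), seed=0,
                 trait="LAI", units="m^2/m^2",
                 band_centers=tt.sentinel2_bands().centers)
print(f"trained on {len(pool)} samples; "
      f"log marginal likelihood {model.log_marginal_likelihood:.1f}")
print(f"noise variance (normalized targets): {model.hyper.sigma_n2:.4f}")

# held-out samples from the same forward chain
held = tt.build_training_set(n=100, n_nonveg=0, seed=9)
res = tt.predict(model, held.X)
report = tt.goodness_of_fit(held.traits["LAI"], res.mean,
                            trait="LAI", units="m^2/m^2")
print(f"\nheld-out fit: RMSE {report.RMSE:.3f} m2/m2, "
      f"NRMSE {report.NRMSE:.1f}%, R2 {report.R2:.3f} (n={report.n})")
print("NRMSE is the RMSE as a percentage of the observed LAI range; "
      "R2 is 1 - SS_res/SS_tot against the 1:1 line.")

# portable export round-trip
pm = tt.export_portable(model)
pm.save("lai_model.json")
back = tt.PortableModel.load("lai_model.json")
r_full = tt.predict(model, held.X[:5])
r_port = tt.predict_portable(back, held.X[:5])
print(f"\nportable vs full model, max |mean difference|: "
      f"{np.max(np.abs(r_full.mean - r_port.mean)):.2e}")
print("first held-out predictions (mean +/- sd, truth):")
for i in range(5):
    print(f"  {r_port.mean[i]:5.2f} +/- {r_port.sd[i]:4.2f}   "
          f"truth {held.traits['LAI'][i]:5.2f}")
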
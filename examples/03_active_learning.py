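"""Shrink a training pool with Euclidean-distance-based-diversity active learning.

Starting from a random 5% of the pool, the loop repeatedly proposes the most
diverse remaining candidate (largest minimum squared Euclidean distance to
the current training set), and keeps it only when the validation RMSE against
a synthetic field campaign strictly improves.  The result is a much smaller
model with equal or better accuracy — the property that makes server-side
per-pixel mapping tractable.
"""

import toatrait as tt

pool = tt.build_training_set(n=500, n_nonveg=40, seed=1)
truth, validation = tt.synth_field_campaign(tt.CampaignConfig(seed=7))
print(f"pool: {len(pool)} samples; campaign: {len(validation)} plots")

result = tt.al_optimize(pool, validation, "LAI", tt.ALConfig(), seed=3)

h = result.history
print(f"\nevaluated {len(h)} candidates, accepted {int(h['accepted'].sum())}")
print(f"training set: {result.n_pool} -> {len(result.training_set)} samples "
      f"({result.reduction_percent:.1f}% reduction)")
print(f"validation RMSE: {result.initial_rmse:.3f} -> {result.final_rmse:.3f} m2/m2")
acc = h[h["accepted"]]
print("\nfirst acceptance events (iteration, EBD distance, RMSE after adding):")
for _, row in acc.head(5).iterrows():
    print(f"  iter {int(row['iter']):4d}  d_E {row['d_E']:7.2f}  "
          f"RMSE {row['rmse']:.3f}")
print("RMSE at acceptance events is strictly decreasing by construction; "
      "the distance sequence need not be monotone.")
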
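"""Train the linear scoring function and predict mutations.

Uses a synthetic dataset with a known ground-truth linear model (50
complexes x 5 mutations, residual spread 0.76 kcal/mol — the statistical
shape of the curated experimental training data), fits the 11-feature OLS
model, and prints the training agreement and diagnostics.
"""

from priddg import fixtures
from priddg.evaluate import regression_metrics
from priddg.model import FEATURE_NAMES, fit, predict

df = fixtures.make_synthetic_dataset(noise_sd=0.76, seed=42)
model = fit(df)

pred = predict(model, df)
r, rmse, slope = regression_metrics(pred, df["ddg_exp"])
print(f"training set: n = {len(df)} mutations, "
      f"{df['pdb_id'].nunique()} complexes")
print(f"R = {r:.2f}, RMSE = {rmse:.2f} kcal/mol, slope = {slope:.2f}")
print("(R near 0.7 at this noise level; RMSE tracks the 0.76 kcal/mol "
      "residual spread)\n")

print("feature          coefficient   p-value     VIF")
for name in FEATURE_NAMES:
    print(f"{name:<16s} {model.coefficients[name]:>11.4f} "
          f"{model.pvalues[name]:>9.2g} {model.vif[name]:>7.2f}")
print("\nVIF < 3 for every feature indicates low collinearity.")
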
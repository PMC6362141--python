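"""Habitat suitability model and the diversity-vs-habitat regression.

Fits the spatially bootstrapped, averaged-PCA Mahalanobis model to
occurrences sampled from a synthetic landscape with known suitability,
scores the HSI raster, and then fits the logarithmic
allelic-richness-vs-habitat curve to the bundled gnatcatcher table.
"""

import numpy as np
from scipy.stats import spearmanr

from kinscape import (SimulationSpec, fit_diversity_models,
                      fit_partitioned_d2, load_ccg_diversity, percent_suitable,
                      score_hsi, simulate_landscape, spatial_bootstrap,
                      thin_occurrences, validate_model)

spec = SimulationSpec(master_seed=7)
env, truth, occ = simulate_landscape(spec)
occ = thin_occurrences(occ, env.ref)
cal = occ.subset(occ.role == "calibration")
model = fit_partitioned_d2(
    spatial_bootstrap(cal, cap=50, iterations=200, seed=0), env)
hsi = score_hsi(model, env, partition=list(range(len(env.names))))

ok = env.mask & truth.mask
rho = spearmanr(hsi.values[ok], truth.values[ok]).statistic
medians = validate_model(hsi, occ)
print(f"fitted HSI vs true suitability: Spearman rho = {rho:.2f} "
      "(cell ranking recovered)")
print(f"median HSI at occurrence cells: "
      + ", ".join(f"{k} {v:.2f}" for k, v in medians.items()))
pct = percent_suitable(hsi, (7500.0, 7500.0), 3000.0, threshold=0.5)
print(f"suitable habitat (HSI >= 0.5) within 3 km of the grid center: "
      f"{pct:.1f}% of land cells")

df = load_ccg_diversity()
fits = {f.form: f for f in fit_diversity_models(df.pct_suitable_30km, df.ar)}
log = fits["logarithmic"]
print(f"\ngnatcatcher aggregations (n=18): Ar = {log.intercept:.2f} + "
      f"{log.slope:.2f} ln(pct suitable, 30 km), R^2 = {log.r2:.2f}")
print(f"linear fit R^2 = {fits['linear'].r2:.2f} — the logarithmic curve "
      "fits better: diversity drops steeply below ~10% suitable habitat")
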
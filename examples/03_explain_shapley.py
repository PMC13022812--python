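"""Attribute a trained season model's predictions to its inputs with Shapley values.

The value function imputes absent features from background reference rows, so
phi is in probability units and sums to the prediction minus the background
mean.  Mean |phi| ranks feature importance; the Pearson correlation between a
feature and its phi column gives the direction of its effect.
"""

import numpy as np

from seasonsdm import cell_of, make_dataset, run_experiment, shap_for_samples
from seasonsdm import features as F

SEASON = "summer"

ds = make_dataset(seed=0, lam=2.0)
res = run_experiment(ds, "M1")
model = res.model_set.models[SEASON]
std = res.model_set.standardizers[SEASON]

rec = ds.records[ds.records["season"] == SEASON].head(40)
rows, cols = cell_of(rec["lat"].to_numpy(), rec["lon"].to_numpy(), ds.stack.grid)
X = std.transform(F.seasonal_matrix(ds.stack, SEASON, rows, cols))

bg = ds.background.points[:200]
brow, bcol = cell_of(bg[:, 0], bg[:, 1], ds.stack.grid)
R = std.transform(F.seasonal_matrix(ds.stack, SEASON, brow, bcol))

report = shap_for_samples(model.forward, X, R, n_permutations=128, seed=0,
                          schema=F.seasonal_schema(ds.stack.variables, SEASON),
                          season=SEASON)

order = np.argsort(-report.mean_abs)
print(f"{SEASON} model, top predictors by mean |phi| (probability units):")
for k in order[:6]:
    var, month = report.schema[k]
    r = report.pearson_r[k]
    print(f"  {var:>8} month {month:>2}: mean|phi|={report.mean_abs[k]:.4f}  "
          f"Pearson r={r:+.2f}")
print("The generative truth loads +3.5 on the season's main variable, so its")
print("three monthly columns should dominate with positive correlations.")
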
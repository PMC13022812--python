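"""Train the three model families and compare their test-set performance.

M0 sees annual-mean predictors, M1 the season's three monthly values, and M2
additionally chains the previous season's predicted probability into each
season's input.  Thresholds that maximize TSS are chosen on the validation
split; metrics are reported on the held-out test split, per season and
globally (the mean over seasons).
"""

from seasonsdm import SEASONS, make_dataset, run_experiment

ds = make_dataset(seed=0, lam=2.0)

for family in ("M0", "M1", "M2"):
    res = run_experiment(ds, family)
    g = res.report.global_metrics
    print(f"{family}: global AUC_ROC={g['auc_roc']:.3f} "
          f"AUC_PR={g['auc_pr']:.3f} TSS={g['tss']:.3f}")
    for s in SEASONS:
        m = res.report.seasonal[s]
        print(f"    {s:>6}: AUC_ROC={m['auc_roc']:.3f} TSS={m['tss']:.3f} "
              f"th={res.report.thresholds[s]:.2f}")

print("Expected ordering: the seasonal families beat the time-static baseline")
print("decisively. The chained family's edge over the independent one is small")
print("and shows up in the mean over replicate seeds (single seeds can tie);")
print("scripts/acceptance.py computes that 5-seed comparison.")
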
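"""Detect the driver value where a pair relationship reverses direction.

Binary synergy/trade-off labels are planted so their association with a
rank-uniformized driver flips sign at x* = 0.6.  A Newton-boosted tree
classifier is fitted, exact Shapley values are computed for the driver,
quantile-binned, LOESS-smoothed, and the zero crossing of the smoothed
curve is the detected threshold.
"""

from ecopipe.experiments import threshold_recovery_experiment

r = threshold_recovery_experiment(seed=3, n=2000, n_bins=20, loess_frac=0.5,
                                  x_star=0.6)

print(f"planted reversal at x* = {r['x_star']}")
print(f"classifier holdout AUC: {r['holdout_auc']:.3f}")
print(f"detected crossing(s):   {[round(c, 4) for c in r['crossings']]}")
print(f"absolute error:         {r['error']:.4f}")

curve = r["curve"]
print("\nbinned driver-vs-SHAP curve (20 quantile bins):")
print(f"{'driver':>8s} {'mean SHAP':>10s} {'smoothed':>10s}")
for x, s, sm in zip(curve.feature_mean, curve.shap_mean, curve.smoothed):
    marker = " <- sign change region" if abs(sm) < 0.2 else ""
    print(f"{x:8.3f} {s:10.3f} {sm:10.3f}{marker}")
print("\nPositive smoothed SHAP: the driver value pushes cells toward "
      "synergy; negative: toward trade-off. The zero crossing is the "
      "threshold where the association reverses.")

null = threshold_recovery_experiment(seed=3, null=True)
print(f"\nnull control (no planted effect): holdout AUC "
      f"{null['holdout_auc']:.3f} -> {null['n_crossings']} crossings "
      "(no-skill models are not interpreted)")
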
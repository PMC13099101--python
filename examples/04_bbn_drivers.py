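"""Identify the landscape factors driving service trade-offs/synergies.

A planted-truth demonstration: seven ES-like targets are synthesized so
that exactly two of the eight factors (precipitation and slope) carry all
the signal.  A two-layer Bayesian belief network (factors -> ES) is
learned from the cell data, service pairs are clamped to their extreme
states per the four scenario designs, and a factor counts as a driver
when any of its |posterior - prior| probability changes exceeds the 95th
percentile of all pooled changes (bootstrap CI on that threshold).
"""

from ecopipe.experiments import driver_recovery_experiment

r = driver_recovery_experiment(seed=7, size=96, n_boot=10_000)

print(f"planted drivers:    {r['planted']}")
print(f"identified drivers: {r['identified']}")
print(f"false positives:    {r['false_positives'] or 'none'}")
print(f"driver threshold:   {r['threshold']:.3f} "
      f"(95% bootstrap CI [{r['ci95'][0]:.3f}, {r['ci95'][1]:.3f}])")
print(f"scenarios run:      {r['n_scenarios']} "
      f"({r['n_deltas']} factor-state probability changes pooled)")
print("\nThe threshold is the 95th percentile of the pooled |posterior - "
      "prior| changes; factors exceeding it are the drivers. Recovery of "
      "exactly the planted pair shows the statistic separates signal "
      "factors from decoupled null factors.")
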
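"""Quantify shared-polymorphism turnover and annual recurrence.

Simulates per-month variant site sets under 20% monthly turnover, summarizes
the percentage of a reference month's SNPs shared with every other month,
fits the exponential-sigmoid decay model to the per-shift medians and runs
the annual-recurrence screen with and without a planted recurrence pool.
"""

import numpy as np

from chronotyper import (SimConfig, VariantProfile, fit_decay_model,
                         recurrence_test, shift_matrix, simulate_variant_sets)
from chronotyper.variants import shift_summary

ids = [f"vOTU_{i:03d}" for i in range(60)]

cfg = SimConfig(turnover=0.2, recurrence_weight=0.0, n_sites=100, seed=8)
sets = simulate_variant_sets(cfg, ids)
profiles = {c: VariantProfile(c, cfg.contig_length, s) for c, s in sets.items()}

summ = shift_summary(shift_matrix(profiles))
for d in (1, 3, 6, 12):
    row = summ[summ["shift"] == d].iloc[0]
    print(f"shift +{d:2d} months: median shared = {row['median_shared']:5.1f}% "
          f"(geometric expectation {100 * 0.8 ** d:5.1f}%)")

fit = fit_decay_model(summ["shift"], summ["median_shared"], side="positive",
                      seed=8)
print(f"exponential-sigmoid fit: k = {fit['k']:.3f}, plateau c = "
      f"{fit['c']:.1f}%, R^2 = {fit['r_squared']:.3f}")

_, null_frac = recurrence_test(profiles)
cfg_rec = SimConfig(turnover=0.2, recurrence_weight=0.5, n_sites=100, seed=8)
sets_rec = simulate_variant_sets(cfg_rec, ids)
profiles_rec = {c: VariantProfile(c, cfg_rec.contig_length, s)
                for c, s in sets_rec.items()}
_, rec_frac = recurrence_test(profiles_rec)
print(f"annual-recurrence screen: {100 * rec_frac:.0f}% flagged with a "
      f"planted annual pool vs {100 * null_frac:.0f}% under pure turnover")
print("Pure turnover loses ~20% of sites per month (Red Queen-like decay); "
      "the recurrence screen flags only profiles whose SNPs return at "
      "12-month gaps.")
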
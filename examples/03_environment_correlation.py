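"""Correlate chronotype medoids with environmental parameters.

Builds a synthetic environment table (annual temperature cycle, nutrients in
anti-phase), clusters the abundance series, picks each chronotype's medoid
and reports Holm-adjusted Spearman correlations.
"""

from chronotyper import (SimConfig, align_to_grid, bootstrap_consensus,
                         chronotype_medoids, cluster_correlation_profiles,
                         correlate_medoids, minmax_scale, simulate_abundance,
                         simulate_env, zscore_matrix)

cfg = SimConfig(n_votus=80, fraction_nonseasonal=0.0, n_chronotypes=4, seed=11)
am, truth = simulate_abundance(cfg)
aligned = align_to_grid(am)
Z, _ = zscore_matrix(aligned.values)
env = minmax_scale(simulate_env(cfg))

model = bootstrap_consensus(Z, am.votu_ids, n_bootstraps=10, subgroup_size=40,
                            seed=11)
medoids = chronotype_medoids(Z, model.votu_ids, model.memberships)
corr = correlate_medoids(aligned, medoids, env)

for c in sorted(medoids):
    sub = corr[corr["chronotype"] == c].set_index("parameter")
    top = sub["rho"].abs().idxmax()
    print(f"chronotype {c} (medoid {medoids[c]}): strongest parameter = "
          f"{top}, rho = {sub.loc[top, 'rho']:+.2f}, "
          f"Holm p = {sub.loc[top, 'p_adj']:.3g}")

Zlink, groups, rho = cluster_correlation_profiles(corr, n_groups=2)
print(f"correlation-profile clustering -> groups {groups}")
print("All annual-cycle parameters (temperature and, in anti-phase, the "
      "nutrients) correlate strongly with the medoids; chronotypes peaking "
      "in opposite seasons carry mirror-image profiles and split into two "
      "antagonistic clades.")
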
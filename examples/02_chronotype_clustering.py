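"""Cluster seasonal abundance series into chronotypes with the bootstrap
consensus algorithm and compare the result with the planted phase groups.
"""

from sklearn.metrics import adjusted_rand_score

from chronotyper import (SimConfig, align_to_grid, bootstrap_consensus,
                         simulate_abundance, zscore_matrix)

cfg = SimConfig(n_votus=120, fraction_nonseasonal=0.0, n_chronotypes=6, seed=1)
am, truth = simulate_abundance(cfg)
Z, _ = zscore_matrix(align_to_grid(am).values)

model = bootstrap_consensus(Z, am.votu_ids, n_bootstraps=20,
                            subgroup_size=40, seed=1)
pred = [model.memberships[v] for v in truth["votu_id"]]
ari = adjusted_rand_score(truth["group"], pred)

print(f"per-bootstrap optimal k: {sorted(set(model.per_bootstrap_k))} "
      f"-> k_final = {model.k_final} (max over bootstraps)")
print(f"adjusted Rand index vs the 6 planted phase groups: {ari:.3f}")
print("ARI 1.0 means the consensus chronotypes are exactly the planted "
      "groups; co-occurrence fractions near 0 or 1 indicate a stable "
      "partition across bootstrap rounds.")
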
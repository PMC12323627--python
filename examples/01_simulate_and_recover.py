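"""Generate a synthetic tripartite design and recover the planted edges.

Builds the default 28-sample design (two cTPut-positive and two
cTPut-negative mite cultures, seven replicates each), standardizes SOL
expression to 3,000 reads, calls permutation-Spearman edges between host
and SOL genes in the cTPut-positive samples, and reports how many of the
planted correlated pairs were recovered.
"""

import symbionet as sn

matrices, samples, catalog, truth = sn.simulate(sn.SimConfig(seed=42))
print(f"compartments: { {c: m.shape for c, m in matrices.items()} }")
print(f"samples: {len(samples.sample_ids)} across cultures {samples.cultures()}")

sol = sn.standardize_counts(matrices["SOL"], 3000)
positive = samples.ids_by_status(True)
edges = sn.correlation_matrix(
    matrices["host"], sol,
    sn.CorrConfig(n_perm=999, alpha=0.05, seed=1),
    sample_subset=positive,
)
n_pos = int((edges["sign"] > 0).sum())
n_neg = int((edges["sign"] < 0).sum())
print(f"significant edges in cTPut-positive samples: {len(edges)} "
      f"({n_pos} positive, {n_neg} negative)")

planted = {(a, b) for (a, ca, b, cb, *_) in truth.planted_pairs
           if ca == "host" and cb == "SOL"}
found = set(zip(edges["source_gene"], edges["target_gene"]))
sens = len(planted & found) / len(planted)
print(f"planted host-SOL pairs recovered: {len(planted & found)}/{len(planted)} "
      f"(sensitivity {sens:.2f})")
# The permutation-Spearman screen recovers most of the correlation
# structure planted at loading 0.9 (sensitivity fluctuates around ~0.9
# across seeds because replicates share each block's latent factor).
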
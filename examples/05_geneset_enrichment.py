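"""Minimum-p permutation enrichment of candidate gene lists.

Runs a null association scan, assigns variants to tiled gene models,
then tests one truly-enriched list (genes holding injected signal) and
one random list against size-matched permutation nulls.
"""

import numpy as np
import pandas as pd

import tempgen as tg
from tempgen.assoc import lmm_scan
from tempgen.enrichment import assign_variants_to_genes, run_enrichment_suite

config = tg.SimConfig(n_founders=300, n_generations=0, n_snvs=3000,
                      n_chromosomes=10, seed=5)
ped = tg.simulate_pedigree(config)
rng = config.rng()
gm, _ = tg.gene_drop_genotypes(ped, config, rng)

genes = pd.DataFrame(
    [(f"g{c}_{k}", str(c), 1 + 4000 * k, 4000 * (k + 1), "+")
     for c in range(1, 11) for k in range(70)],
    columns=["gene", "chrom", "start", "end", "strand"],
)

# inject signal: 15 causal variants, each inside a distinct "candidate" gene
causal = list(range(10, 3000, 200))
Z = gm.dosage[:, causal]
Z = (Z - Z.mean(0)) / Z.std(0)
y = Z.sum(1) * np.sqrt(0.02) + rng.standard_normal(ped.n) * np.sqrt(1 - 0.3)
scan = lmm_scan(y, np.ones((ped.n, 1)), None, gm)

universe = assign_variants_to_genes(scan.table, genes, flank=0)
candidate = [
    universe.loc[
        universe["gene"].isin(
            genes[(genes["chrom"] == gm.variants.loc[j, "chrom"])
                  & (genes["start"] <= gm.variants.loc[j, "pos"])
                  & (genes["end"] >= gm.variants.loc[j, "pos"])]["gene"]
        ),
        "gene",
    ].iloc[0]
    for j in causal
]
random_list = list(np.random.default_rng(0).choice(universe["gene"], 31, replace=False))

results, errors = run_enrichment_suite(
    universe, {"candidates": candidate, "random31": random_list},
    n_permutations=10_000, seed=5,
)
print(f"universe: {len(universe)} genes with >= 1 assigned variant")
for name, r in results.items():
    print(f"{name:10s} n={r.n_target:3d}  mean min-p = {r.observed_mean_min_p:.4f}  "
          f"permutation p = {r.p_value:.4f}  [(k+1)/(B+1) = {r.p_value_adjusted:.4f}]")
print("\nThe candidate list (each gene holds an injected causal variant) has a "
      "far smaller mean minimum p than size-matched random draws; the random "
      "list's permutation p is unremarkable, as it should be under the null.")
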
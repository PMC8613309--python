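"""Kinship-corrected SNV association scan with a spiked-in causal variant.

Simulates a family-structured cohort, injects one causal SNV into the
inhibition composite, and contrasts the calibrated mixed-model scan with
naive regression on the same data.
"""

import numpy as np

import tempgen as tg
from tempgen.assoc import genomic_inflation, genomic_relationship_matrix, lmm_scan

config = tg.SimConfig(n_founders=60, n_generations=2, mean_offspring=3.4,
                      n_snvs=3000, h2_activity=0.6, h2_emotionality=0.6, seed=4)
ped = tg.simulate_pedigree(config)
rng = config.rng()
gm, _ = tg.gene_drop_genotypes(ped, config, rng)
_, truth = tg.simulate_phenotypes(ped, config, rng)

# phenotype: heritable background + one causal SNV explaining ~8% of variance
g = gm.dosage[:, 1234]
gz = (g - g.mean()) / g.std()
y = tg.inverse_normal_transform(
    truth.latent["activity_d1"] * np.sqrt(0.92) + gz * np.sqrt(0.08)
)
X = np.column_stack([np.ones(ped.n), (ped.sex == "M").astype(float)])

K = genomic_relationship_matrix(gm)
res = lmm_scan(y, X, K, gm)
ols = lmm_scan(y, X, None, gm)
man, hits = tg.manhattan_table(res)

causal_id = gm.variants.loc[1234, "id"]
top = res.table.nsmallest(3, "p")[["id", "beta", "p"]]
print(f"{ped.n} animals, {res.n_tested} SNVs, null-model h2 = {res.null_h2:.2f}")
print(f"genomic inflation: LMM {genomic_inflation(res.table['p']):.3f} "
      f"vs naive OLS {genomic_inflation(ols.table['p']):.3f}")
print(f"top signals (injected causal variant is {causal_id}):")
print(top.to_string(index=False))
print(f"{len(hits)} variant(s) exceed the genome-wide threshold p < 5e-8")
print("\nThe LMM stays near lambda = 1 despite the strong family structure "
      "that inflates OLS, and the causal variant tops the scan.")
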
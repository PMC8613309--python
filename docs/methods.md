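# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `tempgen`.

## Phenotype model and scoring

The two-day infant battery yields, per animal and day, continuous items
(time locomoting, time not hanging, exploration rate, cooing rate, barking
rate) and rare behaviors recorded 0/1 (ate food, drank water, crouching,
scratched, threats, lipsmacked). Factor scores are loading-weighted sums of
within-day z-scored items, re-standardized to cohort mean 0 / SD 1 per day.
The original factor loadings are not public, so loadings are a configurable
input defaulting to unit weights with fixed sign conventions; crouching
carries a negative Activity loading (a crouched animal is an inactive one),
and "time NOT hanging" already encodes its reflection. Dichotomous items
enter the z-scoring as 0/1; because they are heavily skewed (few positives),
factor scores built on them are right-skewed, which is why somewhat more
than 25% of a cohort falls below the mean on both factors.

**Classification.** "Below the mean on both factors across two days" is read
as: average each factor over the two days, then require *strictly* below the
cohort mean on both day-averaged factors (ties → not inhibited; continuous
scores make ties measure-zero, and strictness keeps the rule deterministic).
The stricter all-four-scores-below rule is available as `rule="all_four"`.
The continuous composite is minus the mean of the four standardized scores,
so higher = more inhibited.

**Inverse normal transform.** Rank-based with the Blom offset,
`Φ⁻¹((r − 3/8)/(n + 1/4))`, average ranks for ties. Blom is a convention
choice; any offset in the standard family gives scores identical up to a
near-affine map, which the variance-ratio estimates are insensitive to.

## Pedigree and the relationship matrix

Pedigrees are validated (acyclic, sires male, dams female, no id used in
both roles) and topologically sorted on load. **A** is computed by the
tabular method — `A_ij = (A_{j,s} + A_{j,d})/2`, `A_ii = 1 + A_{sd}/2` —
because downstream REML consumes the eigendecomposition of A, not its
inverse, making Henderson's A⁻¹ shortcut pointless here. Unknown single
parents are treated as unrelated phantom founders. Storage is dense: a
~4,400-animal colony needs ~150 MB, acceptable at workstation scale.

## REML animal models

With `A = U D Uᵀ`, rotating `y` and `X` by `Uᵀ` diagonalizes the covariance.

*Univariate.* The restricted likelihood is profiled over the heritability
ratio on [10⁻⁶, 1−10⁻⁶] (bounded scalar minimization, tolerance 10⁻⁸), the
total variance profiled analytically, and both boundaries checked
explicitly afterwards. The SE of h² is the inverse curvature (central
second difference, step 10⁻⁴, evaluation point clipped inside the bounds)
of the restricted log-likelihood. Significance of σ²ₐ > 0 uses the LRT
against h² = 0 with the 50:50 χ²₀/χ²₁ boundary mixture — the convention of
the standard pedigree-analysis packages. A flat likelihood (A with no
eigenvalue spread, e.g. all founders) is flagged `identifiable=False`
rather than reported silently. Sex is the only default covariate: the
battery tests all infants in the same narrow age window, so age adds
nothing.

*Bivariate.* Genetic covariance `ρ_g σ_a1 σ_a2` (scaled by A), residual
covariance `ρ_e σ_e1 σ_e2`. After rotation the likelihood factors into
per-eigenvalue 2×2 blocks, so each evaluation is O(n). Optimization is
Nelder-Mead over (log σ²'s, atanh ρ's), started from the univariate fits
and the phenotypic correlation; the ρ_g = 0 p-value is a 1-df LRT against
the constrained refit (an interior hypothesis, so no boundary mixture),
and the SE of ρ_g comes from the numerical Hessian via the delta method.
Dichotomous IT is analyzed through its continuous composite by default;
the 0/1 label can be passed directly to the same linear REML path (the
default discrete-trait approximation of the classic pedigree tools).

## Mixed-model association

Null-model variance components are estimated once by REML on the kinship
matrix (genotype GRM over standardized dosages `(g−2p)/√(2p(1−p))` by
default, pedigree A optionally) and held fixed across variants — the
standard fast-LMM approximation. Each variant is then a GLS Wald test with
per-variant residual variance and `n − p − 1` degrees of freedom; with
identity kinship this reduces *exactly* to ordinary least-squares t-tests,
which is both a correctness check and the deliberately exposed "naive"
comparator for inflation demonstrations. Missing genotypes are mean-imputed
per variant; monomorphic variants are dropped; no MAF filter is applied by
default. Coordinates are 1-based VCF throughout; variant ids are
`chrom:pos:ref:alt`; the genome-wide threshold defaults to 5×10⁻⁸.

## Permutation gene-set enrichment

Variants are assigned to every gene whose `[start − flank, end + flank]`
span contains them (default flank 10 kb, configurable to 500 kb — real
regulatory attributions can reach hundreds of kb). The universe is the set
of genes with ≥ 1 assigned variant; genes without variants have no minimum
p. The statistic is the raw mean of per-gene minimum p over the target
list; each of B permutations draws a same-size gene set without replacement
from the universe, and `p = #{permutation mean < observed}/B` with strict
inequality (ties count against enrichment). The exact-proportion contract
(`p·B` integer) is kept, with `(k+1)/(B+1)` reported alongside. Raw min-p
means are dominated by large p-values; a log₁₀ variant is easy to add but
the raw mean is the primary statistic by design. Per-list random streams
derive from `(master seed, crc32(list name))`, making multi-list suites
reproducible and mutually independent. Gene-count matching only ("similarly
sized" = same number of genes): no matching on gene length or SNV density,
so lists of unusually long/variant-dense genes will look enriched for
structural reasons — a known limitation shared with the plain form of this
statistic.

## Longitudinal statistics

Logistic regression is IRLS with convergence at relative log-likelihood
change < 10⁻¹⁰; Wald z and two-sided normal p-values from the inverse
Fisher information. Complete separation by a single predictor is detected
up front and raised with the predictor named. IT enters as the 0/1 label
(the continuous composite is an option); age in years, linear, no
interactions. The stability test is Pearson χ² on the 2×2 cross-tabulation,
1 df, no continuity correction by default (Yates optional).

## Synthetic-data generator

The generator defines the study conditions for every validation:

* **Pedigree** — founders with alternating sexes; each later generation
  randomly pairs males and females of the previous generation (monogamous,
  full-sib and parent-offspring matings excluded by default; configurable),
  with `round(mean_offspring × pairs)` offspring assigned to pairs uniformly
  and offspring sexes balanced. Defaults (500 founders, 4 generations,
  mean offspring 2.6) give a ~4,500-member colony like the real cohort.
* **Genotypes** — biallelic SNVs gene-dropped: founders Hardy-Weinberg at
  frequencies uniform on `maf_range` (default 0.05–0.5), fair Mendelian
  transmission below; positions tile `n_chromosomes` (default 20) contigs.
* **Phenotypes** — breeding values drawn exactly as `N(0, G ⊗ A)` via the
  Cholesky factor of A (so phenotype simulation is independent of the SNV
  panel); an optional SNV-effect mode builds Activity breeding values from
  causal dosages for association power studies. Each day × factor latent is
  breeding value + independent day residual with phenotypic variance 1;
  default heritabilities 0.30/0.17 (the reported range endpoints for the
  factors) and genetic correlation 0.65 (mid-range of the reported 0.45–
  0.89). Cross-day phenotypic correlation therefore comes only from the
  genetic term (no permanent-environment component, the simplest structure
  consistent with four separately heritable day × factor variables). Items
  observe their latent with noise chosen for item-latent correlations of
  ~0.75–0.85 — the reliability ballpark of scored behavioral batteries —
  and rare items are dichotomized at z > 1.5 (positives ~7%, matching
  "dichotomized due to rarity"; no published rule exists).
* **Refusal** — first-trial refusal is Bernoulli with
  `logit p = −1.0 + 1.0·IT − 0.25·age` (inhibited animals ~e× the odds,
  older animals less likely, matching the reported directions); a
  first-trial refuser refuses all trials with probability 0.82 (the
  reported all-or-nothing persistence). Repeat assessments are independent
  given the label, so simulated cross-assessment stability is *weaker* than
  the colony's (which reflects a persistent animal-level propensity beyond
  the infant label); the χ² machinery is exercised either way.

What the generator does **not** emulate: linkage/recombination (sites are
independent, so no local LD structure around hits), dominance or epistasis,
selection, X-linkage, genotyping error or missingness patterns, assortative
mating, maternal/common-environment effects, and the phenotypic (as opposed
to genetic) correlation structure of the real cohort, which is unpublished.
Passing tests therefore demonstrate estimator correctness under the assumed
additive bivariate model — not robustness to violations of it.

## Validation design and problem sizes

The colony's restricted phenotype/pedigree data and the 106 WGS genomes are
not redistributable, so validation is parameter recovery on synthetic
cohorts, sized for a single desktop CPU: heritability recovery uses 100
replicate cohorts on a ~1,200-member pedigree at h² = 0.19 (one shared
eigendecomposition); genetic-correlation recovery 50 replicates each at
ρ_g ∈ {0, 0.45, 0.89}, n ≈ 1,000; inflation calibration a ~400-animal
sibship-rich cohort with 6,000 null SNVs (the median-based λ needs many
variants for precision); enrichment nulls 200 random
31-gene lists at 500 permutations; type-I rates 500 replicates per test.
Recovery checks use ±3 standard-error Monte-Carlo bands; oracle
equivalences use absolute tolerances (10⁻⁶ likelihood, 10⁻⁸ GLS, 10⁻⁶
logistic coefficients, 0.02 entrywise for the gene-dropping estimate of A
at 10⁵ loci).

## Numerical notes and edge cases

* Eigenvalues of A are clipped at 0; matrices whose most negative
  eigenvalue is materially below zero are rejected as corrupted.
* `1e-10` jitter on the diagonal before the Cholesky of A (singular A with
  duplicate individuals still fails, as it should).
* The bivariate likelihood returns +∞ penalty outside the positive-definite
  region and for |transformed parameters| > 40, keeping Nelder-Mead inside
  a numerically safe box; perfectly collinear traits drive ρ̂ → 1 and stop
  at the iteration cap with ρ > 0.999.
* Association p-values are clipped away from exact 0; permutation p-values
  are exact proportions and may be exactly 0 (the `(k+1)/(B+1)` variant is
  reported for users who need a strictly positive estimate).
* A variant whose genotypes are all missing is skipped and logged, never
  imputed into the scan.
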
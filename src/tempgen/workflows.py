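"""Study-level orchestration of the analysis stages.

Three canonical analyses mirror how a temperament-genetics study of a
pedigreed colony is organized:

1. **Longitudinal prediction** — does infant inhibited temperament (IT)
   predict refusing a treat from a human years later, and is refusal
   stable across repeat assessments?
2. **Heritability** — animal-model REML heritability of IT and its four
   day x factor components, plus their pairwise genetic correlations.
3. **Association and enrichment** — kinship-corrected SNV association
   with the IT composite, and permutation enrichment of candidate gene
   lists against per-gene minimum p-values.

Each function consumes plain in-memory objects (DataFrames, arrays) so
it can run on synthetic or user data; the CLI wraps these with file I/O.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .assoc import AssociationResult, kinship_for_assoc, lmm_scan, manhattan_table
from .enrichment import run_enrichment_suite
from .genotypes import GenotypeMatrix
from .longitudinal import fit_logistic, refusal_summary, stability_chi2
from .pedigree import MALE, Pedigree
from .phenotype import SCORE_COLUMNS, inverse_normal_transform
from .varcomp import (
    GeneticCorrelationFit,
    VarianceComponentsFit,
    eigendecompose,
    heritability_report,
    reml_bivariate,
    reml_univariate,
)

__all__ = ["study1_longitudinal", "study2_heritability", "study3_association"]


def study1_longitudinal(refusal: pd.DataFrame, labels: pd.DataFrame) -> dict:
    """Logistic and chi-squared analyses of treat refusal.

    ``refusal`` holds one row per animal x assessment (columns animal,
    assessment, refused, first_trial_refused, age); ``labels`` the
    per-animal temperament call.  Returns the IT-only fit, the
    age-controlled fit, the first-assessment-pair stability test and the
    descriptive summary.
    """
    rec = refusal.merge(
        labels["inhibited"].astype(int), left_on="animal", right_index=True
    )
    first = rec[rec["assessment"] == rec["assessment"].min()]
    design_it = first[["inhibited"]].astype(float)
    fit_it = fit_logistic(first["first_trial_refused"].astype(int), design_it)
    design_age = first[["inhibited", "age"]].astype(float)
    fit_it_age = fit_logistic(first["first_trial_refused"].astype(int), design_age)

    wide = rec.pivot_table(
        index="animal", columns="assessment", values="refused", aggfunc="first"
    )
    stability = None
    if wide.shape[1] >= 2:
        a, b = wide.columns[:2]
        both = wide[[a, b]].dropna()
        stability = stability_chi2(both[a].astype(int), both[b].astype(int))

    return {
        "fit_it": fit_it,
        "fit_it_age": fit_it_age,
        "stability": stability,
        "summary": refusal_summary(rec),
    }


def _transformed_traits(scores: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    traits = pd.DataFrame(index=scores.index)
    traits["IT"] = inverse_normal_transform(labels["it_continuous"])
    for col in SCORE_COLUMNS:
        traits[col] = inverse_normal_transform(scores[col])
    return traits


def study2_heritability(
    scores: pd.DataFrame,
    labels: pd.DataFrame,
    pedigree: Pedigree,
    A: np.ndarray,
    rho_pairs: list[tuple[str, str]] | None = None,
    compute_rho: bool = True,
) -> dict:
    """Heritability of IT and its factors, with genetic correlations.

    Phenotypes are inverse-normal transformed and fitted with sex as the
    only covariate (all animals are assessed in the same narrow age
    window, so age adds nothing).  ``scores`` must be indexed by animal
    in pedigree order.
    """
    if not np.array_equal(np.asarray(scores.index), pedigree.ids):
        raise ValueError("scores must be aligned to pedigree order")
    traits = _transformed_traits(scores, labels)
    X = np.column_stack(
        [np.ones(pedigree.n), (pedigree.sex == MALE).astype(float)]
    )
    eigen = eigendecompose(A)
    fits: dict[str, VarianceComponentsFit] = {
        name: reml_univariate(
            traits[name].to_numpy(), X, eigen=eigen, beta_names=["intercept", "sex"]
        )
        for name in traits.columns
    }
    rho_fits: dict[tuple[str, str], GeneticCorrelationFit] = {}
    if compute_rho:
        pairs = rho_pairs or list(itertools.combinations(traits.columns, 2))
        for t1, t2 in pairs:
            rho_fits[(t1, t2)] = reml_bivariate(
                traits[t1].to_numpy(),
                traits[t2].to_numpy(),
                X,
                eigen=eigen,
                compute_se=False,
            )
    report = heritability_report(fits, rho_fits)
    return {"fits": fits, "rho_fits": rho_fits, **report}


def study3_association(
    scores: pd.DataFrame,
    labels: pd.DataFrame,
    genotypes: GenotypeMatrix,
    sex: np.ndarray,
    gene_models: pd.DataFrame | None = None,
    gene_lists: dict[str, list[str]] | None = None,
    kinship_source: str = "grm",
    pedigree: Pedigree | None = None,
    A: np.ndarray | None = None,
    flank: int = 10_000,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> dict:
    """Mixed-model scan of the IT composite plus gene-set enrichment.

    The phenotype is the inverse-normal transformed continuous IT
    composite of the genotyped animals; sex is the fixed covariate; the
    kinship matrix is a genotype GRM by default.  Enrichment runs only
    when gene models and target lists are supplied.
    """
    animals = list(genotypes.samples)
    y = inverse_normal_transform(labels.loc[animals, "it_continuous"])
    X = np.column_stack([np.ones(len(animals)), (np.asarray(sex) == MALE).astype(float)])
    K = kinship_for_assoc(
        kinship_source,
        genotypes=genotypes,
        pedigree_A=A,
        pedigree_ids=pedigree.ids if pedigree is not None else None,
    )
    result: AssociationResult = lmm_scan(y, X, K, genotypes, kinship_source)
    man, hits = manhattan_table(result)
    out = {"association": result, "manhattan": man, "hits": hits}
    if gene_models is not None and gene_lists:
        from .enrichment import assign_variants_to_genes

        gene_minp = assign_variants_to_genes(result.table, gene_models, flank=flank)
        results, errors = run_enrichment_suite(
            gene_minp, gene_lists, n_permutations=n_permutations, seed=seed
        )
        out.update({"gene_minp": gene_minp, "enrichment": results, "enrichment_errors": errors})
    return out
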
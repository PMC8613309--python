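"""Kinship-aware single-variant association (mixed-model GWAS).

Each SNV is tested for association with the phenotype under the linear
mixed model ``y = X beta + g_j b_j + u + e`` with ``u ~ N(0, sigma2_g K)``
for a kinship matrix ``K`` (genotype GRM by default, pedigree ``A``
optionally).  The null-model variance ratio is estimated once by REML via
the eigendecomposition of ``K`` and then held fixed while every variant
is scored with a generalized-least-squares Wald test — the standard
fast-LMM approximation.  With ``K = None`` the same code path reduces to
ordinary least squares, which is deliberately exposed so calibration
against naive regression can be demonstrated on related samples.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, read_vcf  # noqa: F401  (re-export)
from .varcomp import eigendecompose, reml_univariate

log = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "genomic_relationship_matrix",
    "kinship_for_assoc",
    "lmm_scan",
    "manhattan_table",
    "genomic_inflation",
    "read_vcf",
]

GENOME_WIDE_ALPHA = 5e-8


@dataclasses.dataclass
class AssociationResult:
    """Per-variant scan results plus null-model metadata."""

    table: pd.DataFrame          # chrom, pos, ref, alt, id, beta, se, stat, p
    kinship_source: str
    null_h2: float               # variance ratio sigma2_g/(sigma2_g+sigma2_e)
    n_samples: int
    n_tested: int
    n_skipped: int


def genomic_relationship_matrix(
    gm: GenotypeMatrix, min_variants: int = 50
) -> np.ndarray:
    """GRM from standardized dosages: ``Z Z' / m``.

    Dosages are centered at ``2p`` and scaled by ``sqrt(2 p (1-p))``
    using observed allele frequencies; missing entries are mean-imputed
    (zero after standardization).  Monomorphic variants are dropped.
    """
    dos = gm.dosage
    p = np.nanmean(dos, axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    m = int(poly.sum())
    if m < min_variants:
        raise ValueError(
            f"only {m} polymorphic variants; need >= {min_variants} for a stable GRM"
        )
    d = dos[:, poly]
    p = p[poly]
    Z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    Z = np.where(np.isnan(Z), 0.0, Z)
    return (Z @ Z.T) / m


def kinship_for_assoc(
    source: str,
    genotypes: GenotypeMatrix | None = None,
    pedigree_A: np.ndarray | None = None,
    pedigree_ids: np.ndarray | None = None,
    min_variants: int = 50,
) -> np.ndarray:
    """Kinship matrix for the scan: ``"grm"`` or ``"pedigree"``.

    The pedigree option restricts the precomputed ``A`` to the genotyped
    samples (ids aligned to ``genotypes.samples``).
    """
    if source == "grm":
        if genotypes is None:
            raise ValueError("GRM kinship requires genotypes")
        return genomic_relationship_matrix(genotypes, min_variants=min_variants)
    if source == "pedigree":
        if pedigree_A is None or pedigree_ids is None or genotypes is None:
            raise ValueError("pedigree kinship requires A, its ids, and genotypes")
        lookup = {s: i for i, s in enumerate(pedigree_ids)}
        missing = [s for s in genotypes.samples if s not in lookup]
        if missing:
            raise KeyError(f"genotyped sample(s) absent from pedigree: {missing[:10]}")
        idx = np.array([lookup[s] for s in genotypes.samples])
        return pedigree_A[np.ix_(idx, idx)]
    raise ValueError(f"unknown kinship source {source!r}")


def lmm_scan(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None,
    G: GenotypeMatrix,
    kinship_source: str = "grm",
) -> AssociationResult:
    """Scan every variant with a mixed-model Wald test.

    ``y``, rows of ``X`` and ``K`` and samples of ``G`` must be aligned.
    Missing genotypes are mean-imputed per variant; variants monomorphic
    after imputation are skipped.  With ``K=None`` the test is ordinary
    least squares (identity covariance); either way the per-variant test
    is a t-test with ``n - p - 1`` degrees of freedom under the fixed
    null variance ratio.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if len(y) != n or G.n_samples != n:
        raise ValueError("y, X and genotypes must be aligned on samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")

    if K is None:
        d = np.ones(n)
        U = np.eye(n)
        h2 = 0.0
        source = "none (OLS)"
    else:
        d, U = eigendecompose(np.asarray(K, dtype=float))
        fit = reml_univariate(y, X, eigen=(d, U))
        h2 = fit.h2
        source = kinship_source

    yr = U.T @ y
    Xr = U.T @ X
    w = 1.0 / np.clip(h2 * d + (1.0 - h2), 1e-12, None)

    # GLS residualization of y on X once, then every (imputed) variant.
    XtWX = Xr.T @ (w[:, None] * Xr)
    XtWX_inv = np.linalg.inv(XtWX)
    beta0 = XtWX_inv @ (Xr.T @ (w * yr))
    ry = yr - Xr @ beta0
    rss0 = float(np.sum(w * ry * ry))

    dos = G.dosage
    mean_g = np.nanmean(dos, axis=0)
    filled = np.where(np.isnan(dos), mean_g[None, :], dos)
    var_g = filled.var(axis=0)
    keep = var_g > 0.0
    all_missing = np.isnan(dos).all(axis=0)
    n_skipped = int((~keep).sum())
    if all_missing.any():
        log.warning("%d variant(s) with all genotypes missing skipped", int(all_missing.sum()))
    if keep.sum() == 0:
        raise ValueError("no polymorphic variants to test")

    Gr = U.T @ filled[:, keep]
    Eg = Gr - Xr @ (XtWX_inv @ (Xr.T @ (w[:, None] * Gr)))
    gWg = np.einsum("ij,ij->j", Eg, w[:, None] * Eg)
    gWy = Eg.T @ (w * ry)
    beta = gWy / gWg
    rss = rss0 - beta * gWy
    dof = n - p - 1
    sigma2 = np.clip(rss, 0.0, None) / dof
    se = np.sqrt(sigma2 / gWg)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    table = G.variants.loc[keep, ["chrom", "pos", "ref", "alt", "id"]].reset_index(drop=True)
    table["beta"] = beta
    table["se"] = se
    table["stat"] = tstat
    table["p"] = pvals
    return AssociationResult(
        table=table,
        kinship_source=source,
        null_h2=float(h2),
        n_samples=n,
        n_tested=int(keep.sum()),
        n_skipped=n_skipped,
    )


def manhattan_table(
    result: AssociationResult, threshold: float = GENOME_WIDE_ALPHA
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready table (cumulative coordinate, -log10 p) and flagged hits."""
    tab = result.table.copy()
    if tab.empty:
        raise ValueError("no association results")
    offset = 0
    cum = np.empty(len(tab))
    chrom_order = list(pd.unique(tab["chrom"]))
    for chrom in chrom_order:
        mask = (tab["chrom"] == chrom).to_numpy()
        pos = tab.loc[mask, "pos"].to_numpy()
        cum[mask] = pos + offset
        offset += pos.max() + 1
    tab["cum_pos"] = cum
    tab["neglog10_p"] = -np.log10(tab["p"])
    tab["significant"] = tab["p"] < threshold
    hits = tab[tab["significant"]].sort_values("p").reset_index(drop=True)
    return tab, hits


def manhattan_plot(table: pd.DataFrame, path: str, threshold: float = GENOME_WIDE_ALPHA) -> None:
    """Save a Manhattan plot (alternating chromosome shades, threshold line)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for k, (chrom, grp) in enumerate(table.groupby("chrom", sort=False)):
        ax.scatter(grp["cum_pos"], grp["neglog10_p"], s=4,
                   color="#444444" if k % 2 else "#1f77b4", rasterized=True)
    ax.axhline(-np.log10(threshold), color="red", lw=1)
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic inflation factor lambda: median chi2 over its null median."""
    pvals = np.asarray(pvals, dtype=float)
    pvals = pvals[np.isfinite(pvals)]
    if len(pvals) == 0:
        raise ValueError("no p-values")
    chi2_obs = stats.chi2.isf(np.clip(pvals, 1e-300, 1.0), df=1)
    return float(np.median(chi2_obs) / stats.chi2.ppf(0.5, df=1))
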
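"""Gene-level minimum-p permutation enrichment.

Candidate gene lists from human genome-wide gene-association studies are
tested for enrichment of small association p-values: every variant is
assigned to each gene whose flanked interval contains it, each gene keeps
the minimum p over its variants, the observed statistic is the mean of
those minima over the target list, and its significance is the fraction
of size-matched random gene sets (drawn without replacement from the
universe of genes that received at least one variant) whose mean minimum
p is *lower* than the target's.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentResult",
    "read_gene_models",
    "read_gene_list",
    "assign_variants_to_genes",
    "permutation_enrichment",
    "run_enrichment_suite",
]

DEFAULT_FLANK = 10_000
MAX_FLANK = 500_000
DEFAULT_PERMUTATIONS = 10_000


@dataclasses.dataclass
class EnrichmentResult:
    """Permutation test of one target gene list."""

    name: str
    n_target: int                 # target genes found in the universe
    n_requested: int              # size of the supplied list
    observed_mean_min_p: float
    n_permutations: int
    n_lower: int                  # permutations with mean strictly below observed
    p_value: float                # n_lower / n_permutations
    p_value_adjusted: float       # (n_lower + 1) / (n_permutations + 1)
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_gene_models(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Load gene models from BED6 or GFF3 into a 1-based closed table.

    BED is 0-based half-open, GFF3 1-based closed; both are converted to
    one 1-based closed convention (columns gene, chrom, start, end,
    strand).  For GFF3 only ``gene`` features are kept and the symbol is
    taken from ``Name`` (falling back to ``ID``).  Format is inferred
    from the extension when not given.
    """
    import pyranges as pr

    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff3" if suffix in (".gff", ".gff3") else "bed"
    if fmt == "bed":
        df = pr.read_bed(str(path)).df
        name_col = "Name"
    elif fmt == "gff3":
        df = pr.read_gff3(str(path)).df
        df = df[df["Feature"] == "gene"].copy()
        name_col = "Name" if "Name" in df.columns else "ID"
        if name_col == "Name" and df["Name"].isna().any():
            df["Name"] = df["Name"].fillna(df["ID"])
    else:
        raise ValueError(f"unknown gene-model format {fmt!r}")
    out = pd.DataFrame(
        {
            "gene": df[name_col].astype(str),
            "chrom": df["Chromosome"].astype(str),
            # pyranges is internally 0-based half-open for both dialects
            "start": df["Start"].astype(int) + 1,
            "end": df["End"].astype(int),
            "strand": df["Strand"].astype(str) if "Strand" in df else ".",
        }
    ).reset_index(drop=True)
    bad = out[out["start"] > out["end"]]
    if len(bad):
        raise ValueError(f"gene(s) with start > end: {bad['gene'].tolist()[:5]}")
    return out


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def assign_variants_to_genes(
    assoc_table: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = DEFAULT_FLANK,
) -> pd.DataFrame:
    """Per-gene minimum association p over variants in the flanked span.

    A variant at position ``pos`` is assigned to every gene with
    ``start - flank <= pos <= end + flank`` on the same chromosome
    (multi-assignment allowed).  Genes containing no variant are absent
    from the output; an empty result raises (it almost always means the
    two inputs use different assemblies or chromosome names).
    """
    if not (0 <= flank <= MAX_FLANK):
        raise ValueError(f"flank must be in [0, {MAX_FLANK}]")
    need = {"chrom", "pos", "p"}
    if not need <= set(assoc_table.columns):
        raise ValueError(f"association table needs columns {sorted(need)}")

    rows = []
    by_chrom = {
        str(c): grp.sort_values("pos") for c, grp in assoc_table.groupby("chrom")
    }
    for g in genes.itertuples(index=False):
        grp = by_chrom.get(str(g.chrom))
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, g.start - flank, side="left")
        hi = np.searchsorted(pos, g.end + flank, side="right")
        if hi > lo:
            pslice = grp["p"].to_numpy()[lo:hi]
            rows.append((g.gene, float(pslice.min()), int(hi - lo)))
    if not rows:
        raise ValueError(
            "no variant overlaps any gene interval; check assembly/chromosome naming"
        )
    return (
        pd.DataFrame(rows, columns=["gene", "min_p", "n_variants"])
        .groupby("gene", as_index=False)
        .agg(min_p=("min_p", "min"), n_variants=("n_variants", "sum"))
    )


def permutation_enrichment(
    gene_minp: pd.DataFrame,
    target_genes: Iterable[str],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    name: str = "target",
) -> EnrichmentResult:
    """Size-matched random-gene-set permutation test of a target list.

    The observed statistic is the mean of the target genes' minimum
    p-values (targets absent from the universe are dropped and counted).
    Each of ``n_permutations`` draws, without replacement, a random gene
    set of the same size from the whole universe; the reported p-value is
    the exact proportion of permutation means *strictly below* the
    observed mean, with the standard ``(k+1)/(B+1)`` correction reported
    alongside.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    universe = gene_minp["gene"].to_numpy()
    minp = gene_minp["min_p"].to_numpy(dtype=float)
    targets = list(dict.fromkeys(target_genes))
    mask = np.isin(universe, targets)
    n_found = int(mask.sum())
    if n_found == 0:
        raise ValueError(f"no gene of list {name!r} is in the min-p universe")
    t_obs = float(minp[mask].mean())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_repr = -1 if isinstance(seed, np.random.Generator) else int(seed)
    G = len(universe)
    B = int(n_permutations)
    k = 0
    # chunked sampling without replacement via random-key argpartition
    chunk = max(1, min(B, int(2e7) // max(G, 1)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        keys = rng.random((b, G))
        idx = np.argpartition(keys, n_found - 1, axis=1)[:, :n_found]
        means = minp[idx].mean(axis=1)
        k += int(np.sum(means < t_obs))
        done += b

    return EnrichmentResult(
        name=name,
        n_target=n_found,
        n_requested=len(targets),
        observed_mean_min_p=t_obs,
        n_permutations=B,
        n_lower=k,
        p_value=k / B,
        p_value_adjusted=(k + 1) / (B + 1),
        seed=seed_repr,
    )


def _list_seed(master_seed: int, list_name: str) -> np.random.Generator:
    """Independent, reproducible stream per list: seeded by (master, crc32(name))."""
    return np.random.default_rng([int(master_seed), zlib.crc32(list_name.encode())])


def run_enrichment_suite(
    gene_minp: pd.DataFrame,
    lists: Mapping[str, Iterable[str]],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> tuple[dict[str, EnrichmentResult], dict[str, str]]:
    """Run the permutation test for several target lists.

    Per-list random streams are derived deterministically from the master
    seed and the list name, so lists are independent and the whole suite
    is reproducible.  A failing list (e.g. empty intersection with the
    universe) is reported in the errors dict without aborting the others.
    """
    if not lists:
        raise ValueError("no target lists supplied")
    results: dict[str, EnrichmentResult] = {}
    errors: dict[str, str] = {}
    for list_name, genes in lists.items():
        try:
            res = permutation_enrichment(
                gene_minp,
                genes,
                n_permutations=n_permutations,
                seed=_list_seed(seed, list_name),
                name=list_name,
            )
            res.seed = seed
            results[list_name] = res
        except ValueError as exc:
            errors[list_name] = str(exc)
    return results, errors
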
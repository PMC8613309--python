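"""Genotype dosage matrices and VCF input/output.

Genotypes are held as an animals x variants dosage matrix (0/1/2 copies
of the alternate allele, ``nan`` = missing) plus a variant metadata table
(chrom, pos, ref, alt, id).  Variant ids follow the ``chrom:pos:ref:alt``
convention.  Reading uses cyvcf2; writing emits plain uncompressed VCF
v4.2 with diploid GT fields.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "read_vcf", "write_vcf"]

META_COLUMNS = ["chrom", "pos", "ref", "alt", "id"]


@dataclasses.dataclass
class GenotypeMatrix:
    """Dosage matrix with aligned sample ids and variant metadata."""

    samples: np.ndarray          # (n,) sample ids
    dosage: np.ndarray           # (n, m) float, 0/1/2 or nan
    variants: pd.DataFrame       # m rows, columns META_COLUMNS

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError("sample count does not match dosage rows")
        if len(self.variants) != m:
            raise ValueError("variant count does not match dosage columns")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not increasing on chrom {chrom}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"sample(s) not in genotype matrix: {missing[:10]}")
        idx = np.array([lookup[s] for s in ids])
        return GenotypeMatrix(
            samples=np.asarray(ids, dtype=object),
            dosage=self.dosage[idx],
            variants=self.variants,
        )

    def allele_frequencies(self) -> np.ndarray:
        """Observed alternate-allele frequency per variant (missing skipped)."""
        return np.nanmean(self.dosage, axis=0) / 2.0


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a diploid VCF into a dosage matrix.

    Multi-allelic sites are skipped (logged).  Missing genotypes (./.)
    become ``nan``, never 0.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dos)
        vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        meta.append((str(var.CHROM), int(var.POS), var.REF, var.ALT[0], vid))
    if n_multi:
        log.warning("skipped %d multi-allelic site(s) in %s", n_multi, path)
    if not rows:
        raise ValueError(f"no usable biallelic sites in {path}")
    variants = pd.DataFrame(meta, columns=META_COLUMNS)
    return GenotypeMatrix(
        samples=samples,
        dosage=np.stack(rows, axis=1),
        variants=variants,
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str | Path, extra_header: Sequence[str] = ()) -> None:
    """Write the matrix as uncompressed VCF v4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for line in extra_header:
            fh.write(f"##{line}\n")
        for chrom in pd.unique(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, gm.samples))
            + "\n"
        )
        dosage = gm.dosage
        for j, row in enumerate(gm.variants.itertuples(index=False)):
            calls = [
                "./." if np.isnan(d) else _GT[int(d)] for d in dosage[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )
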
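"""Synthetic colony generator with known ground truth.

The restricted inputs of the original colony study — a multi-generational
breeding pedigree, per-animal behavioral item scores, whole-genome SNVs
and later-life treat-refusal outcomes — are emulated here with the exact
statistical structure the analysis assumes:

* a multi-generational pedigree from random within-generation mating
  (avoiding parent-offspring and full-sib matings by default);
* biallelic SNVs gene-dropped through the pedigree by fair Mendelian
  transmission from Hardy-Weinberg founders;
* bivariate latent Activity / Emotionality factors whose additive
  genetic values follow ``N(0, G (x) A)`` — heritabilities and the
  genetic correlation are configurable — observed through the item
  battery with item noise and rare-item dichotomization;
* a binary treat-refusal outcome driven logistically by inhibited
  temperament and age.

Every downstream stage can therefore be checked against known truth.
All randomness flows from one integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .genotypes import GenotypeMatrix, write_vcf
from .items import ACTIVITY, EMOTIONALITY, ITEMS
from .pedigree import (
    FEMALE,
    MALE,
    Pedigree,
    PedigreeError,
    numerator_relationship_matrix,
    write_pedigree,
)

__all__ = [
    "SimConfig",
    "TrueValues",
    "simulate_pedigree",
    "gene_drop_genotypes",
    "simulate_phenotypes",
    "simulate_refusal",
    "simulate_dataset",
    "write_dataset",
]


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic colony.

    Defaults mirror the published study conditions: a ~4400-member
    four-generation pedigree, factor heritabilities at the reported range
    endpoints (0.30 and 0.17), a genetic correlation of 0.65 between the
    factors, and a treat-refusal model in which inhibited animals are
    ~e^1 times more likely to refuse and older animals less likely.
    """

    n_founders: int = 500
    n_generations: int = 4
    mean_offspring: float = 2.6
    allow_inbreeding: bool = False

    n_snvs: int = 5000
    n_chromosomes: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)

    h2_activity: float = 0.30
    h2_emotionality: float = 0.17
    rho_g_true: float = 0.65
    sex_effect_activity: float = 0.0
    sex_effect_emotionality: float = 0.0
    rare_item_threshold: float = 1.5

    refusal_intercept: float = -1.0
    beta_it: float = 1.0
    beta_age: float = -0.25
    persistence: float = 0.82   # P(refuse all trials | refused first trial)

    # optional SNV-effect mode: breeding values as sums of SNV effects
    n_causal_snvs: int = 0

    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("h2_activity", "h2_emotionality"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (-1.0 <= self.rho_g_true <= 1.0):
            raise ValueError("rho_g_true must be in [-1, 1]")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclasses.dataclass
class TrueValues:
    """Ground truth of one simulated cohort.

    ``breeding_values`` has one row per animal (columns activity,
    emotionality); ``realized_h2`` is var(breeding value)/var(latent
    phenotype) of this particular sample, per day x factor variable.
    """

    breeding_values: pd.DataFrame
    allele_freqs: np.ndarray | None
    snv_effects: np.ndarray | None
    realized_h2: dict[str, float]
    latent: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "realized_h2": self.realized_h2,
            "breeding_values": {
                "animal": self.breeding_values.index.tolist(),
                "activity": self.breeding_values["activity"].round(6).tolist(),
                "emotionality": self.breeding_values["emotionality"].round(6).tolist(),
            },
            "allele_freqs": (
                None if self.allele_freqs is None else np.round(self.allele_freqs, 6).tolist()
            ),
            "snv_effects": (
                None if self.snv_effects is None else np.round(self.snv_effects, 6).tolist()
            ),
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# pedigree


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random sexes constrained to an even split (both sexes whenever n>=2)."""
    sexes = np.array([MALE, FEMALE] * (n // 2) + [MALE] * (n % 2), dtype=object)
    rng.shuffle(sexes)
    return sexes


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Breed a multi-generational pedigree by random within-generation mating.

    Founders (generation 0) get alternating sexes.  In each later
    generation, males and females of the previous generation are randomly
    paired (full-sib pairs rejected unless ``allow_inbreeding``); the
    generation's ``round(mean_offspring * n_pairs)`` offspring are
    assigned to pairs uniformly at random, with sexes balanced.
    """
    rng = config.rng() if rng is None else rng
    ids = [f"I{k:06d}" for k in range(config.n_founders)]
    sexes = [MALE if k % 2 == 0 else FEMALE for k in range(config.n_founders)]
    rows: list[tuple[str, str, str, str]] = [
        (i, "0", "0", s) for i, s in zip(ids, sexes)
    ]
    gen_of = {i: 0 for i in ids}
    parents_of: dict[str, tuple[str, str]] = {i: ("0", "0") for i in ids}
    counter = config.n_founders

    sex_of = {r[0]: r[3] for r in rows}
    prev = [r[0] for r in rows]
    for gen in range(1, config.n_generations + 1):
        males = [i for i in prev if sex_of[i] == MALE]
        females = [i for i in prev if sex_of[i] == FEMALE]
        if not males or not females:
            raise PedigreeError(
                f"generation {gen - 1} lacks one sex; cannot breed generation {gen}"
            )
        rng.shuffle(males)
        rng.shuffle(females)
        pairs = list(zip(males, females))
        if not config.allow_inbreeding:
            ok = [
                (m, f)
                for m, f in pairs
                if parents_of[m] == ("0", "0")
                or parents_of[m] != parents_of[f]
            ]
            pairs = ok
        if not pairs:
            raise PedigreeError(
                f"no eligible matings in generation {gen} "
                "(all candidate pairs are full sibs)"
            )
        n_off = int(round(config.mean_offspring * len(pairs)))
        assign = rng.integers(0, len(pairs), size=n_off)
        off_sex = _balanced_sexes(n_off, rng)
        new: list[str] = []
        for k in range(n_off):
            sire, dam = pairs[assign[k]]
            cid = f"I{counter:06d}"
            counter += 1
            rows.append((cid, sire, dam, off_sex[k]))
            sex_of[cid] = off_sex[k]
            parents_of[cid] = (sire, dam)
            gen_of[cid] = gen
            new.append(cid)
        prev = new

    return Pedigree.from_records(rows, generation=gen_of)


# ---------------------------------------------------------------------------
# genotypes


def gene_drop_genotypes(
    pedigree: Pedigree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    allele_freqs: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop biallelic SNVs through the pedigree by Mendelian transmission.

    Founder genotypes are Hardy-Weinberg draws at per-site frequencies
    sampled uniformly from ``config.maf_range`` (or supplied); each
    non-founder receives one allele from each parent, a heterozygous
    parent transmitting either allele with probability 1/2.  A missing
    parent contributes a fresh population allele (phantom founder).

    Returns the genotype matrix (0/1/2 dosages, no missingness) and the
    founder allele frequencies.
    """
    rng = config.rng() if rng is None else rng
    m = config.n_snvs
    if allele_freqs is None:
        lo, hi = config.maf_range
        allele_freqs = rng.uniform(lo, hi, size=m)
    p = np.asarray(allele_freqs, dtype=float)
    n = pedigree.n
    geno = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        a_pat = (
            rng.random(m) < (geno[s] / 2.0)
            if s >= 0
            else rng.random(m) < p
        )
        a_mat = (
            rng.random(m) < (geno[d] / 2.0)
            if d >= 0
            else rng.random(m) < p
        )
        geno[i] = a_pat.astype(np.int8) + a_mat.astype(np.int8)

    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chroms = [str(1 + j // per_chrom) for j in range(m)]
    pos = [1000 * (1 + j % per_chrom) for j in range(m)]
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=m)]
    alt = np.array(
        [bases[(list(bases).index(r) + rng.integers(1, 4)) % 4] for r in ref]
    )
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "id": [f"{c}:{q}:{r}:{a}" for c, q, r, a in zip(chroms, pos, ref, alt)],
        }
    )
    gm = GenotypeMatrix(
        samples=pedigree.ids.copy(),
        dosage=geno.astype(float),
        variants=variants,
    )
    return gm, p


# ---------------------------------------------------------------------------
# phenotypes


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    """Symmetric square root tolerating singular (h2=0 or |rho|=1) inputs."""
    w, v = np.linalg.eigh(mat)
    w = np.clip(w, 0.0, None)
    return v @ np.diag(np.sqrt(w)) @ v.T


def _breeding_values(
    A: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw bivariate breeding values with covariance G (x) A (Cholesky route)."""
    h2a, h2e = config.h2_activity, config.h2_emotionality
    cov_g = config.rho_g_true * np.sqrt(h2a * h2e)
    G = np.array([[h2a, cov_g], [cov_g, h2e]])
    n = A.shape[0]
    L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    Z = rng.standard_normal((n, 2))
    return L @ Z @ _psd_sqrt(G).T


def simulate_phenotypes(
    pedigree: Pedigree,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    A: np.ndarray | None = None,
    genotypes: GenotypeMatrix | None = None,
) -> tuple[pd.DataFrame, TrueValues]:
    """Simulate the two-day behavioral item battery for every animal.

    Latent Activity and Emotionality on each day are breeding value plus
    an independent day-specific residual (phenotypic variance 1 per
    day x factor); breeding values are bivariate normal with covariance
    ``G (x) A`` where ``G`` encodes the configured heritabilities and
    genetic correlation.  Items observe their factor's latent value
    through the registry's sign, scale and noise; rare items are
    dichotomized at the configured z-threshold.  With
    ``config.n_causal_snvs > 0`` and genotypes supplied, the Activity
    breeding values are instead sums of SNV effects (for association
    power studies).

    Returns the tidy record table (animal, day, sex, item columns) and
    the :class:`TrueValues` ground truth.
    """
    rng = config.rng() if rng is None else rng
    if A is None:
        A = numerator_relationship_matrix(pedigree)
    n = pedigree.n
    if np.linalg.matrix_rank(A, tol=1e-10) < min(10, n) and n > 1:
        raise ValueError("relationship matrix is singular; invalid pedigree")

    bv = _breeding_values(A, config, rng)
    if config.n_causal_snvs > 0:
        if genotypes is None:
            raise ValueError("SNV-effect mode requires genotypes")
        bv = bv.copy()
        bv[:, 0] = _snv_breeding_values(genotypes, config, rng)

    sex_ind = (pedigree.sex == MALE).astype(float)
    sex_eff = {
        ACTIVITY: config.sex_effect_activity,
        EMOTIONALITY: config.sex_effect_emotionality,
    }
    h2 = {ACTIVITY: config.h2_activity, EMOTIONALITY: config.h2_emotionality}
    bv_by_factor = {ACTIVITY: bv[:, 0], EMOTIONALITY: bv[:, 1]}

    latent: dict[str, np.ndarray] = {}
    realized: dict[str, float] = {}
    for factor in (ACTIVITY, EMOTIONALITY):
        for day in (1, 2):
            resid = rng.standard_normal(n) * np.sqrt(max(1.0 - h2[factor], 0.0))
            lat = bv_by_factor[factor] + resid + sex_eff[factor] * sex_ind
            key = f"{factor}_d{day}"
            latent[key] = lat
            var_lat = lat.var(ddof=0)
            realized[key] = (
                float(bv_by_factor[factor].var(ddof=0) / var_lat) if var_lat > 0 else 0.0
            )

    frames = []
    for day in (1, 2):
        cols: dict[str, np.ndarray] = {
            "animal": pedigree.ids,
            "day": np.full(n, day),
            "sex": pedigree.sex,
        }
        for it in ITEMS:
            signal = it.sign * latent[f"{it.factor}_d{day}"]
            noise = rng.standard_normal(n) * it.sim_noise
            if it.dichotomous:
                underlying = signal + noise
                z = (underlying - underlying.mean()) / underlying.std(ddof=0)
                cols[it.name] = (z > config.rare_item_threshold).astype(int)
            else:
                raw = it.sim_offset + it.sim_scale * (signal + noise)
                cols[it.name] = np.clip(raw, 0.0, None)
        frames.append(pd.DataFrame(cols))
    records = pd.concat(frames, ignore_index=True)

    truth = TrueValues(
        breeding_values=pd.DataFrame(
            {"activity": bv[:, 0], "emotionality": bv[:, 1]},
            index=pd.Index(pedigree.ids, name="animal"),
        ),
        allele_freqs=None,
        snv_effects=None,
        realized_h2=realized,
        latent=pd.DataFrame(latent, index=pd.Index(pedigree.ids, name="animal")),
    )
    return records, truth


def _snv_breeding_values(
    genotypes: GenotypeMatrix, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Additive SNV-effect breeding values scaled to variance h2_activity."""
    m = genotypes.n_variants
    idx = rng.choice(m, size=min(config.n_causal_snvs, m), replace=False)
    effects = rng.standard_normal(len(idx))
    g = genotypes.dosage[:, idx]
    score = (g - g.mean(axis=0)) @ effects
    sd = score.std(ddof=0)
    if sd == 0:
        return np.zeros(genotypes.n_samples)
    return score / sd * np.sqrt(config.h2_activity)


# ---------------------------------------------------------------------------
# refusal outcomes


def simulate_refusal(
    labels: pd.DataFrame,
    ages: np.ndarray | pd.Series,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_assessments: int = 1,
    spacing_years: float = 1.8,
    sex: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate treat-refusal assessments from temperament labels.

    First-trial refusal is Bernoulli with
    ``logit(p) = intercept + beta_it * inhibited + beta_age * age``.
    A first-trial refuser refuses all three trials with probability
    ``config.persistence`` (the all-or-nothing character of the task);
    an animal that accepts the first treat accepts throughout.  Repeat
    assessments are independent draws given the same temperament label
    and an age advanced by ``spacing_years``, so cross-assessment
    stability comes only from the shared temperament (there is no extra
    per-animal propensity term).
    """
    rng = config.rng() if rng is None else rng
    it = labels["inhibited"].to_numpy(dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(labels):
        raise ValueError("need one age per animal")
    out = []
    for k in range(n_assessments):
        age_k = ages + k * spacing_years
        eta = config.refusal_intercept + config.beta_it * it + config.beta_age * age_k
        first = rng.random(len(it)) < expit(eta)
        all_three = first & (rng.random(len(it)) < config.persistence)
        out.append(
            pd.DataFrame(
                {
                    "animal": labels.index,
                    "assessment": k + 1,
                    "first_trial_refused": first,
                    "refused": all_three,
                    "age": age_k,
                    "sex": sex if sex is not None else ["U"] * len(it),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# one-call dataset


def simulate_dataset(
    config: SimConfig,
) -> dict:
    """Generate pedigree, genotypes, phenotypes, labels and refusal data.

    A single generator seeded from ``config.seed`` drives every stage, so
    identical configs give identical datasets.  Returns a dict with keys
    ``pedigree``, ``A``, ``genotypes``, ``allele_freqs``, ``records``,
    ``truth``, ``scores``, ``labels``, ``refusal``.
    """
    from .phenotype import classify_it, score_factors

    rng = config.rng()
    ped = simulate_pedigree(config, rng)
    A = numerator_relationship_matrix(ped)
    gm, freqs = gene_drop_genotypes(ped, config, rng)
    records, truth = simulate_phenotypes(ped, config, rng, A=A, genotypes=gm)
    truth.allele_freqs = freqs
    scores = score_factors(records)
    labels = classify_it(scores)
    ages = rng.uniform(2.0, 10.0, size=ped.n)
    refusal = simulate_refusal(
        labels, ages, config, rng, n_assessments=2, sex=ped.sex
    )
    return {
        "pedigree": ped,
        "A": A,
        "genotypes": gm,
        "allele_freqs": freqs,
        "records": records,
        "truth": truth,
        "scores": scores,
        "labels": labels,
        "refusal": refusal,
    }


def write_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Simulate and write the full dataset plus a manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(config)
    write_pedigree(data["pedigree"], outdir / "pedigree.tsv", header=f"seed={config.seed}")
    data["records"].to_csv(outdir / "phenotypes.csv", index=False)
    write_vcf(data["genotypes"], outdir / "genotypes.vcf", extra_header=[f"tempgenSeed={config.seed}"])
    data["truth"].to_json(outdir / "truth.json")
    data["scores"].to_csv(outdir / "factor_scores.csv")
    data["labels"].to_csv(outdir / "labels.csv")
    data["refusal"].to_csv(outdir / "refusal.csv", index=False)
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "files": [
            "pedigree.tsv",
            "phenotypes.csv",
            "genotypes.vcf",
            "truth.json",
            "factor_scores.csv",
            "labels.csv",
            "refusal.csv",
        ],
        "n_animals": int(data["pedigree"].n),
        "n_snvs": int(data["genotypes"].n_variants),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return data
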
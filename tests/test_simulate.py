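"""Synthetic colony generator: structure, Mendelian rules, ground truth."""

import numpy as np
import pandas as pd
import pytest

import tempgen as tg
from tempgen.pedigree import PedigreeError, numerator_relationship_matrix
from tempgen.simulate import _breeding_values


class TestPedigreeSimulation:
    def test_nuclear_family_forced_by_construction(self):
        cfg = tg.SimConfig(n_founders=2, n_generations=1, mean_offspring=2.0,
                           n_snvs=10, seed=1)
        ped = tg.simulate_pedigree(cfg)
        assert ped.n == 4
        for i in range(2, 4):
            assert ped.sire[i] == 0 and ped.dam[i] == 1

    def test_zero_generations_founders_only(self):
        cfg = tg.SimConfig(n_founders=8, n_generations=0, n_snvs=10, seed=1)
        ped = tg.simulate_pedigree(cfg)
        assert ped.n == 8
        assert ped.is_founder.all()

    def test_seed_determinism(self):
        cfg = tg.SimConfig(n_founders=20, n_generations=3, mean_offspring=2.5,
                           n_snvs=10, seed=7)
        p1 = tg.simulate_pedigree(cfg)
        p2 = tg.simulate_pedigree(cfg)
        pd.testing.assert_frame_equal(p1.to_frame(), p2.to_frame())

    def test_single_founder_rejected(self):
        with pytest.raises(ValueError, match="at least 2 founders"):
            tg.SimConfig(n_founders=1)

    def test_single_sex_generation_fails_loudly(self):
        # one offspring in generation 1 cannot breed generation 2
        cfg = tg.SimConfig(n_founders=2, n_generations=2, mean_offspring=1.0,
                           n_snvs=10, seed=1)
        with pytest.raises(PedigreeError, match="lacks one sex"):
            tg.simulate_pedigree(cfg)

    def test_no_full_sib_matings_by_default(self, small_dataset):
        ped = small_dataset["pedigree"]
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s >= 0 and d >= 0 and ped.sire[s] >= 0 and ped.sire[d] >= 0:
                assert not (
                    ped.sire[s] == ped.sire[d] and ped.dam[s] == ped.dam[d]
                ), f"offspring {ped.ids[i]} comes from a full-sib mating"


class TestGeneDrop:
    def test_mendelian_consistency_all_trios(self, small_dataset):
        """Offspring dosage is always attainable from the parents' genotypes."""
        ped = small_dataset["pedigree"]
        dos = small_dataset["genotypes"].dosage
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s < 0 or d < 0:
                continue
            lo = (dos[s] == 2).astype(int) + (dos[d] == 2).astype(int)
            hi = 2 - (dos[s] == 0).astype(int) - (dos[d] == 0).astype(int)
            assert (dos[i] >= lo).all() and (dos[i] <= hi).all()

    def test_parent_offspring_dosage_correlation_half(self):
        cfg = tg.SimConfig(n_founders=2, n_generations=1, mean_offspring=2.0,
                           n_snvs=20_000, maf_range=(0.5, 0.5), seed=5)
        ped = tg.simulate_pedigree(cfg)
        gm, _ = tg.gene_drop_genotypes(ped, cfg)
        r = np.corrcoef(gm.dosage[0], gm.dosage[2])[0, 1]
        assert r == pytest.approx(0.5, abs=0.03)

    def test_allele_frequency_conserved_down_pedigree(self):
        cfg = tg.SimConfig(n_founders=30, n_generations=3, mean_offspring=2.6,
                           n_snvs=5000, seed=9)
        ped = tg.simulate_pedigree(cfg)
        gm, p = tg.gene_drop_genotypes(ped, cfg)
        founders = ped.is_founder
        f_founder = gm.dosage[founders].mean(axis=0) / 2
        f_last = gm.dosage[ped.generation == ped.generation.max()].mean(axis=0) / 2
        # no selection: mean frequency drift across loci averages out
        assert abs(f_founder.mean() - f_last.mean()) < 0.01
        assert abs(f_founder.mean() - p.mean()) < 0.01


class TestPhenotypes:
    def test_determinism(self, small_config):
        d1 = tg.simulate_dataset(small_config)
        d2 = tg.simulate_dataset(small_config)
        pd.testing.assert_frame_equal(d1["records"], d2["records"])
        assert np.array_equal(d1["genotypes"].dosage, d2["genotypes"].dosage)
        pd.testing.assert_frame_equal(d1["refusal"], d2["refusal"])

    def test_no_heritability_means_zero_breeding_values(self):
        cfg = tg.SimConfig(n_founders=20, n_generations=2, mean_offspring=2.5,
                           h2_activity=0.0, h2_emotionality=0.0, n_snvs=10, seed=3)
        ped = tg.simulate_pedigree(cfg)
        _, truth = tg.simulate_phenotypes(ped, cfg)
        assert np.allclose(truth.breeding_values.to_numpy(), 0.0)

    def test_perfect_genetic_correlation_degenerate(self):
        cfg = tg.SimConfig(n_founders=20, n_generations=2, mean_offspring=2.5,
                           h2_activity=0.4, h2_emotionality=0.4, rho_g_true=1.0,
                           n_snvs=10, seed=3)
        ped = tg.simulate_pedigree(cfg)
        _, truth = tg.simulate_phenotypes(ped, cfg)
        bv = truth.breeding_values
        r = np.corrcoef(bv["activity"], bv["emotionality"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_breeding_value_covariance_matches_A(self):
        """Empirical covariance of replicate breeding values is h2 * A."""
        cfg = tg.SimConfig(n_founders=6, n_generations=2, mean_offspring=2.0,
                           h2_activity=0.4, h2_emotionality=0.4, rho_g_true=0.0,
                           n_snvs=10, seed=21)
        ped = tg.simulate_pedigree(cfg)
        assert ped.n <= 20
        A = numerator_relationship_matrix(ped)
        rng = np.random.default_rng(99)
        reps = 600
        draws = np.stack([_breeding_values(A, cfg, rng)[:, 0] for _ in range(reps)])
        emp = draws.T @ draws / reps
        target = cfg.h2_activity * A
        # per-entry Monte-Carlo SD of a covariance estimate
        mc_sd = cfg.h2_activity * np.sqrt(
            (np.outer(np.diag(A), np.diag(A)) + A**2) / reps
        )
        assert (np.abs(emp - target) < 5 * mc_sd + 1e-12).all()

    def test_realized_h2_definition(self, small_dataset):
        truth = small_dataset["truth"]
        bv = truth.breeding_values["activity"].to_numpy()
        lat = truth.latent["activity_d1"].to_numpy()
        expect = bv.var() / lat.var()
        assert truth.realized_h2["activity_d1"] == pytest.approx(expect)

    def test_rare_items_are_rare_binary(self, small_dataset):
        rec = small_dataset["records"]
        for item in ("ate_food", "crouching", "threats"):
            vals = rec[item].unique()
            assert set(vals) <= {0, 1}
            assert rec[item].mean() < 0.25


class TestRefusal:
    def test_null_rate_matches_intercept(self):
        cfg = tg.SimConfig(refusal_intercept=-1.0, beta_it=0.0, beta_age=0.0,
                           persistence=1.0, seed=2)
        labels = pd.DataFrame({"inhibited": [True, False] * 2500},
                              index=[f"a{i}" for i in range(5000)])
        out = tg.simulate_refusal(labels, np.full(5000, 5.0), cfg)
        from scipy.special import expit

        assert out["first_trial_refused"].mean() == pytest.approx(
            expit(-1.0), abs=0.02
        )

    def test_huge_it_effect_all_inhibited_refuse(self):
        cfg = tg.SimConfig(refusal_intercept=-2.0, beta_it=50.0, beta_age=0.0,
                           seed=2)
        labels = pd.DataFrame({"inhibited": [True] * 200 + [False] * 200},
                              index=[f"a{i}" for i in range(400)])
        out = tg.simulate_refusal(labels, np.full(400, 5.0), cfg)
        assert out.loc[out["animal"].isin(labels.index[:200]),
                       "first_trial_refused"].all()

    def test_logistic_coefficient_recovered(self):
        """Fitting the generating model recovers beta_it within 2 SE."""
        cfg = tg.SimConfig(refusal_intercept=-1.0, beta_it=1.0, beta_age=-0.25,
                           seed=8)
        n = 5000
        rng = np.random.default_rng(8)
        labels = pd.DataFrame({"inhibited": rng.random(n) < 0.3},
                              index=[f"a{i}" for i in range(n)])
        ages = rng.uniform(2, 10, n)
        out = tg.simulate_refusal(labels, ages, cfg, rng)
        design = pd.DataFrame(
            {"inhibited": labels["inhibited"].astype(float).to_numpy(), "age": ages}
        )
        fit = tg.fit_logistic(out["first_trial_refused"].astype(int), design)
        it = fit["inhibited"]
        assert abs(it["coef"] - 1.0) < 2 * it["se"]
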
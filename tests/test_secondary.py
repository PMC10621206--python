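import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import snpsig as sg
from snpsig.mining import MEMBER, match_signature

from conftest import cohort_from_bools


def confounded_dataset(seed):
    """Two diverged populations, disease driven by population, one signature
    whose carriers concentrate in the high-risk population."""
    cfg = sg.SimulationConfig(
        n_samples=2000, n_snps=30, planted=(), missing_rate=0.0,
        populations=((0.5, 0.05), (0.5, 0.05)),
        population_odds=(0.15, 0.6),
        forced_freqs={0: (0.05, 0.5)},
        random_seed=seed,
    )
    ds = sg.simulate_dataset(cfg, with_symptoms=False)
    membership = match_signature(ds.matrix, [("snp00000", 1)]) == MEMBER
    return ds, membership


def balanced_dataset(seed):
    cfg = sg.SimulationConfig(
        n_samples=2000, n_snps=30, missing_rate=0.0,
        planted=(sg.PlantedSignature(features=((2, 1), (3, 1)), odds_multiplier=4.0),),
        populations=((0.5, 0.05), (0.5, 0.05)),
        population_odds=(0.2, 0.2),
        random_seed=seed,
    )
    ds = sg.simulate_dataset(cfg, with_symptoms=False)
    membership = match_signature(ds.matrix, [("snp00002", 1), ("snp00003", 1)]) == MEMBER
    return ds, membership


class TestConfounderCheck:
    def test_ancestry_driven_signature_fails(self):
        ds, membership = confounded_dataset(0)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        (res,) = sg.ancestry_confounder_check(
            {"s": membership}, cohort, ds.ancestry, ds.matrix.sample_ids
        )
        assert res.verdict == "fail"

    def test_balanced_true_signature_passes(self):
        ds, membership = balanced_dataset(1)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        (res,) = sg.ancestry_confounder_check(
            {"s": membership}, cohort, ds.ancestry, ds.matrix.sample_ids
        )
        assert res.verdict == "pass"

    def test_constant_ancestry_reduces_to_unadjusted_test(self):
        ds, membership = balanced_dataset(2)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        constant = pd.Series(0.0, index=ds.matrix.sample_ids)
        (res,) = sg.ancestry_confounder_check(
            {"s": membership}, cohort, constant, ds.matrix.sample_ids
        )
        cc = sorted(cohort.cases + cohort.controls)
        pos = {s: i for i, s in enumerate(ds.matrix.sample_ids)}
        y = (cohort.labels.reindex(cc) == "case").to_numpy(dtype=float)
        x = membership[[pos[s] for s in cc]].astype(float)
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert res.membership_p == pytest.approx(float(fit.pvalues[1]), rel=0.05, abs=1e-6)

    def test_bonferroni_dominates_raw(self):
        ds, membership = balanced_dataset(3)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        other = np.roll(membership, 7)
        results = sg.ancestry_confounder_check(
            {"a": membership, "b": other}, cohort, ds.ancestry, ds.matrix.sample_ids
        )
        for r in results:
            assert r.adjusted_p >= r.membership_p - 1e-12


class TestPhenotypeEnrichment:
    def test_identical_groups_null(self):
        # identical flag proportions in carriers and non-carriers
        phen = pd.DataFrame({"flag": [1, 0] * 10 + [1, 0] * 10})
        carriers = np.array([True] * 20 + [False] * 20)
        res = sg.phenotype_enrichment(carriers, phen, {"flag": "categorical"})
        assert res[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert res[0].raw_p == pytest.approx(1.0)

    def test_two_proportion_hand_formula(self):
        phen = pd.DataFrame({"flag": [1] * 30 + [0] * 70 + [1] * 10 + [0] * 90})
        carriers = np.array([True] * 100 + [False] * 100)
        (res,) = sg.phenotype_enrichment(carriers, phen, {"flag": "categorical"})
        assert res.statistic == pytest.approx(3.5355, abs=1e-3)
        assert res.direction == "up"

    def test_shifted_continuous_phenotype_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            carriers = np.zeros(200, dtype=bool)
            carriers[:60] = True
            values = rng.normal(0, 1, 200)
            values[carriers] += 1.0
            phen = pd.DataFrame({"score": values})
            (res,) = sg.phenotype_enrichment(carriers, phen, {"score": "continuous"})
            hits += res.adjusted_p < 0.05
        assert hits >= 18

    def test_small_group_flagged_underpowered(self):
        phen = pd.DataFrame({"score": np.arange(20.0)})
        carriers = np.zeros(20, dtype=bool)
        carriers[:3] = True
        (res,) = sg.phenotype_enrichment(carriers, phen, {"score": "continuous"})
        assert res.underpowered


class TestSeededMine:
    def test_seeding_with_all_snps_equals_unrestricted(self):
        cfg = sg.SimulationConfig(
            n_samples=600, n_snps=15, missing_rate=0.0,
            planted=(sg.PlantedSignature(features=((0, 1), (1, 1)), odds_multiplier=5.0),),
            random_seed=4,
        )
        ds = sg.simulate_dataset(cfg, with_symptoms=False)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        mcfg = sg.MiningConfig(max_order=2, beam_width=None, n_permutations=29, random_seed=4)
        full = sg.mine_signatures(ds.matrix, cohort, mcfg)
        seeded = sg.seeded_mine(ds.matrix, cohort, list(ds.matrix.snp_ids), mcfg)
        assert [(s.features, s.q_value) for s in full] == [(s.features, s.q_value) for s in seeded]

    def test_seeded_output_contains_a_seed_and_is_subset_of_full(self):
        cfg = sg.SimulationConfig(
            n_samples=600, n_snps=15, missing_rate=0.0,
            planted=(sg.PlantedSignature(features=((0, 1), (1, 1)), odds_multiplier=5.0),),
            random_seed=5,
        )
        ds = sg.simulate_dataset(cfg, with_symptoms=False)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        mcfg = sg.MiningConfig(max_order=2, beam_width=None, n_permutations=29, random_seed=5)
        seeded = sg.mine_candidates(ds.matrix, cohort, mcfg, seed_snps={"snp00000"})
        full = sg.mine_candidates(ds.matrix, cohort, mcfg)
        assert seeded
        assert all("snp00000" in s.snps for s in seeded)
        assert {s.features for s in seeded} <= {s.features for s in full}

    def test_missing_seeds_dropped_and_empty_seed_list_empty_result(self):
        cfg = sg.SimulationConfig(n_samples=300, n_snps=8, planted=(), random_seed=6)
        ds = sg.simulate_dataset(cfg, with_symptoms=False)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        mcfg = sg.MiningConfig(max_order=2, beam_width=None, n_permutations=29)
        assert sg.seeded_mine(ds.matrix, cohort, [], mcfg) == []
        assert sg.seeded_mine(ds.matrix, cohort, ["nope"], mcfg) == []

    def test_cross_cohort_recovery(self):
        """A signature planted in two independent cohorts is found in the
        second when seeded with the SNPs mined from the first."""
        planted = (sg.PlantedSignature(features=((0, 1), (1, 1)), odds_multiplier=5.0),)
        mcfg = sg.MiningConfig(max_order=2, beam_width=60, n_permutations=49, random_seed=0)
        hits = 0
        for seed in range(5):
            cfg_a = sg.SimulationConfig(n_samples=1000, n_snps=40, planted=planted,
                                        missing_rate=0.0, random_seed=100 + seed)
            cfg_b = sg.SimulationConfig(n_samples=1000, n_snps=40, planted=planted,
                                        missing_rate=0.0, random_seed=200 + seed)
            ds_a = sg.simulate_dataset(cfg_a, with_symptoms=False)
            ds_b = sg.simulate_dataset(cfg_b, with_symptoms=False)
            co_a = cohort_from_bools(ds_a.disease.to_numpy(), ds_a.matrix.sample_ids)
            co_b = cohort_from_bools(ds_b.disease.to_numpy(), ds_b.matrix.sample_ids)
            val_a = [s for s in sg.mine_signatures(ds_a.matrix, co_a, mcfg) if s.validated]
            seeds = sorted({snp for s in val_a for snp in s.snps})
            val_b = [s for s in sg.seeded_mine(ds_b.matrix, co_b, seeds, mcfg) if s.validated]
            hits += sg.recovery_fraction(ds_b.truth, val_b) == 1.0
        assert hits >= 4
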
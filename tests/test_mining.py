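import itertools

import numpy as np
import pytest
from scipy.stats import fisher_exact, kstest

import snpsig as sg
from snpsig.errors import ValidationError
from snpsig.matrix import MISSING
from snpsig.mining import INCOMPLETE, MEMBER, NON_MEMBER

from conftest import cohort_from_bools, make_matrix


class TestMatchSignature:
    def test_empty_feature_set_matches_everyone(self, tiny_matrix):
        assert (sg.match_signature(tiny_matrix, []) == MEMBER).all()

    def test_single_feature_lookup(self):
        m = make_matrix([[0], [1], [1], [2], [MISSING]], snp_ids=["snpX"])
        memb = sg.match_signature(m, [("snpX", 1)])
        assert memb.tolist() == [NON_MEMBER, MEMBER, MEMBER, NON_MEMBER, INCOMPLETE]

    def test_conjunction_monotonicity(self, tiny_matrix):
        small = sg.match_signature(tiny_matrix, [("snp0", 1)])
        big = sg.match_signature(tiny_matrix, [("snp0", 1), ("snp1", 1)])
        assert ((big == MEMBER) <= (small == MEMBER)).all()

    def test_duplicate_snp_rejected(self, tiny_matrix):
        with pytest.raises(ValidationError):
            sg.match_signature(tiny_matrix, [("snp0", 1), ("snp0", 2)])


class TestSignatureStats:
    @pytest.mark.parametrize(
        "case_count, control_count, expected_or",
        [
            (57, 23, 4.67),
            (396, 703, 1.06),
            (164, 226, 1.36),
            (141, 186, 1.43),
        ],
    )
    def test_published_severe_cohort_examples(self, case_count, control_count, expected_or):
        """Signature and component-SNP odds ratios of the worked example."""
        _, _, orr, _ = sg.signature_stats_from_counts(case_count, control_count, 459, 864)
        assert abs(orr - expected_or) <= 0.01

    def test_everyone_member_gives_unit_odds(self):
        m = make_matrix([[0]] * 10)
        cohort = cohort_from_bools([True] * 4 + [False] * 6, m.sample_ids)
        memb = sg.match_signature(m, [("snp0", 0)])
        a, b, orr, p = sg.signature_stats(memb, cohort, m.sample_ids)
        assert (a, b) == (4, 6)
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_incomplete_members_excluded_from_counts(self):
        m = make_matrix([[1], [1], [MISSING], [0]])
        cohort = cohort_from_bools([True, True, True, False], m.sample_ids)
        memb = sg.match_signature(m, [("snp0", 1)])
        a, b, _, _ = sg.signature_stats(memb, cohort, m.sample_ids)
        assert (a, b) == (2, 0)


def brute_force_mine(matrix, cohort, config):
    """Independent exhaustive oracle: every feature and feature pair, filtered
    with scipy's Fisher test on the same criteria the search applies."""
    A, B = cohort.n_cases, cohort.n_controls
    labels = cohort.labels.reindex(matrix.sample_ids).to_numpy()
    case = labels == "case"
    ctrl = labels == "control"
    found = {}
    combos = [((f,),) for f in range(1)]
    features = [(snp, st) for snp in matrix.snp_ids for st in (0, 1, 2)]
    for order in (1, 2):
        for feats in itertools.combinations(features, order):
            snps = {s for s, _ in feats}
            if len(snps) < order:
                continue
            member = np.ones(matrix.n_samples, dtype=bool)
            for snp, st in feats:
                member &= matrix.column(snp) == st
            a = int((member & case).sum())
            b = int((member & ctrl).sum())
            if a / A < config.min_case_prevalence:
                continue
            if b == 0:
                orr = ((a + 0.5) / 0.5) / (A / B)
            else:
                orr = (a / b) / (A / B)
            if orr <= 1.0:
                continue
            p = fisher_exact([[a, A - a], [b, B - b]])[1]
            if p >= config.alpha:
                continue
            found[frozenset(feats)] = (a, b, p)
    return found


class TestMineOracleEquivalence:
    def test_beam_equals_exhaustive_at_order_two(self):
        """Unlimited-beam layered search == brute-force enumeration (22 SNPs)."""
        cfg = sg.SimulationConfig(
            n_samples=300,
            n_snps=22,
            missing_rate=0.02,
            planted=(sg.PlantedSignature(features=((0, 1), (1, 1)), odds_multiplier=4.0),),
            random_seed=13,
        )
        ds = sg.simulate_dataset(cfg, with_symptoms=False)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        mcfg = sg.MiningConfig(max_order=2, beam_width=None, n_permutations=19)
        mined = sg.mine_candidates(ds.matrix, cohort, mcfg, dedup=False)
        oracle = brute_force_mine(ds.matrix, cohort, mcfg)
        assert {s.features for s in mined} == set(oracle)
        for s in mined:
            a, b, p = oracle[s.features]
            assert (s.case_count, s.control_count) == (a, b)
            assert s.p_value == pytest.approx(p, rel=1e-8)

    def test_column_and_sample_order_invariance(self):
        cfg = sg.SimulationConfig(n_samples=200, n_snps=12, missing_rate=0.0,
                                  planted=(), random_seed=3)
        ds = sg.simulate_dataset(cfg, with_symptoms=False)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        mcfg = sg.MiningConfig(max_order=2, beam_width=None, n_permutations=19)
        base = sg.mine_candidates(ds.matrix, cohort, mcfg)
        rng = np.random.default_rng(0)
        shuffled = ds.matrix.subset(
            samples=rng.permutation(ds.matrix.n_samples),
            snps=rng.permutation(ds.matrix.n_snps),
        )
        again = sg.mine_candidates(shuffled, cohort, mcfg)
        assert [(s.features, s.case_count) for s in base] == [
            (s.features, s.case_count) for s in again
        ]

    def test_dedup_collapses_redundant_superset(self):
        # snp1 state 1 occurs only alongside snp0 state 1 -> identical membership
        states = [[1, 1], [1, 1], [1, 1], [0, 0], [0, 0], [0, 2], [2, 0], [0, 0]] * 4
        m = make_matrix(states)
        cohort = cohort_from_bools([True, True, True, False] * 8, m.sample_ids)
        mcfg = sg.MiningConfig(max_order=2, beam_width=None, n_permutations=19)
        mined = sg.mine_candidates(m, cohort, mcfg)
        featsets = {s.features for s in mined}
        assert frozenset({("snp0", 1), ("snp1", 1)}) not in featsets


class TestPermutationFdr:
    def test_vacuous_candidate_has_empirical_p_one(self):
        m = make_matrix([[0]] * 20)
        cohort = cohort_from_bools([True] * 8 + [False] * 12, m.sample_ids)
        out = sg.permutation_fdr(m, cohort, [[("snp0", 0)]], n_permutations=49, seed=0)
        assert out["empirical_p"].iloc[0] == pytest.approx(1.0)

    def test_single_candidate_q_equals_empirical_p(self):
        rng = np.random.default_rng(5)
        states = rng.choice([0, 1], size=(60, 1), p=[0.5, 0.5])
        m = make_matrix(states)
        case = (states[:, 0] == 1) | (rng.random(60) < 0.2)
        cohort = cohort_from_bools(case, m.sample_ids)
        out = sg.permutation_fdr(m, cohort, [[("snp0", 1)]], n_permutations=99, seed=1)
        assert out["q_value"].iloc[0] == pytest.approx(out["empirical_p"].iloc[0])

    def test_too_few_permutations_rejected(self, tiny_matrix):
        cohort = cohort_from_bools([True, False, True, False, True, False], tiny_matrix.sample_ids)
        with pytest.raises(ValueError):
            sg.permutation_fdr(tiny_matrix, cohort, [[("snp0", 1)]], n_permutations=10)


class TestSingleSnpAssociation:
    def test_null_pvalues_roughly_uniform(self):
        cfg = sg.SimulationConfig(n_samples=600, n_snps=300, missing_rate=0.0,
                                  planted=(), baseline_odds=0.5, random_seed=8)
        ds = sg.simulate_dataset(cfg, with_symptoms=False)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        table = sg.single_snp_association(ds.matrix, cohort)
        # Fisher p-values are discrete and conservative; KS should still not
        # reject uniformity outright on null data
        assert kstest(table["p"], "uniform").pvalue > 0.01
        assert not table["genome_wide_significant"].any()

    def test_perfect_separator_reaches_genome_wide_significance(self):
        states = [[2]] * 50 + [[0]] * 50
        m = make_matrix(states)
        cohort = cohort_from_bools([True] * 50 + [False] * 50, m.sample_ids)
        table = sg.single_snp_association(m, cohort)
        assert table["p"].iloc[0] < 1e-20
        assert bool(table["genome_wide_significant"].iloc[0])

    def test_monomorphic_snp_p_is_one(self):
        m = make_matrix([[0]] * 10)
        cohort = cohort_from_bools([True] * 5 + [False] * 5, m.sample_ids)
        assert sg.single_snp_association(m, cohort)["p"].iloc[0] == 1.0


class TestMineSignaturesSmall:
    def test_planted_pair_recovered_and_validated(self):
        cfg = sg.SimulationConfig(
            n_samples=1000, n_snps=40, missing_rate=0.01,
            planted=(sg.PlantedSignature(features=((0, 1), (1, 1)), odds_multiplier=6.0),),
            random_seed=2,
        )
        ds = sg.simulate_dataset(cfg, with_symptoms=False)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        mcfg = sg.MiningConfig(max_order=2, beam_width=60, n_permutations=49, random_seed=2)
        sigs = sg.mine_signatures(ds.matrix, cohort, mcfg)
        validated = [s for s in sigs if s.validated]
        assert sg.recovery_fraction(ds.truth, validated) == 1.0

    def test_deterministic_given_seed(self):
        cfg = sg.SimulationConfig(n_samples=400, n_snps=20, planted=(), random_seed=1)
        ds = sg.simulate_dataset(cfg, with_symptoms=False)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        mcfg = sg.MiningConfig(max_order=2, beam_width=30, n_permutations=29, random_seed=7)
        a = sg.mine_signatures(ds.matrix, cohort, mcfg)
        b = sg.mine_signatures(ds.matrix, cohort, mcfg)
        assert [(s.features, s.q_value) for s in a] == [(s.features, s.q_value) for s in b]
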
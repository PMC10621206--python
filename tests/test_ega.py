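import math

import numpy as np
import pytest

import snpsig as sg
from snpsig.ega import EgaBlock, n_expanded
from snpsig.errors import UnsupportedOrderError, ValidationError

from conftest import cohort_from_bools, make_matrix


def block(wt, var, interacting, critical_state=1):
    """Convenience: build an EgaBlock from (cases, controls) tuples."""
    complete = min(*wt, *var) > 0 and sum(wt) >= 15 and sum(var) >= 15
    return EgaBlock(
        critical_snp="crit",
        critical_state=critical_state,
        interacting=interacting,
        variant_cases=var[0],
        variant_controls=var[1],
        wt_cases=wt[0],
        wt_controls=wt[1],
        complete=complete,
    )


class TestEnumeration:
    @pytest.mark.parametrize("k, expected", [(1, 3), (2, 9), (3, 27), (4, 81), (5, 243)])
    def test_cell_count_arithmetic(self, k, expected):
        assert n_expanded(k) == expected

    @pytest.mark.parametrize("k", [2, 3])
    def test_enumerate_yields_all_cells(self, k):
        cfg = sg.SimulationConfig(n_samples=400, n_snps=5, missing_rate=0.05,
                                  planted=(), random_seed=1)
        ds = sg.simulate_dataset(cfg, with_symptoms=False)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        snps = ds.matrix.snp_ids[:k]
        expanded = sg.enumerate_expanded(ds.matrix, cohort, snps)
        assert len(expanded) == 3**k
        # counts partition the complete-genotype case/control samples
        cc = sorted(cohort.cases + cohort.controls)
        rows = [ds.matrix.sample_ids.index(s) for s in cc]
        cols = [ds.matrix.snp_index(s) for s in snps]
        complete = (ds.matrix.states[np.ix_(rows, cols)] != sg.MISSING).all(axis=1)
        assert sum(e.total for e in expanded) == int(complete.sum())

    @pytest.mark.parametrize("k", [4, 5])
    def test_high_order_rejected(self, k):
        cfg = sg.SimulationConfig(n_samples=100, n_snps=6, planted=(), random_seed=0)
        ds = sg.simulate_dataset(cfg, with_symptoms=False)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        with pytest.raises(UnsupportedOrderError):
            sg.enumerate_expanded(ds.matrix, cohort, ds.matrix.snp_ids[:k])


class TestEgaOddsRatios:
    def test_published_wild_type_block(self):
        """Heterozygous 17:19 vs wild type 74:160 -> OR 1.93, CI (0.95, 3.93)."""
        orr, (lo, hi) = sg.ega_odds_ratio(17, 19, 74, 160)
        assert abs(orr - 1.93) <= 0.01
        assert abs(lo - 0.95) <= 0.01
        assert abs(hi - 3.93) <= 0.01

    @pytest.mark.parametrize(
        "var, wt, expected",
        [((7, 10), (57, 23), 0.28), ((6, 28), (71, 108), 0.33)],
    )
    def test_published_minor_allele_blocks(self, var, wt, expected):
        orr, _ = sg.ega_odds_ratio(*var, *wt)
        assert abs(orr - expected) <= 0.01

    def test_equal_odds_give_unit_ratio(self):
        orr, _ = sg.ega_odds_ratio(20, 40, 10, 20)
        assert orr == pytest.approx(1.0)

    def test_zero_cell_is_nan_no_continuity_correction(self):
        orr, _ = sg.ega_odds_ratio(0, 10, 20, 30)
        assert math.isnan(orr)

    def test_block_ratio_is_exactly_variant_over_wt(self):
        b = block(wt=(30, 60), var=(25, 20), interacting=(("p1", 0),))
        assert b.ega_odds_ratio == pytest.approx(b.variant_odds / b.wt_odds)
        lo, hi = b.ci95
        assert lo < b.ega_odds_ratio < hi


class TestBlocks:
    def test_blocks_group_by_interacting_assignment(self):
        cfg = sg.SimulationConfig(n_samples=2000, n_snps=4, missing_rate=0.0,
                                  planted=(), baseline_odds=0.5, random_seed=6)
        ds = sg.simulate_dataset(cfg, with_symptoms=False)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        snps = ds.matrix.snp_ids[:2]
        expanded = sg.enumerate_expanded(ds.matrix, cohort, snps)
        blocks = sg.ega_blocks(expanded, snps[0])
        # 3 interacting states x up to 2 critical comparisons each
        assert 1 <= len(blocks) <= 6
        for b in blocks:
            assert b.critical_snp == snps[0]
            assert len(b.interacting) == 1

    def test_critical_snp_must_belong_to_signature(self):
        cfg = sg.SimulationConfig(n_samples=200, n_snps=4, planted=(), random_seed=0)
        ds = sg.simulate_dataset(cfg, with_symptoms=False)
        cohort = cohort_from_bools(ds.disease.to_numpy(), ds.matrix.sample_ids)
        expanded = sg.enumerate_expanded(ds.matrix, cohort, ds.matrix.snp_ids[:2])
        with pytest.raises(ValidationError):
            sg.ega_blocks(expanded, ds.matrix.snp_ids[3])


class TestClassification:
    def test_all_protective_is_universal(self):
        blocks = [
            block((40, 40), (10, 25), (("p1", 0),)),
            block((30, 20), (8, 12), (("p1", 1),)),
            block((25, 25), (9, 20), (("p1", 2),)),
        ]
        assert sg.classify_ega(blocks).category == "universally_protective"

    def test_published_two_interactor_pattern_is_snp_specific_protective(self):
        """Risk only where both interacting SNPs are wild type; protection
        wherever either interacting SNP carries a minor allele."""
        blocks = [
            block((74, 160), (17, 19), (("k", 0), ("r", 0))),
            block((57, 23), (7, 10), (("k", 0), ("r", 1))),
            block((114, 267), (14, 50), (("k", 1), ("r", 0))),
            block((48, 76), (6, 25), (("k", 1), ("r", 1))),
            block((71, 108), (6, 28), (("k", 2), ("r", 0))),
            block((17, 35), (3, 8), (("k", 2), ("r", 1))),
        ]
        out = sg.classify_ega(blocks)
        assert out.category == "snp_specific_protective"

    def test_alternating_directions_are_ambiguous(self):
        blocks = [
            block((40, 40), (30, 10), (("p1", 0),)),
            block((30, 20), (8, 30), (("p1", 1),)),
            block((25, 25), (30, 8), (("p1", 2),)),
        ]
        assert sg.classify_ega(blocks).category == "ambiguous"

    def test_single_causative_cell_is_combination_specific(self):
        # risk confined to the (p1=1, p2=1) interacting assignment; the minor
        # allele of either interacting SNP alone does not flip the direction
        blocks = [
            block((25, 25), (7, 22), (("p1", 0), ("p2", 0))),
            block((30, 30), (8, 25), (("p1", 1), ("p2", 0))),
            block((28, 28), (9, 24), (("p1", 0), ("p2", 1))),
            block((40, 40), (35, 8), (("p1", 1), ("p2", 1))),
        ]
        assert sg.classify_ega(blocks).category == "combination_specific_causative"

    def test_insufficient_blocks_flagged(self):
        out = sg.classify_ega([block((40, 40), (10, 25), (("p1", 0),))])
        assert out.category == "ambiguous"
        assert out.insufficient_data

    def test_invariant_to_block_order(self):
        blocks = [
            block((74, 160), (17, 19), (("k", 0), ("r", 0))),
            block((57, 23), (7, 10), (("k", 0), ("r", 1))),
            block((114, 267), (14, 50), (("k", 1), ("r", 0))),
        ]
        a = sg.classify_ega(blocks).category
        b = sg.classify_ega(blocks[::-1]).category
        assert a == b


class TestPooledAlleleTest:
    def test_published_pooled_protective_or(self):
        assert abs(sg.odds_ratio_2x2(41, 134, 316, 532) - 0.52) <= 0.01

    def test_published_wild_type_stratum_or(self):
        assert abs(sg.odds_ratio_2x2(19, 22, 74, 160) - 1.86) <= 0.01

    def test_no_effect_gives_unit_or_and_p_one(self):
        # carriers and wild type with identical odds
        states = [[1]] * 20 + [[0]] * 40
        case = [True] * 10 + [False] * 10 + [True] * 20 + [False] * 20
        m = make_matrix(states)
        cohort = cohort_from_bools(case, m.sample_ids)
        orr, p = sg.pooled_allele_test(m, cohort, "snp0")
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_stratum_restriction(self):
        states = [[1, 0]] * 10 + [[0, 0]] * 20 + [[1, 1]] * 10 + [[0, 1]] * 20
        case = ([True] * 8 + [False] * 2) + ([True] * 5 + [False] * 15) + [True] * 2 + [False] * 8 + [True] * 5 + [False] * 15
        m = make_matrix(states)
        cohort = cohort_from_bools(case, m.sample_ids)
        orr_all, _ = sg.pooled_allele_test(m, cohort, "snp0")
        orr_wt, _ = sg.pooled_allele_test(m, cohort, "snp0", stratum={"snp1": (0,)})
        assert orr_wt == pytest.approx((8 / 2) / (5 / 15))
        assert orr_all != pytest.approx(orr_wt)

    def test_empty_stratum_raises(self, tiny_matrix):
        cohort = cohort_from_bools([True, False, True, False, True, False], tiny_matrix.sample_ids)
        with pytest.raises(ValidationError):
            sg.pooled_allele_test(tiny_matrix, cohort, "snp0", stratum={"snp1": (99,)})
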
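import math
from fractions import Fraction

import numpy as np
import pytest

from turtur.datatypes import SNPDataset
from turtur.sumstats import (
    NoSegregationError,
    fus_fs,
    gene_diversity,
    mtdna_basic_stats,
    mtdna_stats,
    neutrality_significance,
    snp_summary_stats,
    tajimas_d,
)
from turtur.synthetic_data import make_toy_alignment


class TestGeneDiversity:
    def test_monomorphic_locus_is_zero(self):
        assert gene_diversity(np.array([0, 0, 0])) == 0.0

    def test_single_heterozygote(self):
        # n = 2 copies, p = 0.5: (2/1)(1 - 0.5) = 1
        assert gene_diversity(np.array([1])) == pytest.approx(1.0)

    def test_three_genotype_example(self):
        # doses (0, 1, 2): n = 6, p = 0.5: (6/5)(1 - 0.5) = 0.6
        assert gene_diversity(np.array([0, 1, 2])) == pytest.approx(0.6)

    def test_missing_copies_excluded(self):
        assert gene_diversity(np.array([0, 1, 2, -1])) == pytest.approx(0.6)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            gene_diversity(np.array([-1, -1]))


class TestSnpSummaryStats:
    def build(self):
        # locus diversities by hand: 0 (monomorphic), 0.5 (n=4, p=1/4), 1.0 (n=2, het)
        g = np.array([[0, 0, 1], [0, 1, -1]], dtype=np.int8)
        return SNPDataset(genotypes=g)

    def test_hand_computed_aggregation(self):
        stats = snp_summary_stats(self.build())
        assert stats.prop_monomorphic == pytest.approx(1 / 3)
        assert stats.mean_gd_poly == pytest.approx(0.75)
        assert stats.var_gd_poly == pytest.approx(0.125)  # unbiased over {0.5, 1.0}
        assert stats.mean_gd_all == pytest.approx(0.5)

    def test_invariant_to_row_and_locus_order(self, rng):
        g = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        g[rng.random(g.shape) < 0.1] = -1
        base = snp_summary_stats(SNPDataset(genotypes=g))
        shuffled = SNPDataset(
            genotypes=g[rng.permutation(12)][:, rng.permutation(40)]
        )
        assert snp_summary_stats(shuffled).as_array() == pytest.approx(base.as_array())

    def test_all_monomorphic_is_degenerate(self):
        g = np.zeros((4, 5), dtype=np.int8)
        stats = snp_summary_stats(SNPDataset(genotypes=g))
        assert stats.degenerate
        assert stats.prop_monomorphic == 1.0
        assert math.isnan(stats.mean_gd_poly)
        assert stats.mean_gd_all == 0.0


class TestMtdnaStats:
    def test_identical_pair(self):
        stats = mtdna_basic_stats(make_toy_alignment("identical_pair"))
        assert (stats.S, stats.n_haplotypes, stats.Hd, stats.pi) == (0, 1, 0.0, 0.0)

    def test_two_haplotypes_among_four(self):
        # 2+2 split differing at 1 of 100 sites: Hd = (4/3)(1 - 1/2) = 2/3,
        # pi_total = 4 discordant pairs / 6 pairs = 2/3, pi = (2/3)/100
        stats = mtdna_basic_stats(make_toy_alignment("two_haplotypes_4seq"))
        assert stats.S == 1
        assert stats.n_haplotypes == 2
        assert stats.Hd == pytest.approx(2 / 3)
        assert stats.pi_total == pytest.approx(2 / 3)
        assert stats.pi == pytest.approx(2 / 300)

    def test_complete_deletion_drops_ambiguous_columns(self):
        from turtur.datatypes import HaplotypeAlignment

        aln = HaplotypeAlignment(sequences=["ACGTN", "ACCT-", "ACCTA"])
        stats = mtdna_basic_stats(aln)
        assert stats.retained_length == 4
        assert stats.S == 1

    def test_pairwise_deletion_keeps_sites(self):
        from turtur.datatypes import HaplotypeAlignment

        aln = HaplotypeAlignment(sequences=["ACGTA", "ACCTN"])
        stats = mtdna_basic_stats(aln, deletion="pairwise")
        assert stats.pi == pytest.approx(1 / 4)


def _tajima_oracle(S: int, n: int, pi_total: float) -> float:
    """Exact-rational evaluation of the defining formula."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_total - S / a1) / math.sqrt(float(var)))


class TestTajimasD:
    def test_zero_when_pi_equals_watterson(self):
        n = 10
        a1 = sum(1.0 / i for i in range(1, n))
        assert tajimas_d(5, n, 5 / a1) == pytest.approx(0.0)

    @pytest.mark.parametrize("n,S,pi", [(10, 16, 3.888), (25, 40, 9.1), (95, 73, 6.7)])
    def test_matches_exact_arithmetic_oracle(self, n, S, pi):
        assert tajimas_d(S, n, pi) == pytest.approx(_tajima_oracle(S, n, pi), abs=1e-12)

    def test_fixture_alignment_matches_oracle(self):
        stats = mtdna_basic_stats(make_toy_alignment("tajima_n10"))
        assert stats.S >= 1
        expected = _tajima_oracle(stats.S, 10, stats.pi_total)
        assert tajimas_d(stats.S, 10, stats.pi_total) == pytest.approx(expected, abs=1e-12)

    def test_no_segregation_raises(self):
        with pytest.raises(NoSegregationError):
            tajimas_d(0, 10, 0.0)


class TestFusFs:
    def test_k_obs_one_is_plus_infinity_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert fus_fs(10, 1, 2.0) == math.inf

    def test_small_case_against_exact_stirling(self):
        # n=5, theta=1: |s(5,k)| = 24, 50, 35, 10, 1; rising factorial = 120
        # P(K >= 3) = (35 + 10 + 1)/120, P(K < 3) = (24 + 50)/120
        expected = math.log(46 / 74)
        assert fus_fs(5, 3, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            fus_fs(1, 1, 1.0)
        with pytest.raises(ValueError):
            fus_fs(5, 6, 1.0)
        with pytest.raises(ValueError):
            fus_fs(5, 3, 0.0)


class TestNeutralitySignificance:
    def test_reproducible_under_fixed_seed(self, scenario4_demography):
        from turtur.coalescent_sim import simulate_mtdna_alignment

        aln = simulate_mtdna_alignment(20, 600, scenario4_demography,
                                       rng=np.random.default_rng(3))
        p1 = neutrality_significance(aln, "D", 200, np.random.default_rng(4))
        p2 = neutrality_significance(aln, "D", 200, np.random.default_rng(4))
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_warns_on_few_replicates(self, scenario4_demography):
        from turtur.coalescent_sim import simulate_mtdna_alignment

        aln = simulate_mtdna_alignment(12, 600, scenario4_demography,
                                       rng=np.random.default_rng(6))
        with pytest.warns(UserWarning, match="fewer than 100"):
            neutrality_significance(aln, "Fs", 50, np.random.default_rng(0))

    def test_constant_size_alignment_is_not_extreme(self):
        """Data simulated under the null should not look like an expansion."""
        from turtur.coalescent_sim import simulate_mtdna_alignment
        from turtur.demographic_models import DemographicScenario

        big = DemographicScenario(scenario_id=1, epochs=((0.0, 1_000_000.0),))
        ps = []
        for seed in (101, 102, 103):
            aln = simulate_mtdna_alignment(25, 800, big,
                                           rng=np.random.default_rng(seed))
            ps.append(
                neutrality_significance(aln, "D", 300, np.random.default_rng(seed + 50))
            )
        assert np.median(ps) > 0.05
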
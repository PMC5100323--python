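import numpy as np
import pytest
from scipy.stats import kstest
from sklearn.metrics import silhouette_score

from turtur.datatypes import SNPDataset
from turtur.structure_analysis import (
    GroupingScheme,
    amova,
    pca_genotypes,
    weir_cockerham_fst,
)
from turtur.synthetic_data import make_structured_dataset, make_toy_alignment


def toy_scheme():
    aln = make_toy_alignment("six_haplotypes_two_groups")
    return aln, GroupingScheme.from_table(
        aln.ids, aln.populations, ["g1", "g1", "g1", "g2", "g2", "g2"]
    )


def brute_force_three_level(aln, pops, groups):
    """Independent sums-of-squares decomposition via explicit loops."""
    valid = np.isin(aln.sequences, np.frombuffer(b"ACGT", dtype=np.uint8)).all(axis=0)
    seqs = aln.sequences[:, valid]
    n = len(pops)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2[i, j] = np.sum(seqs[i] != seqs[j])

    def ss(idx):
        total = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                total += d2[idx[a], idx[b]]
        return total / len(idx)

    every = list(range(n))
    ss_total = ss(every)
    ss_g = sum(ss([i for i in every if groups[i] == g]) for g in sorted(set(groups)))
    ss_p = sum(ss([i for i in every if pops[i] == p]) for p in sorted(set(pops)))
    return ss_total - ss_g, ss_g - ss_p, ss_p


class TestAmovaToy:
    def test_matches_hand_computed_decomposition(self, rng):
        """All variation between two groups: among-group component is 100 %."""
        aln, scheme = toy_scheme()
        result = amova(aln, scheme, n_permutations=0, rng=rng)
        ssd_ag, ssd_ap, ssd_wp = brute_force_three_level(
            aln, np.array(aln.populations), np.array(["g1"] * 3 + ["g2"] * 3)
        )
        np.testing.assert_allclose(
            result.components["SS"].to_numpy(), [ssd_ag, ssd_ap, ssd_wp], atol=1e-9
        )
        # hand solution: MS = (6, 0, 0); sigma = (2, 0, 0)
        np.testing.assert_allclose(
            result.components["variance"].to_numpy(), [2.0, 0.0, 0.0], atol=1e-9
        )
        assert result.components["pct_variance"].iloc[0] == pytest.approx(100.0, abs=1e-9)
        assert result.components["pct_variance"].sum() == pytest.approx(100.0, abs=1e-6)
        assert result.phi["Phi_CT"] == pytest.approx(1.0)

    def test_identical_individuals_are_degenerate(self, rng):
        g = np.ones((8, 20), dtype=np.int8) * 2
        ds = SNPDataset(genotypes=g)
        scheme = GroupingScheme.from_table(
            ds.individual_ids,
            [f"p{i % 4}" for i in range(8)],
            [f"g{i % 2}" for i in range(8)],
        )
        result = amova(ds, scheme, n_permutations=10, rng=rng)
        assert result.degenerate
        assert np.allclose(result.components["variance"], 0.0)
        assert result.components["pct_variance"].isna().all()


@pytest.fixture(scope="module")
def structured():
    ds, _ = make_structured_dataset(
        n_pops=4, n_per_pop=12, n_loci=300, fst=0.08, seed=5,
        groups=["g1", "g1", "g2", "g2"],
    )
    scheme = GroupingScheme.from_table(ds.individual_ids, ds.populations, ds.groups)
    return ds, scheme


class TestAmovaFourLevel:
    def test_percentages_sum_and_phi_identity(self, structured, rng):
        ds, scheme = structured
        result = amova(ds, scheme, n_permutations=0, rng=rng)
        assert result.components["pct_variance"].sum() == pytest.approx(100.0, abs=1e-6)
        phi = result.phi
        lhs = 1 - phi["Phi_IT"]
        rhs = (1 - phi["Phi_CT"]) * (1 - phi["Phi_SC"]) * (1 - phi["Phi_IS"])
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_fully_differentiated_groups(self, rng):
        """Two fixed groups: all variance among groups, none within."""
        g = np.vstack([np.zeros((6, 30)), np.full((6, 30), 2)]).astype(np.int8)
        ds = SNPDataset(genotypes=g)
        scheme = GroupingScheme.from_table(
            ds.individual_ids,
            ["p1"] * 3 + ["p2"] * 3 + ["p3"] * 3 + ["p4"] * 3,
            ["g1"] * 6 + ["g2"] * 6,
        )
        result = amova(ds, scheme, n_permutations=0, rng=rng)
        assert result.components["pct_variance"].iloc[0] == pytest.approx(100.0)
        assert result.phi["Phi_IT"] == pytest.approx(1.0)

    def test_population_structure_is_detected(self, structured):
        ds, scheme = structured
        result = amova(ds, scheme, n_permutations=99,
                       rng=np.random.default_rng(1), permute=("Phi_SC",))
        # Balding-Nichols demes differentiate populations, not flyway groups
        assert result.components["pct_variance"].iloc[1] > 3.0
        assert result.p_values["Phi_SC"] < 0.05

    def test_missing_sample_in_scheme_raises(self, structured):
        ds, _ = structured
        bad = GroupingScheme(population={"nobody": "p1"}, group_of_population={"p1": "g1"})
        with pytest.raises(ValueError, match="not in the grouping scheme"):
            amova(ds, bad, n_permutations=0)


class TestPermutationNull:
    def test_null_pvalues_are_uniform(self):
        """Freshly randomised labels give a flat p-value distribution."""
        ds, _ = make_structured_dataset(n_pops=4, n_per_pop=8, n_loci=60, fst=0.0, seed=2,
                                        groups=["g1", "g1", "g2", "g2"])
        master = np.random.default_rng(77)
        pvals = []
        for _ in range(200):
            perm = master.permutation(ds.n_individuals)
            shuffled = SNPDataset(
                genotypes=ds.genotypes[perm],
                individual_ids=ds.individual_ids,
                populations=ds.populations,
                groups=ds.groups,
            )
            scheme = GroupingScheme.from_table(
                shuffled.individual_ids, shuffled.populations, shuffled.groups
            )
            result = amova(shuffled, scheme, n_permutations=49, rng=master,
                           permute=("Phi_SC",))
            pvals.append(result.p_values["Phi_SC"])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestPcaGenotypes:
    def test_identical_individuals_share_coordinates(self):
        g = np.tile(np.array([0, 1, 2, 1, 0], dtype=np.int8), (4, 1))
        g[2, 0] = 2  # one distinct individual so variance is nonzero
        coords, _ = pca_genotypes(SNPDataset(genotypes=g), n_components=2)
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-9)
        np.testing.assert_allclose(coords[0], coords[3], atol=1e-9)

    def test_coordinates_are_centred(self):
        ds, _ = make_structured_dataset(n_pops=3, n_per_pop=15, n_loci=150, fst=0.1, seed=9)
        coords, explained = pca_genotypes(ds, n_components=4)
        np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-9)
        assert np.all(np.diff(explained) <= 1e-12)

    def test_strong_structure_separates_on_pc1(self):
        ds, _ = make_structured_dataset(n_pops=2, n_per_pop=30, n_loci=500, fst=0.2, seed=3)
        coords, _ = pca_genotypes(ds, n_components=2)
        labels = np.array(ds.populations)
        assert silhouette_score(coords[:, :1], labels) > 0.5

    def test_panmictic_data_show_no_clustering(self):
        ds, _ = make_structured_dataset(n_pops=3, n_per_pop=20, n_loci=500, fst=0.0, seed=4)
        coords, _ = pca_genotypes(ds, n_components=2)
        labels = np.array(ds.populations)  # arbitrary 3-way split of panmictic data
        assert silhouette_score(coords[:, :2], labels) < 0.1

    def test_zero_variance_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_genotypes(SNPDataset(genotypes=np.ones((3, 4), dtype=np.int8)))


def test_weir_cockerham_recovers_simulated_fst():
    estimates = [
        weir_cockerham_fst(
            make_structured_dataset(n_pops=3, n_per_pop=50, n_loci=1000, fst=0.1,
                                    seed=seed)[0]
        )
        for seed in range(10)
    ]
    assert abs(np.mean(estimates) - 0.1) < 0.03
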
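import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from turtur.abc_inference import (
    ReferenceTable,
    build_reference_table,
    estimate_parameters,
    model_choice_direct,
    model_choice_logistic,
    pca_goodness_of_fit,
    standardize_and_distance,
)
from turtur.demographic_models import NormalPrior, PriorSpec, default_priors
from turtur.sumstats import STAT_NAMES


def synthetic_table(rng, n_per_scenario=400, separation=6.0):
    """Hand-built table with well-separated per-scenario statistic clouds."""
    rows = []
    for sid in range(1, 6):
        center = np.array([0.1, 0.1, 0.01, 0.1]) + separation * 0.01 * sid
        stats = center + rng.normal(0, 0.005, size=(n_per_scenario, 4))
        frame = pd.DataFrame(stats, columns=list(STAT_NAMES))
        frame.insert(0, "scenario", sid)
        frame["N3"] = np.exp(rng.normal(12, 0.5, size=n_per_scenario))
        rows.append(frame)
    return ReferenceTable(data=pd.concat(rows, ignore_index=True))


@pytest.fixture(scope="module")
def small_table():
    rng = np.random.default_rng(42)
    return build_reference_table(
        default_priors(), n_sims_per_scenario=300, n_individuals=25, n_loci=120, rng=rng
    )


class TestBuildReferenceTable:
    def test_allocation_and_ids(self, rng):
        table = build_reference_table(default_priors(), 2, 10, 200, rng)
        assert table.n_rows == 10
        assert sorted(table.data["scenario"].value_counts().items()) == [
            (s, 2) for s in range(1, 6)
        ]

    def test_seed_determinism(self):
        t1 = build_reference_table(default_priors(), 10, 10, 40,
                                   np.random.default_rng(3))
        t2 = build_reference_table(default_priors(), 10, 10, 40,
                                   np.random.default_rng(3))
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_diversity_increases_with_population_size(self):
        """Constant-size tables at 100x different N separate in mean diversity."""
        def one_size_prior(n):
            return PriorSpec(params={"N3": NormalPrior(mean=n, sd=0.0, fixed=True)})

        big = build_reference_table(one_size_prior(1e6), 500, 15, 100,
                                    np.random.default_rng(4), scenario_ids=(1,),
                                    locus_mutation_rate=2e-6)
        small = build_reference_table(one_size_prior(1e4), 500, 15, 100,
                                      np.random.default_rng(5), scenario_ids=(1,),
                                      locus_mutation_rate=2e-6)
        p = mannwhitneyu(
            big.data["mean_gd_all"], small.data["mean_gd_all"], alternative="greater"
        ).pvalue
        assert p < 0.01

    def test_csv_round_trip(self, small_table, tmp_path):
        path = tmp_path / "table.csv"
        small_table.to_csv(path)
        back = ReferenceTable.from_csv(path)
        assert back.n_rows == small_table.n_rows
        assert back.meta["n_loci"] == str(small_table.meta["n_loci"])
        np.testing.assert_allclose(back.stats_matrix(), small_table.stats_matrix())


class TestDistances:
    def test_zero_distance_for_observed_table_row(self, small_table):
        observed = small_table.stats_matrix()[17]
        distances, _, _ = standardize_and_distance(small_table, observed)
        assert distances[17] == pytest.approx(0.0, abs=1e-12)

    def test_row_duplication_leaves_distances_unchanged(self, small_table):
        observed = small_table.stats_matrix().mean(axis=0)
        d1, _, _ = standardize_and_distance(small_table, observed)
        doubled = small_table.append(small_table)
        d2, _, _ = standardize_and_distance(doubled, observed)
        np.testing.assert_allclose(d2[: len(d1)], d1)

    def test_matches_naive_recomputation(self, small_table, rng):
        observed = small_table.stats_matrix().mean(axis=0)
        distances, sds, used = standardize_and_distance(small_table, observed)
        stats = small_table.stats_matrix()
        for i in rng.choice(small_table.n_rows, size=100, replace=False):
            manual = math.sqrt(
                sum(
                    ((stats[i, j] - observed[j]) / sds[j]) ** 2
                    for j in range(4)
                    if used[j]
                )
            )
            assert distances[i] == pytest.approx(manual, rel=1e-12)

    def test_zero_variance_statistic_excluded(self):
        rng = np.random.default_rng(0)
        table = synthetic_table(rng)
        table.data["var_gd_poly"] = 0.5  # constant column
        with pytest.warns(UserWarning, match="zero-variance"):
            distances, _, used = standardize_and_distance(
                table, table.stats_matrix().mean(axis=0)
            )
        assert not used[2]
        assert np.all(np.isfinite(distances))


class TestModelChoiceDirect:
    def test_tolerance_one_recovers_allocation_exactly(self, small_table):
        observed = small_table.stats_matrix().mean(axis=0)
        result = model_choice_direct(small_table, observed, tolerance=1.0)
        counts = small_table.data["scenario"].value_counts()
        for sid, prob in result.probabilities.items():
            assert prob == counts[sid] / small_table.n_rows
        assert sum(result.probabilities.values()) == pytest.approx(1.0, abs=1e-9)

    def test_pure_accepted_set_gives_certainty(self, rng):
        table = synthetic_table(rng)
        observed = table.data.loc[table.data["scenario"] == 4, list(STAT_NAMES)].mean()
        result = model_choice_direct(table, observed.to_numpy(), tolerance=0.01, rng=rng)
        assert result.probabilities[4] == 1.0
        assert result.ci95[4] == (1.0, 1.0)
        assert result.degenerate


class TestModelChoiceLogistic:
    def test_no_signal_returns_uniform_probabilities(self):
        rng = np.random.default_rng(9)
        table = synthetic_table(rng, separation=0.0)  # identical clouds
        observed = table.stats_matrix().mean(axis=0)
        result = model_choice_logistic(table, observed, tolerance=0.5, rng=rng)
        for prob in result.probabilities.values():
            assert prob == pytest.approx(0.2, abs=0.1)
        assert sum(result.probabilities.values()) == pytest.approx(1.0, abs=1e-6)

    def test_agrees_with_direct_on_separated_clouds(self, rng):
        table = synthetic_table(rng, separation=2.0)
        observed = (
            table.data.loc[table.data["scenario"] == 4, list(STAT_NAMES)]
            .mean()
            .to_numpy()
        )
        direct = model_choice_direct(table, observed, tolerance=0.05, rng=rng)
        logistic = model_choice_logistic(table, observed, tolerance=0.2, rng=rng)
        assert logistic.best_scenario() == direct.best_scenario() == 4

    def test_single_class_acceptance_is_degenerate(self, rng):
        table = synthetic_table(rng, separation=10.0)
        observed = (
            table.data.loc[table.data["scenario"] == 2, list(STAT_NAMES)]
            .mean()
            .to_numpy()
        )
        result = model_choice_logistic(table, observed, tolerance=0.01, rng=rng)
        assert result.degenerate
        assert result.probabilities[2] == 1.0


class TestEstimateParameters:
    def test_self_consistency_at_a_table_row(self, small_table):
        sub = small_table.data[small_table.data["scenario"] == 4]
        row = sub.iloc[10]
        observed = row[list(STAT_NAMES)].to_numpy(dtype=float)
        posterior = estimate_parameters(
            small_table, observed, scenario_id=4, tolerance=1.0 / len(sub)
        )
        assert posterior.n_accepted == 1
        assert posterior.summaries["N3"]["median"] == pytest.approx(row["N3"], rel=1e-6)

    def test_unadjusted_equals_weighted_rejection_quantiles(self, small_table):
        observed = small_table.stats_matrix().mean(axis=0)
        posterior = estimate_parameters(
            small_table, observed, scenario_id=4, tolerance=0.2, adjust=False
        )
        # brute-force oracle: replicate the weighted quantile from raw pieces
        sub_mask = small_table.scenario_ids() == 4
        sub = ReferenceTable(
            data=small_table.data.loc[sub_mask].reset_index(drop=True),
            meta=small_table.meta,
        )
        distances, _, _ = standardize_and_distance(sub, observed)
        n_acc = math.ceil(0.2 * len(distances))
        acc = np.argsort(distances, kind="stable")[:n_acc]
        w = 1 - (distances[acc] / distances[acc].max()) ** 2
        values = sub.data["N3"].to_numpy()[acc]
        order = np.argsort(values)
        cdf = np.cumsum(w[order]) / w.sum()
        expected_median = float(np.interp(0.5, cdf, values[order]))
        assert posterior.summaries["N3"]["median"] == pytest.approx(expected_median)
        assert not posterior.adjusted

    def test_interval_is_ordered(self, small_table):
        observed = small_table.stats_matrix().mean(axis=0)
        posterior = estimate_parameters(small_table, observed, scenario_id=4, tolerance=0.1)
        for s in posterior.summaries.values():
            assert s["q025"] <= s["median"] <= s["q975"]


class TestPcaGoodnessOfFit:
    def test_centroid_observation_has_low_percentile(self, rng):
        table = synthetic_table(rng)
        observed = (
            table.data.loc[table.data["scenario"] == 3, list(STAT_NAMES)]
            .mean()
            .to_numpy()
        )
        fit = pca_goodness_of_fit(table, observed, rng=rng)
        assert fit.percentiles[3] < 10.0
        assert not fit.poor_fit

    def test_outlying_observation_flags_poor_fit(self, rng):
        table = synthetic_table(rng)
        observed = table.stats_matrix().max(axis=0) * 50
        fit = pca_goodness_of_fit(table, observed, rng=rng)
        assert fit.poor_fit
        assert all(p > 99 for p in fit.percentiles.values())

    def test_too_many_components_rejected(self, rng):
        table = synthetic_table(rng)
        with pytest.raises(ValueError):
            pca_goodness_of_fit(table, table.stats_matrix().mean(axis=0),
                                n_components=10, rng=rng)
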
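import numpy as np
import pandas as pd
import pytest

from selenet import synthetic
from selenet.errors import ParameterError
from selenet.expression import ddcq_fold_change, mean_profiles
from selenet.interactome import InteractionRecord, merge_interactomes


def merge_sources(sources):
    record_lists = [
        [InteractionRecord(a, b, f"s{i}", j) for j, (a, b) in enumerate(src)]
        for i, src in enumerate(sources)
    ]
    return merge_interactomes(record_lists)


class TestInteractomeGenerator:
    def test_single_source_equals_union(self):
        sources, truth = synthetic.simulate_interactome_sources(50, 2, 1, 0.0, 0, seed=1)
        assert len(sources) == 1
        assert sorted(sources[0]) == truth.generator_params["union_edges"]

    def test_union_of_sources_equals_truth_union(self):
        sources, truth = synthetic.simulate_interactome_sources(60, 2, 3, 0.3, 1, seed=2)
        union = sorted(set().union(*map(set, sources)))
        assert union == truth.generator_params["union_edges"]

    def test_overlap_fraction_of_edges_in_two_sources(self):
        sources, truth = synthetic.simulate_interactome_sources(80, 2, 3, 0.25, 0, seed=3)
        m = len(truth.generator_params["union_edges"])
        counts = {}
        for src in sources:
            for e in src:
                counts[e] = counts.get(e, 0) + 1
        n_shared = sum(1 for c in counts.values() if c >= 2)
        assert n_shared == int(0.25 * m)

    def test_planted_hub_has_maximum_degree(self):
        sources, truth = synthetic.simulate_interactome_sources(100, 3, 3, 0.2, 1, seed=4)
        g = merge_sources(sources).graph
        hub = truth.planted_hub_ids[0]
        degrees = dict(g.degree())
        assert degrees[hub] == max(degrees.values())
        assert degrees[hub] >= 0.2 * 100

    def test_same_seed_reproduces_identical_files(self, tmp_path):
        for run in ("a", "b"):
            sources, _ = synthetic.simulate_interactome_sources(40, 2, 2, 0.1, 1, seed=5)
            synthetic.write_edge_lists(sources, [tmp_path / f"{run}{i}.tsv" for i in range(2)])
        for i in range(2):
            assert (tmp_path / f"a{i}.tsv").read_bytes() == (tmp_path / f"b{i}.tsv").read_bytes()

    def test_overlap_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            synthetic.simulate_interactome_sources(40, 2, 2, 1.5, 0, seed=1)


class TestExpressionGenerator:
    def test_noiseless_planted_ratio_exact(self):
        m, _ = synthetic.simulate_expression_study(
            10, {"tumor": 3, "normal": 3}, {"G1": 2.0}, noise_sd=0.0, seed=1
        )
        prof = mean_profiles(m, ["tumor", "normal"])
        assert prof.loc["G1", "tumor"] / prof.loc["G1", "normal"] == pytest.approx(4.0)

    def test_unplanted_gene_ratio_one(self):
        m, _ = synthetic.simulate_expression_study(
            5, {"tumor": 2, "normal": 2}, {"G1": 2.0}, noise_sd=0.0, seed=1
        )
        prof = mean_profiles(m, ["tumor", "normal"])
        others = [g for g in m.genes if g != "G1"]
        assert np.allclose(prof.loc[others, "tumor"], prof.loc[others, "normal"])

    def test_truth_genes_present_in_matrix(self):
        planted = {"GPX1": 1.5, "SELENOW": -2.0}
        m, truth = synthetic.simulate_expression_study(
            20, {"tumor": 2, "normal": 2}, planted, noise_sd=0.1, seed=2
        )
        assert set(truth.planted_log2fc) <= set(m.genes)

    def test_estimator_unbiased_over_replicates(self):
        # Monte-Carlo mean of the estimated log2FC for one planted gene
        estimates = []
        for rep in range(200):
            m, _ = synthetic.simulate_expression_study(
                10, {"tumor": 20, "normal": 20}, {"G1": 2.0}, noise_sd=0.25, seed=1000 + rep
            )
            prof = mean_profiles(m, ["tumor", "normal"])
            estimates.append(np.log2(prof.loc["G1", "tumor"] / prof.loc["G1", "normal"]))
        assert np.mean(estimates) == pytest.approx(2.0, abs=0.05)

    def test_same_seed_identical_matrix(self):
        a, _ = synthetic.simulate_expression_study(8, {"tumor": 3, "normal": 3}, {}, 0.3, seed=9)
        b, _ = synthetic.simulate_expression_study(8, {"tumor": 3, "normal": 3}, {}, 0.3, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_negative_noise_rejected(self):
        with pytest.raises(ParameterError):
            synthetic.simulate_expression_study(5, {"tumor": 2, "normal": 2}, {}, -0.1, seed=1)


class TestCqGenerator:
    def test_empty_gene_list_rejected(self):
        with pytest.raises(ParameterError):
            synthetic.simulate_cq_table([], ["tnbc", "normal"], {}, 3, seed=1)

    def test_housekeeping_constant_across_groups_without_jitter(self):
        cq, _ = synthetic.simulate_cq_table(
            ["G1"], ["tnbc", "normal"], {"G1": 2.0}, replicates=2, seed=1, jitter_sd=0.0
        )
        hk = cq.data[cq.data["gene"] == "ACTB"]["cq"]
        assert hk.nunique() == 1

    def test_median_recovered_fold_change_within_five_percent(self):
        fcs = []
        for rep in range(200):
            cq, _ = synthetic.simulate_cq_table(
                ["G1"], ["tnbc", "normal"], {"G1": 3.0}, replicates=3, seed=2000 + rep, jitter_sd=0.1
            )
            out = ddcq_fold_change(cq, "tnbc", "normal")
            fcs.append(out.loc["G1", "fold_change"])
        assert np.median(fcs) == pytest.approx(8.0, rel=0.05)


class TestIHCGenerator:
    def test_perfect_latent_correlation_gives_identical_intensities(self):
        cohort, _ = synthetic.simulate_ihc_cohort(50, latent_rho=1.0, grade_shift=0.0, seed=1)
        assert (cohort.data["SELENOS"] == cohort.data["VCP"]).all()

    def test_zero_latent_correlation_gives_near_zero_ordinal_r(self):
        cohort, _ = synthetic.simulate_ihc_cohort(
            10000, latent_rho=0.0, grade_shift=0.0, thresholds=(-0.5, 0.5), seed=2
        )
        r = np.corrcoef(cohort.data["SELENOS"], cohort.data["VCP"])[0, 1]
        assert abs(r) <= 0.05

    def test_grade_shift_raises_grade3_intensities(self):
        cohort, _ = synthetic.simulate_ihc_cohort(600, seed=3)
        means = cohort.data.groupby("grade")["SELENOS"].mean()
        assert means[3] > means[2]

    def test_ki67_within_range_and_grade_dependent(self):
        cohort, _ = synthetic.simulate_ihc_cohort(600, seed=4)
        assert cohort.data["ki67"].between(0, 100).all()
        means = cohort.data.groupby("grade")["ki67"].mean()
        assert means[3] > means[2]

    def test_non_increasing_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            synthetic.simulate_ihc_cohort(10, thresholds=(1.0, 1.0), seed=1)

    def test_latent_rho_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            synthetic.simulate_ihc_cohort(10, latent_rho=1.2, seed=1)


class TestSurvivalGenerator:
    def test_no_censoring_means_all_events(self):
        table, _ = synthetic.simulate_survival_cohort(50, 2.0, censor_rate=0.0, seed=1)
        assert (table.data["event"] == 1).all()

    def test_censor_rate_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            synthetic.simulate_survival_cohort(50, 2.0, censor_rate=1.0, seed=1)

    def test_nonpositive_hazard_ratio_rejected(self):
        with pytest.raises(ParameterError):
            synthetic.simulate_survival_cohort(50, 0.0, seed=1)

    def test_planted_hazard_ratio_orders_group_medians(self):
        worse = 0
        sims = 60
        for rep in range(sims):
            table, truth = synthetic.simulate_survival_cohort(200, 2.5, censor_rate=0.0, seed=3000 + rep)
            groups = pd.Series(truth.generator_params["group_of"])
            med = table.data.groupby(groups)["time"].median()
            worse += med["high"] < med["low"]
        assert worse >= 0.95 * sims

    def test_null_hazard_ratio_symmetric_medians(self):
        lower = 0
        sims = 60
        for rep in range(sims):
            table, truth = synthetic.simulate_survival_cohort(100, 1.0, censor_rate=0.0, seed=4000 + rep)
            groups = pd.Series(truth.generator_params["group_of"])
            med = table.data.groupby(groups)["time"].median()
            lower += med["high"] < med["low"]
        # under the null the high group wins about half the time
        assert 0.25 * sims <= lower <= 0.75 * sims

    def test_truth_group_labels_cover_cohort(self):
        table, truth = synthetic.simulate_survival_cohort(30, 2.0, seed=5)
        assert set(truth.generator_params["group_of"]) == set(table.data.index)
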
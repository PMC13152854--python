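import numpy as np
import pandas as pd
import pytest

from budtraj.divergence import (
    abundance_gate,
    cultivar_concordance,
    discordance_flag,
    module_stage_divergence,
    select_candidates,
    stage_group_difference,
)
from budtraj.io import validate_design
from budtraj.qc import log2p1, replicate_means
from budtraj.synthetic import TruthSpec, generate_dataset
from budtraj.trajectory import ClusterAssignment, cluster_kmeans, zscore_trajectories

from conftest import toy_design


def four_cultivar_means(rows, stages=("S1", "S2")):
    cults = (("W", "Low"), ("X", "Low"), ("Y", "High"), ("Z", "High"))
    cols = pd.MultiIndex.from_tuples(
        [(c, s) for c, _ in cults for s in stages])
    design = validate_design(toy_design(cultivars=cults, stages=stages))
    df = pd.DataFrame(rows, columns=cols,
                      index=[f"g{i}" for i in range(len(rows))])
    return df, design


class TestStageGroupDifference:
    def test_arithmetic(self):
        # at S1: High cultivars (2.0, 3.0), Low (1.0, 2.0) -> d = 1.0
        rows = [[1.0, 0, 2.0, 0, 2.0, 0, 3.0, 0]]
        means, design = four_cultivar_means(rows)
        d = stage_group_difference(means, design)
        assert d.loc["g0", "S1"] == pytest.approx(1.0)

    def test_identical_groups_give_zero(self):
        rows = [[3.0, 4.0] * 4]
        means, design = four_cultivar_means(rows)
        d = stage_group_difference(means, design)
        np.testing.assert_allclose(d.to_numpy(), 0.0, atol=1e-12)

    def test_swapping_group_labels_negates(self):
        rows = [[1.0, 5.0, 2.0, 4.0, 2.5, 7.0, 3.0, 1.0]]
        means, design = four_cultivar_means(rows)
        d = stage_group_difference(means, design)
        flipped = design.copy()
        flipped["cr_group"] = flipped["cr_group"].map(
            {"Low": "High", "High": "Low"})
        d2 = stage_group_difference(means, validate_design(flipped))
        np.testing.assert_allclose(d2.to_numpy(), -d.to_numpy(), atol=1e-12)


class TestModuleStageDivergence:
    @staticmethod
    def one_cluster(genes):
        labels = pd.Series("C1", index=genes, name="cluster")
        centroids = pd.DataFrame(0.0, index=["C1"], columns=range(3))
        return ClusterAssignment(labels, 1, 0, centroids, 0.0)

    def test_mean_of_absolute_differences(self):
        d = pd.DataFrame({"S1": [0.4, -0.6], "S2": [0.1, 0.1]},
                         index=["g0", "g1"])
        md = module_stage_divergence(d, self.one_cluster(["g0", "g1"]))
        assert md.loc["C1", "S1"] == pytest.approx(0.5)

    def test_tie_breaks_to_earliest_stage(self):
        d = pd.DataFrame({"S1": [0.0], "S2": [0.0], "S3": [0.0]}, index=["g0"])
        md = module_stage_divergence(d, self.one_cluster(["g0"]))
        assert md.loc["C1", "peak_stage"] == "S1"
        assert md.loc["C1", ["S1", "S2", "S3"]].eq(0).all()

    def test_planted_peak_recovered(self, ref_ds):
        means = replicate_means(ref_ds.expression.values,
                                ref_ds.expression.design)
        assignment = cluster_kmeans(zscore_trajectories(means), k=8, seed=11)
        log_means = replicate_means(ref_ds.expression.values,
                                    ref_ds.expression.design, scale="log")
        d = stage_group_difference(log_means, ref_ds.expression.design)
        md = module_stage_divergence(d, assignment)
        for mod, peak in {0: "S3", 1: "S2", 3: "S1"}.items():
            genes = ref_ds.genes_of_archetype(mod)
            cluster = assignment.labels.reindex(genes).mode()[0]
            assert md.loc[cluster, "peak_stage"] == peak


class TestDiscordance:
    @pytest.mark.parametrize("d_row, expected", [
        ((0.3, 0.2, 0.4), False),        # constant sign
        ((0.3, -0.3, 0.1), True),        # sign change
        ((0.01, -0.01, 0.02), False),    # all below eps
        ((0.3, -0.04, 0.2), False),      # opposite sign below eps ignored
    ])
    def test_sign_rules(self, d_row, expected):
        d = pd.DataFrame([d_row], columns=["S1", "S2", "S3"], index=["g0"])
        assert discordance_flag(d, eps=0.05)["g0"] == expected


class TestConcordance:
    def rows_with_trends(self, trends, magnitude=1.0):
        # trend over (S1 -> S2): per-cultivar pairs
        row = []
        for t in trends:
            row += [0.0, t * magnitude]
        return [row]

    @pytest.mark.parametrize("trends, count, passes", [
        ((+1, +1, +1, -1), 3, True),
        ((+1, +1, -1, -1), 2, False),
        ((+1, +1, +1, +1), 4, True),
    ])
    def test_k_of_n_rule(self, trends, count, passes):
        rows = self.rows_with_trends(trends)
        means, _ = four_cultivar_means(rows)
        _, counts, ok = cultivar_concordance(means, eps=0.05, k_of_n=3)
        assert counts["g0"] == count
        assert bool(ok["g0"]) is passes

    def test_sub_eps_trend_counts_as_zero(self):
        rows = self.rows_with_trends((+1, +1, +1, +1), magnitude=0.01)
        means, _ = four_cultivar_means(rows)
        trend, counts, ok = cultivar_concordance(means, eps=0.05)
        assert (trend.loc["g0"] == 0).all()
        assert counts["g0"] == 0 and not ok["g0"]


class TestAbundanceGate:
    def test_boundary_inclusive(self):
        # mean exactly 0.5 and max exactly 1.0 passes
        vals = pd.DataFrame([[1.0, 0.5, 0.0, 0.5]], index=["g0"])
        assert abundance_gate(vals)["g0"]

    def test_mean_below_threshold_fails(self):
        vals = pd.DataFrame([[5.0] + [0.0] * 11], index=["g0"])
        assert vals.loc["g0"].mean() < 0.5
        assert not abundance_gate(vals)["g0"]

    def test_all_zero_fails(self):
        vals = pd.DataFrame([[0.0] * 6], index=["g0"])
        assert not abundance_gate(vals)["g0"]


class TestSelectCandidates:
    @staticmethod
    def run_selection(ds, seed=0):
        means = replicate_means(ds.expression.values, ds.expression.design)
        assignment = cluster_kmeans(zscore_trajectories(means), k=8, seed=seed)
        log_means = replicate_means(ds.expression.values,
                                    ds.expression.design, scale="log")
        d = stage_group_difference(log_means, ds.expression.design)
        disc = discordance_flag(d)
        _, _, conc = cultivar_concordance(log_means)
        abund = abundance_gate(ds.expression.values)
        from budtraj.trajectory import flag_cr_divergent_clusters
        flagged, _ = flag_cr_divergent_clusters(assignment, disc, 0.5)
        classes = ds.annotations.class_of(ds.truth.index)
        cands, counts = select_candidates(assignment, flagged, disc, conc,
                                          abund, classes)
        return cands, counts, assignment, flagged

    def test_zero_noise_recovers_planted_plausible_genes(self):
        spec = TruthSpec(n_genes=400, noise_sd=0.0, coexpr_blocks=(),
                         cultivar_jitter_sd=0.0, gene_mean_loc=8.0,
                         gene_mean_scale=0.5, baseline_sd=0.8, seed=21)
        ds = generate_dataset(spec)
        cands, _, _, _ = self.run_selection(ds, seed=21)
        truth = ds.truth
        classes = ds.annotations.class_of(truth.index)
        expected = truth.index[truth["divergent"] & (classes != "other")]
        assert set(cands) == set(expected)
        assert len(expected) > 20

    def test_class_filter_excludes_other(self, ref_ds):
        cands, _, assignment, flagged = self.run_selection(ref_ds, seed=11)
        classes = ref_ds.annotations.class_of(ref_ds.truth.index)
        assert len(cands) > 0
        assert (classes.reindex(cands) != "other").all()

    def test_candidates_subset_of_flagged_clusters(self, ref_ds):
        cands, counts, assignment, flagged = self.run_selection(ref_ds, seed=11)
        flagged_genes = assignment.labels.index[
            assignment.labels.isin(flagged)]
        assert set(cands) <= set(flagged_genes)
        assert counts.sum() == len(cands)

    def test_empty_plausibility_set_rejected(self, ref_ds):
        _, _, assignment, flagged = self.run_selection(ref_ds, seed=11)
        empty = pd.Series(False, index=assignment.labels.index)
        with pytest.raises(ValueError):
            select_candidates(assignment, flagged, empty, empty, empty,
                              pd.Series("TF", index=assignment.labels.index),
                              plausible=set())


class TestScaleSensitivity:
    def test_doubling_tpm_shifts_d_less_than_one(self, ref_ds):
        """Doubling every TPM moves each log2 group difference by strictly
        less than 1 and rarely changes sign-based flags."""
        design = ref_ds.expression.design
        log_means = replicate_means(ref_ds.expression.values, design,
                                    scale="log")
        d1 = stage_group_difference(log_means, design)
        doubled = replicate_means(ref_ds.expression.values * 2.0, design,
                                  scale="log")
        d2 = stage_group_difference(doubled, design)
        shift = (d2 - d1).abs()
        assert shift.to_numpy().max() < 1.0
        # sign calls are stable wherever the call margin exceeds the shift
        clear = (d1.abs() >= shift + 0.05).all(axis=1)
        assert clear.sum() > 100
        f1 = discordance_flag(d1)
        f2 = discordance_flag(d2)
        assert (f1[clear] == f2[clear]).all()
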
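import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from budtraj.io import hormones_wide, validate_design
from budtraj.network import (
    adjacency_from_corr,
    connected_subgraph,
    consensus_network,
    correlation_matrix,
    correlation_network,
    correlation_pvalue,
    detect_modules,
    edges_frame,
    module_eigengene,
    module_trait_association,
    node_centrality,
    per_cultivar_correlations,
    residualize_by_stage,
    tom_similarity,
    trait_frame,
)
from budtraj.qc import log2p1

from conftest import toy_design
from oracles import betweenness_brute, tom_brute


class TestResidualize:
    def test_stage_constant_gene_residuals_are_zero(self, design36):
        stage_vals = {"S1": 2.0, "S2": 5.0, "S3": 3.0}
        vals = np.array([[stage_vals[s] for s in design36["stage"]]])
        df = pd.DataFrame(vals, columns=list(design36["sample_id"]))
        resid = residualize_by_stage(df, design36)
        np.testing.assert_allclose(resid.to_numpy(), 0.0, atol=1e-12)

    def test_residual_stage_means_are_zero(self, ref_ds, design36):
        logx = log2p1(ref_ds.expression.values)
        resid = residualize_by_stage(logx, design36)
        for s in ("S1", "S2", "S3"):
            cols = design36.loc[design36["stage"] == s, "sample_id"]
            np.testing.assert_allclose(resid[list(cols)].mean(axis=1), 0.0,
                                       atol=1e-12)

    def test_cultivar_offsets_survive_up_to_constant(self):
        # two cultivars with a pure offset: residuals keep the offset shape
        design = validate_design(toy_design(stages=("S1", "S2"), reps=1))
        df = pd.DataFrame([[1.0, 1.0, 5.0, 5.0]],
                          columns=list(design["sample_id"]))
        resid = residualize_by_stage(df, design)
        np.testing.assert_allclose(resid.to_numpy(), [[-2, -2, 2, 2]],
                                   atol=1e-12)

    def test_invariant_to_adding_stage_constant_vector(self, ref_ds, design36):
        logx = log2p1(ref_ds.expression.values.iloc[:30])
        shift = {"S1": 3.0, "S2": -1.0, "S3": 0.5}
        shifted = logx + np.array([shift[s] for s in design36["stage"]])
        r1 = correlation_matrix(residualize_by_stage(logx, design36))
        r2 = correlation_matrix(residualize_by_stage(shifted, design36))
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-9)


class TestCorrelationNetwork:
    def test_identical_genes_connected_with_r_one(self, rng, design36):
        base = rng.normal(0, 1, 36)
        df = pd.DataFrame([base, base, rng.normal(0, 1, 36)],
                          index=["a", "b", "c"],
                          columns=list(design36["sample_id"]))
        g = correlation_network(df, min_abs_r=0.8)
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["weight"] == pytest.approx(1.0)

    def test_degree_counts_incident_edges(self, rng, design36):
        df = pd.DataFrame(rng.normal(0, 1, (12, 36)),
                          columns=list(design36["sample_id"]))
        g = correlation_network(df, min_abs_r=0.2)
        for node in g.nodes:
            assert g.nodes[node]["degree"] == len(list(g.edges(node)))

    def test_independent_noise_rarely_connected(self):
        hits = total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(0, 1, (40, 36)))
            g = correlation_network(df, min_abs_r=0.8)
            hits += g.number_of_edges()
            total += 40 * 39 / 2
        assert hits / total < 0.01

    def test_zero_variance_gene_dropped_with_warning(self, rng, design36):
        df = pd.DataFrame(rng.normal(0, 1, (3, 36)),
                          index=["a", "b", "c"],
                          columns=list(design36["sample_id"]))
        df.loc["c"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            g = correlation_network(df, min_abs_r=0.9)
        assert "c" not in g.nodes


class TestTOM:
    def test_two_mutually_connected_genes(self):
        adj = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"),
                           columns=list("ab"))
        tom = tom_similarity(adj)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_empty_adjacency_gives_identity(self):
        adj = pd.DataFrame(np.zeros((4, 4)))
        tom = tom_similarity(adj)
        np.testing.assert_allclose(tom.to_numpy(), np.eye(4), atol=1e-12)

    def test_matches_brute_force_triple_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(2, 7))
            a = rng.uniform(0, 1, (n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            tom = tom_similarity(pd.DataFrame(a))
            np.testing.assert_allclose(tom.to_numpy(), tom_brute(a),
                                       atol=1e-12)

    def test_bounded_on_powered_correlations(self, ref_ds, design36):
        logx = log2p1(ref_ds.expression.values.iloc[:60])
        corr = correlation_matrix(residualize_by_stage(logx, design36))
        tom = tom_similarity(adjacency_from_corr(corr))
        vals = tom.to_numpy()
        assert vals.min() >= -1e-12 and vals.max() <= 1 + 1e-12

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(ValueError):
            tom_similarity(pd.DataFrame([[0.0, 1.2], [1.2, 0.0]]))
        with pytest.raises(ValueError):
            tom_similarity(pd.DataFrame([[0.5, 0.1], [0.1, 0.5]]))


class TestDetectModules:
    @staticmethod
    def two_block_data(rng, n_per=30, n_samples=40, noise=0.3):
        f1 = rng.normal(0, 1, n_samples)
        f2 = rng.normal(0, 1, n_samples)
        rows = [f1 + rng.normal(0, noise, n_samples) for _ in range(n_per)]
        rows += [f2 + rng.normal(0, noise, n_samples) for _ in range(n_per)]
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(2 * n_per)])

    def test_two_planted_blocks_give_two_modules(self, rng):
        df = self.two_block_data(rng)
        corr = correlation_matrix(df)
        tom = tom_similarity(adjacency_from_corr(corr))
        modules = detect_modules(tom, min_module_size=20)
        non_grey = modules[modules != "grey"]
        assert set(non_grey.unique()) == {"turquoise", "blue"}
        first = set(modules.index[:30])
        assert len(set(modules[list(first)].unique())) == 1

    def test_identical_genes_one_module(self, rng):
        base = rng.normal(0, 1, 30)
        df = pd.DataFrame([base + rng.normal(0, 0.01, 30) for _ in range(25)])
        corr = correlation_matrix(df)
        tom = tom_similarity(adjacency_from_corr(corr))
        modules = detect_modules(tom, min_module_size=20)
        assert (modules == "turquoise").all()

    def test_below_min_size_goes_grey(self, rng):
        df = self.two_block_data(rng, n_per=5)
        corr = correlation_matrix(df)
        tom = tom_similarity(adjacency_from_corr(corr))
        modules = detect_modules(tom, min_module_size=20)
        assert (modules == "grey").all()

    def test_min_module_size_validated(self, rng):
        df = self.two_block_data(rng, n_per=5)
        tom = tom_similarity(adjacency_from_corr(correlation_matrix(df)))
        with pytest.raises(ValueError):
            detect_modules(tom, min_module_size=1)


class TestEigengene:
    def test_identical_standardized_genes(self, rng):
        profile = rng.normal(0, 1, 24)
        df = pd.DataFrame([2 * profile + 1, profile - 3, 5 * profile],
                          index=list("abc"))
        me, explained = module_eigengene(df, ["a", "b", "c"])
        r = np.corrcoef(me, profile)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)
        assert explained == pytest.approx(1.0, abs=1e-9)
        assert me.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_sign_alignment_follows_module_mean(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (10, 24)))
        me, _ = module_eigengene(df, list(df.index))
        z = ((df.T - df.mean(axis=1)) / df.std(axis=1, ddof=1)).T
        assert np.corrcoef(me, z.mean(axis=0))[0, 1] > 0
        # flipping every gene flips the mean, so the aligned eigengene flips
        me_flipped, _ = module_eigengene(-df, list(df.index))
        assert np.corrcoef(me, me_flipped)[0, 1] == pytest.approx(-1.0,
                                                                  abs=1e-9)

    def test_explained_fraction_in_unit_interval(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (8, 24)))
        _, explained = module_eigengene(df, list(df.index))
        assert 0 < explained <= 1

    def test_empty_module_rejected(self, rng):
        with pytest.raises(ValueError):
            module_eigengene(pd.DataFrame(rng.normal(0, 1, (3, 5))), [])


class TestTraitAssociation:
    def make_traits(self, ds):
        return trait_frame(ds.expression.design,
                           hormones_wide(ds.hormones, ds.expression.design))

    def test_eigengene_equal_to_aba(self, ref_ds):
        traits = self.make_traits(ref_ds)
        aba = traits["ABA"].astype(float)
        me = (aba - aba.mean()) / aba.std(ddof=1)
        corr, pval, _ = module_trait_association(
            pd.DataFrame({"MEx": me}), traits)
        assert corr.loc["MEx", "ABA"] == pytest.approx(1.0, abs=1e-12)
        assert pval.loc["MEx", "ABA"] < 1e-30

    def test_pvalue_matches_t_closed_form(self, rng, ref_ds):
        traits = self.make_traits(ref_ds)
        me = pd.Series(rng.normal(0, 1, len(traits)), index=traits.index)
        corr, pval, _ = module_trait_association(
            pd.DataFrame({"MEx": me}), traits)
        for trait in ("stage_num", "ABA", "GA3", "GA7"):
            r, p_ref = stats.pearsonr(me, traits[trait].astype(float))
            assert corr.loc["MEx", trait] == pytest.approx(r, abs=1e-12)
            assert pval.loc["MEx", trait] == pytest.approx(p_ref, abs=1e-10)

    def test_cr_group_aliased_with_cultivar_is_dropped(self, ref_ds):
        traits = self.make_traits(ref_ds)
        me = pd.Series(np.arange(len(traits), dtype=float),
                       index=traits.index)
        _, _, fits = module_trait_association(pd.DataFrame({"MEx": me}),
                                              traits)
        fit = fits["MEx"]
        assert fit.aliased == ["cr_group_num"]
        assert "cr_group_num" not in fit.params.index
        assert "ABA" in fit.params.index


class TestConsensusNetwork:
    @staticmethod
    def matrices_with_pair(rs):
        out = {}
        for ci, r in enumerate(rs):
            m = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
            m.loc["a", "b"] = m.loc["b", "a"] = r
            out[f"c{ci}"] = m
        return out

    def test_three_of_four_same_sign_retained(self):
        g = consensus_network(self.matrices_with_pair([0.9, 0.8, 0.7, -0.6]),
                              k_of_n=3, min_abs_r=0.5)
        assert g.has_edge("a", "b")
        e = g.edges["a", "b"]
        assert e["support"] == 3
        assert e["weight"] == pytest.approx(0.7)

    def test_two_two_split_dropped(self):
        g = consensus_network(self.matrices_with_pair([0.9, 0.9, -0.9, -0.9]),
                              k_of_n=3, min_abs_r=0.5)
        assert not g.has_edge("a", "b")

    def test_magnitude_bar_counts_supporters_only(self):
        # three positive but one below |r| bar -> only 2 supporters
        g = consensus_network(self.matrices_with_pair([0.9, 0.8, 0.3, -0.6]),
                              k_of_n=3, min_abs_r=0.5)
        assert not g.has_edge("a", "b")

    def test_monotone_in_k_and_threshold(self, ref_ds):
        logx = log2p1(ref_ds.expression.values.iloc[:80])
        per_cult = per_cultivar_correlations(logx, ref_ds.expression.design)

        def edge_set(k, r):
            g = consensus_network(per_cult, k_of_n=k, min_abs_r=r)
            return {tuple(sorted(e)) for e in g.edges}

        base = edge_set(3, 0.5)
        assert edge_set(4, 0.5) <= base
        assert edge_set(3, 0.7) <= base
        assert edge_set(4, 0.7) <= edge_set(4, 0.5)

    def test_k_beyond_cultivars_rejected(self):
        with pytest.raises(ValueError):
            consensus_network(self.matrices_with_pair([0.9, 0.9]), k_of_n=3)


class TestCentrality:
    def test_star_graph_degrees(self):
        g = nx.star_graph(4)
        cent = node_centrality(g)
        assert cent.loc[0, "degree"] == 4
        assert (cent.loc[1:, "degree"] == 1).all()

    def test_path_center_betweenness_one(self):
        g = nx.path_graph(3)
        cent = node_centrality(g)
        assert cent.loc[1, "betweenness"] == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = 6
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
            cent = node_centrality(g)
            brute = betweenness_brute(list(g.edges), list(g.nodes))
            for v in g.nodes:
                assert cent.loc[v, "betweenness"] == pytest.approx(
                    brute[v], abs=1e-12)

    def test_connected_subgraph_drops_isolates(self):
        g = nx.Graph()
        g.add_nodes_from("abcd")
        g.add_edge("a", "b")
        sub = connected_subgraph(g)
        assert set(sub.nodes) == {"a", "b"}
        assert node_centrality(nx.Graph()).empty

    def test_edges_frame_sorted_pairs(self):
        g = nx.Graph()
        g.add_edge("z", "a", weight=0.5, sign=1)
        df = edges_frame(g)
        assert df.loc[0, "gene1"] == "a" and df.loc[0, "gene2"] == "z"
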
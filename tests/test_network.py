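import numpy as np
import networkx as nx
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from paddynet import network
from paddynet.network import (CorrelationMatrix, build_network,
                              correlation_matrix, detect_modules,
                              export_network, module_environment_mantel,
                              network_topology, nnsd_chi2, node_roles,
                              null_model_ensemble, prevalence_filter,
                              rewire_degree_preserving, rmt_threshold,
                              unfold_spacings)
from paddynet.tables_io import OTUTable

from conftest import planted_block_correlation


def _otu(counts, samples=None, otus=None):
    counts = np.asarray(counts)
    return OTUTable(counts=pd.DataFrame(
        counts,
        index=samples or [f"S{i}" for i in range(counts.shape[0])],
        columns=otus or [f"O{j}" for j in range(counts.shape[1])]))


def _triangle(r=0.9):
    ids = list("abc")
    m = np.full((3, 3), r)
    np.fill_diagonal(m, 1.0)
    return build_network(CorrelationMatrix(ids, m), 0.8)


class TestPrevalenceFilter:
    def test_counts_presence_threshold(self):
        counts = np.zeros((10, 3), dtype=int)
        counts[:, 0] = 1          # present in 10
        counts[:9, 1] = 1         # present in 9
        counts[:5, 2] = 1         # present in 5
        kept = prevalence_filter(_otu(counts), 0.9)
        assert kept.otu_ids == ["O0", "O1"]

    def test_epsilon_threshold_keeps_everything(self):
        counts = np.eye(4, dtype=int) + 1
        counts[0, 0] = 0
        kept = prevalence_filter(_otu(counts), 1e-9)
        assert kept.n_otus == 4

    def test_full_prevalence_drops_otu_absent_once(self):
        counts = np.ones((5, 2), dtype=int)
        counts[2, 1] = 0
        kept = prevalence_filter(_otu(counts), 1.0)
        assert kept.otu_ids == ["O0"]

    def test_no_survivor_is_an_error(self):
        counts = np.zeros((10, 3), dtype=int)
        for i in range(10):
            counts[i, i % 3] = 2  # every OTU present in only ~1/3 of samples
        with pytest.raises(ValueError, match="threshold"):
            prevalence_filter(_otu(counts), 0.9)


class TestCorrelationMatrix:
    def test_proportional_otus_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 50, size=12)
        counts = np.column_stack([a, 2 * a, rng.integers(1, 50, size=12)])
        corr = correlation_matrix(_otu(counts))
        i, j = corr.otu_ids.index("O0"), corr.otu_ids.index("O1")
        assert corr.values[i, j] == pytest.approx(1.0)
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)

    def test_independent_otus_have_zero_mean_correlation(self):
        """Two independent Poisson OTUs at n=45: the across-replicate
        mean correlation must vanish."""
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(1000):
            x = np.log10(rng.poisson(10, 45) + 0.5)
            y = np.log10(rng.poisson(10, 45) + 0.5)
            rs.append(np.corrcoef(x, y)[0, 1])
        assert abs(np.mean(rs)) < 0.02


class TestRMTThreshold:
    def test_exponential_spacings_classified_poisson(self):
        rng = np.random.default_rng(0)
        s = rng.exponential(1.0, 2000)
        chi2_p, chi2_g, _ = nnsd_chi2(s / s.mean())
        assert chi2_p < chi2_g

    def test_goe_matrix_classified_goe(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(200, 200))
        spacings = unfold_spacings(np.linalg.eigvalsh((a + a.T) / np.sqrt(2)))
        chi2_p, chi2_g, _ = nnsd_chi2(spacings)
        assert chi2_g < chi2_p

    def test_planted_blocks_recovered(self):
        """Five planted correlation blocks: the scan must settle inside
        the between/within gap and the thresholded graph must fall
        apart into exactly the five blocks."""
        labels, r, _ = planted_block_correlation(seed=3)
        scan = rmt_threshold(CorrelationMatrix(labels, r))
        assert 0.40 <= scan.selected_st <= 0.84
        g = build_network(CorrelationMatrix(labels, r), scan.selected_st)
        assert nx.number_connected_components(g) == 5
        assert g.number_of_nodes() == 100

    def test_retained_nodes_monotone_non_increasing(self):
        labels, r, _ = planted_block_correlation(seed=11)
        scan = rmt_threshold(CorrelationMatrix(labels, r))
        retained = scan.table["n_retained_nodes"].to_numpy()
        assert (np.diff(retained) <= 0).all()

    def test_no_transition_is_an_error(self):
        ids = [f"O{i}" for i in range(12)]
        m = np.full((12, 12), 0.95)
        np.fill_diagonal(m, 1.0)
        with pytest.raises(ValueError, match="no RMT transition"):
            rmt_threshold(CorrelationMatrix(ids, m))


class TestBuildNetwork:
    def test_threshold_above_max_correlation_is_error(self):
        ids = list("abc")
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 1.0)
        with pytest.raises(ValueError, match="no edge"):
            build_network(CorrelationMatrix(ids, m), 0.9)

    def test_triangle_construction(self):
        g = _triangle()
        assert (g.number_of_nodes(), g.number_of_edges()) == (3, 3)
        assert all(d["weight"] == pytest.approx(0.9)
                   for _, _, d in g.edges(data=True))

    def test_raising_threshold_never_adds_edges(self):
        labels, r, _ = planted_block_correlation(seed=5)
        corr = CorrelationMatrix(labels, r)
        g_low = build_network(corr, 0.5)
        g_high = build_network(corr, 0.88)
        low = {frozenset(e) for e in g_low.edges()}
        high = {frozenset(e) for e in g_high.edges()}
        assert high <= low
        assert set(g_high.nodes()) <= set(g_low.nodes())

    def test_negative_correlations_carry_sign(self):
        ids = list("abc")
        m = np.array([[1.0, -0.9, 0.85], [-0.9, 1.0, 0.1],
                      [0.85, 0.1, 1.0]])
        g = build_network(CorrelationMatrix(ids, m), 0.8)
        assert g["a"]["b"]["sign"] == -1
        assert g["a"]["c"]["sign"] == 1


class TestTopology:
    def test_triangle(self):
        t = network_topology(_triangle())
        assert (t.avg_k, t.gd, t.avg_cc) == (2.0, 1.0, 1.0)

    def test_path_graph(self):
        g = nx.path_graph(3)
        t = network_topology(nx.relabel_nodes(g, str))
        assert t.avg_k == pytest.approx(4 / 3)
        assert t.gd == pytest.approx(4 / 3)
        assert t.avg_cc == 0.0

    def test_two_point_degree_histogram_is_collinear(self):
        t = network_topology(nx.relabel_nodes(nx.star_graph(9), str))
        assert t.power_law_r2 == pytest.approx(1.0)


class TestModules:
    def test_two_disjoint_triangles(self):
        g = nx.union(nx.complete_graph(3), nx.complete_graph(3),
                     rename=("a", "b"))
        m = detect_modules(g)
        assert m.n_modules == 2
        assert m.modularity_q == pytest.approx(0.5)

    def test_complete_graph_is_one_module(self):
        m = detect_modules(nx.relabel_nodes(nx.complete_graph(5), str))
        assert (m.n_modules, m.modularity_q) == (1, 0.0)

    def test_planted_blocks_yield_high_ari(self):
        labels, r, truth = planted_block_correlation(seed=3)
        corr = CorrelationMatrix(labels, r)
        g = build_network(corr, 0.6)
        m = detect_modules(g)
        ari = adjusted_rand_score(truth, [m.membership[n] for n in labels])
        assert ari > 0.9

    def test_greedy_q_not_below_trivial_partition(self, small_bundle):
        core = prevalence_filter(small_bundle.otu, 0.9)
        corr = correlation_matrix(core)
        g = build_network(corr, 0.7)
        assert detect_modules(g).modularity_q >= 0.0


class TestNullModel:
    def _planted_graph(self):
        labels, r, _ = planted_block_correlation(seed=3)
        return build_network(CorrelationMatrix(labels, r), 0.6)

    def test_degree_sequence_exactly_conserved(self):
        g = self._planted_graph()
        rng = np.random.default_rng(0)
        emp = sorted(d for _, d in g.degree())
        for _ in range(20):
            r = rewire_degree_preserving(g, rng)
            assert sorted(d for _, d in r.degree()) == emp
            assert not any(u == v for u, v in r.edges())

    def test_same_seed_reproduces_ensemble(self):
        g = self._planted_graph()
        s1 = null_model_ensemble(g, n_random=10, seed=5).metrics
        s2 = null_model_ensemble(g, n_random=10, seed=5).metrics
        pd.testing.assert_frame_equal(s1, s2)

    def test_planted_modularity_exceeds_null_by_3_sd(self):
        g = self._planted_graph()
        stats = null_model_ensemble(g, n_random=50, seed=1).metrics
        row = stats.loc["modularity"]
        assert row["empirical"] > row["null_mean"] + 3 * row["null_sd"]


class TestNodeRoles:
    def test_internal_node_has_zero_participation(self):
        g = nx.union(nx.complete_graph(3), nx.complete_graph(3),
                     rename=("a", "b"))
        m = detect_modules(g)
        roles = {r.node: r for r in node_roles(g, m)}
        assert all(r.pi == 0.0 for r in roles.values())

    def test_even_split_participation(self):
        g = nx.Graph()
        g.add_edges_from([("x", "a1"), ("x", "a2"), ("x", "b1"),
                          ("x", "b2"), ("a1", "a2"), ("b1", "b2")])
        from paddynet.network import ModuleSet
        m = ModuleSet(membership={"x": 1, "a1": 1, "a2": 1,
                                  "b1": 2, "b2": 2}, modularity_q=0.0)
        roles = {r.node: r for r in node_roles(g, m)}
        assert roles["x"].pi == pytest.approx(0.5)

    def test_star_center_is_module_hub(self):
        g = nx.relabel_nodes(nx.star_graph(10), str)
        from paddynet.network import ModuleSet
        m = ModuleSet(membership={n: 1 for n in g.nodes()},
                      modularity_q=0.0)
        roles = {r.node: r for r in node_roles(g, m)}
        assert roles["0"].zi > 2.5
        assert roles["0"].role == "module_hub"

    def test_every_node_gets_exactly_one_role(self):
        labels, r, _ = planted_block_correlation(seed=7)
        g = build_network(CorrelationMatrix(labels, r), 0.6)
        m = detect_modules(g)
        roles = node_roles(g, m)
        assert sorted(x.node for x in roles) == sorted(g.nodes())
        valid = {"peripheral", "module_hub", "connector", "network_hub"}
        for x in roles:
            assert x.role in valid
            assert 0.0 <= x.pi <= 1.0 - 1.0 / m.n_modules + 1e-12


class TestModuleEnvironmentMantel:
    def test_responder_module_tracks_gradient(self, strong_bundle):
        """Module 1 is planted as a monotone pH responder; its
        community distance must associate with pH at n=45."""
        otu = strong_bundle.otu
        truth = strong_bundle.truth["module_of"]
        from paddynet.network import ModuleSet
        membership = {o: m for o, m in truth.items() if m is not None}
        table = otu.subset_otus(list(membership))
        m = ModuleSet(membership=membership, modularity_q=0.0)
        env = strong_bundle.soil.data[["ph"]]
        res = module_environment_mantel(table, m, env, permutations=199,
                                        seed=0, module_ids=[1, 3])
        p_responder = res.loc[res.module == 1, "p"].iloc[0]
        assert p_responder < 0.05

    def test_joint_sample_permutation_leaves_r_unchanged(self, small_bundle):
        otu = small_bundle.otu
        truth = small_bundle.truth["module_of"]
        from paddynet.network import ModuleSet
        membership = {o: m for o, m in truth.items() if m is not None}
        table = otu.subset_otus(list(membership))
        m = ModuleSet(membership=membership, modularity_q=0.0)
        env = small_bundle.soil.data[["ph"]]
        r1 = module_environment_mantel(table, m, env, permutations=99,
                                       seed=0, module_ids=[1])
        rng = np.random.default_rng(4)
        perm = rng.permutation(table.n_samples)
        shuffled = OTUTable(counts=table.counts.iloc[perm])
        r2 = module_environment_mantel(shuffled, m,
                                       env.iloc[perm], permutations=99,
                                       seed=0, module_ids=[1])
        assert r1["r"].iloc[0] == pytest.approx(r2["r"].iloc[0])

    def test_small_module_skipped_with_warning(self, small_bundle):
        from paddynet.network import ModuleSet
        otus = small_bundle.otu.otu_ids[:3]
        table = small_bundle.otu.subset_otus(otus)
        m = ModuleSet(membership={o: 1 for o in otus}, modularity_q=0.0)
        with pytest.warns(UserWarning, match="skipped"):
            out = module_environment_mantel(table, m,
                                            small_bundle.soil.data[["ph"]],
                                            permutations=99, seed=0)
        assert out.empty


class TestExport:
    @pytest.mark.parametrize("fmt, reader", [
        ("gexf", nx.read_gexf),
        ("graphml", nx.read_graphml),
    ])
    def test_roundtrip_preserves_counts(self, tmp_path, fmt, reader):
        labels, r, _ = planted_block_correlation(seed=3)
        g = build_network(CorrelationMatrix(labels, r), 0.6)
        m = detect_modules(g)
        roles = node_roles(g, m)
        path = tmp_path / f"net.{fmt}"
        export_network(g, m, roles, path, fmt=fmt)
        back = reader(path)
        assert back.number_of_nodes() == g.number_of_nodes()
        assert back.number_of_edges() == g.number_of_edges()
        modules_seen = {d["module"] for _, d in back.nodes(data=True)}
        assert len(modules_seen) == m.n_modules

    def test_triangle_edgelist(self, tmp_path):
        g = _triangle()
        m = detect_modules(g)
        path = tmp_path / "net.tsv"
        export_network(g, m, node_roles(g, m), path, fmt="edgelist_tsv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 4  # header + 3 edges
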
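"""Random walk with restart: operator, convergence, PDN, NGSEA."""

import networkx as nx
import numpy as np
import pytest

import endotrio as et
from endotrio.network_propagation import ConvergenceError, read_edge_list, seed_vector
from endotrio.set_enrichment import InvalidSpecError


def graph(*edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


class TestNormalizeAdjacency:
    def test_two_node(self):
        w, nodes = et.normalize_adjacency(graph(("g1", "g2")))
        assert nodes == ["g1", "g2"]
        assert np.allclose(w.toarray(), [[0, 1], [1, 0]])

    def test_triangle_columns_stochastic(self):
        w, _ = et.normalize_adjacency(graph(("a", "b"), ("b", "c"), ("a", "c")))
        assert np.allclose(np.asarray(w.sum(axis=0)).ravel(), 1.0)

    def test_isolated_node_zero_column(self):
        g = graph(("a", "b"))
        g.add_node("c")
        w, nodes = et.normalize_adjacency(g)
        assert np.asarray(w.sum(axis=0)).ravel()[nodes.index("c")] == 0.0

    def test_empty_network(self):
        with pytest.raises(InvalidSpecError):
            et.normalize_adjacency(nx.Graph())


class TestPropagate:
    def test_edgeless_fixed_point(self):
        g = nx.Graph()
        g.add_nodes_from(["g1", "g2", "g3"])
        st = et.propagate(g, ["g1"], alpha=0.3)
        assert st.f[st.nodes.index("g1")] == pytest.approx(0.3, abs=1e-9)
        assert st.f.sum() == pytest.approx(0.3, abs=1e-9)

    def test_two_node_closed_form(self):
        st = et.propagate(graph(("g1", "g2")), ["g1"], alpha=0.3)
        # alpha (I - 0.7 W)^-1 f0 = 0.3/(1-0.49) * (1, 0.7)
        assert st.f[0] == pytest.approx(0.5882, abs=1e-4)
        assert st.f[1] == pytest.approx(0.4118, abs=1e-4)

    def test_regular_graph_uniform_seed_is_fixed_point(self):
        g = nx.cycle_graph(6)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(6)})
        st = et.propagate(g, list(g.nodes))
        assert np.allclose(st.f, st.f0, atol=1e-8)

    def test_agrees_with_linear_solve(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            g = nx.gnp_random_graph(60, 0.08, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            seeds = [f"n{i}" for i in rng.choice(60, 5, replace=False)]
            it = et.propagate(g, seeds)
            cf = et.closed_form_flow(g, seeds)
            assert np.abs(it.f - cf.f).max() < 1e-6

    def test_flow_conservation_connected(self):
        g = nx.relabel_nodes(nx.barbell_graph(5, 2), lambda i: f"n{i}")
        st = et.propagate(g, ["n0", "n7"])
        assert abs(st.f.sum() - st.f0.sum()) < 1e-8

    def test_seed_edge_monotonicity(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            g = nx.gnp_random_graph(40, 0.1, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            seed = "n0"
            target = "n20"
            if g.has_edge(seed, target):
                g.remove_edge(seed, target)
            before = et.propagate(g, [seed]).flow_of(target)
            g.add_edge(seed, target)
            after = et.propagate(g, [seed]).flow_of(target)
            assert after >= before - 1e-12

    def test_nonnegative_and_unreachable_zero(self):
        g = graph(("a", "b"), ("c", "d"))  # two components
        st = et.propagate(g, ["a"])
        assert (st.f >= 0).all()
        assert st.flow_of("c") == 0.0 and st.flow_of("d") == 0.0

    def test_nonconvergence_raises(self):
        g = nx.relabel_nodes(nx.path_graph(30), lambda i: f"n{i}")
        with pytest.raises(ConvergenceError):
            et.propagate(g, ["n0"], max_iter=2)

    def test_invalid_alpha(self):
        with pytest.raises(InvalidSpecError):
            et.propagate(graph(("a", "b")), ["a"], alpha=1.0)

    def test_no_seeds_in_network(self):
        with pytest.raises(InvalidSpecError):
            et.propagate(graph(("a", "b")), ["zzz"])


class TestPdnSum:
    def test_cases(self):
        g = graph(("g1", "g2"))
        st = et.propagate(g, ["g1"])
        assert et.pdn_sum(st, [], ["g1"]) == 0.0
        assert et.pdn_sum(st, ["g2"], ["g1"]) == pytest.approx(0.4118, abs=1e-4)
        assert et.pdn_sum(st, ["g1"], ["g1"]) == 0.0  # seeds excluded (novelty)
        assert et.pdn_sum(st, ["absent"], ["g1"]) == 0.0


@pytest.fixture(scope="module")
def setting():
    u = et.generate_gene_universe(800, seed=31)
    genes = u["gene"].tolist()
    seeds = genes[:15]
    module = genes[15:25]
    net = et.generate_network(
        800, planted_module=module, seed=32, genes=genes, anchor_genes=seeds
    )
    return u, net, seeds, module


class TestNgsea:

    def test_planted_module_detected(self, setting):
        u, net, seeds, module = setting
        res = et.ngsea(module, seeds, net, u, n_null=300, seed=1)
        assert res.empirical_p < 0.05

    def test_random_candidates_not_flagged(self, setting):
        u, net, seeds, _ = setting
        rng = np.random.default_rng(4)
        ps = []
        for rep in range(20):
            cand = list(rng.choice(u["gene"][100:], 10, replace=False))
            ps.append(et.ngsea(cand, seeds, net, u, n_null=200,
                               seed=rng).empirical_p)
        assert np.median(ps) > 0.1  # roughly uniform, not anti-conservative

    def test_absent_candidates_give_p_one(self):
        u = et.generate_gene_universe(600, seed=33)
        genes = u["gene"].tolist()
        net = et.generate_network(300, seed=34, genes=genes[:300])
        cand = genes[400:420]  # in universe, absent from network
        res = et.ngsea(cand, genes[:10], net, u, n_null=100, seed=2)
        assert res.observed == 0.0
        assert res.empirical_p == pytest.approx(1.0)

    def test_no_seeds_error(self, setting):
        u, net, _, module = setting
        with pytest.raises(InvalidSpecError):
            et.ngsea(module, ["NOPE"], net, u, n_null=10, seed=0)


def test_edge_list_roundtrip(tmp_path):
    from endotrio.synthetic_data import write_edge_list

    g = graph(("a", "b"), ("b", "c"))
    path = tmp_path / "net.tsv"
    write_edge_list(g, path)
    back = read_edge_list(path)
    assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))


def test_sif_accepted(tmp_path):
    path = tmp_path / "net.sif"
    path.write_text("a\tpp\tb\nb\tpp\tc\n")
    g = read_edge_list(path)
    assert g.number_of_edges() == 2
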
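import networkx as nx
import numpy as np
import pytest
from scipy import sparse

from cognet.svo_structure import (
    InsufficientDataError,
    NoFitError,
    articulation_share,
    degeneracy,
    gn_clusters,
    neighborhood_valence_test,
    sample_soft_configuration,
    shrinkage_factor,
    soft_cm_shrinkage_null,
    tail_exponent,
    two_proportion_chi2,
)
from cognet.synthetic import sample_discrete_power_law
from conftest import valenced_graph


def csgraph_gc_sizes(G, removed=None):
    """Independent oracle for giant-component bookkeeping via scipy."""
    nodes = [n for n in G.nodes if n != removed]
    if not nodes:
        return {}
    idx = {n: i for i, n in enumerate(nodes)}
    rows, cols = [], []
    for a, b in G.edges():
        if removed in (a, b):
            continue
        rows += [idx[a], idx[b]]
        cols += [idx[b], idx[a]]
    m = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(nodes), len(nodes))
    )
    _, labels = sparse.csgraph.connected_components(m.tocsr(), directed=False)
    comps = {}
    for n, lab in zip(nodes, labels):
        comps.setdefault(lab, set()).add(n)
    return comps


class TestDegeneracy:
    @pytest.mark.parametrize("n_leaves", [2, 5, 20])
    def test_stars_reach_one(self, n_leaves):
        assert degeneracy(nx.star_graph(n_leaves)) == pytest.approx(1.0)

    @pytest.mark.parametrize("G", [nx.complete_graph(4), nx.cycle_graph(9)])
    def test_regular_graphs_are_zero(self, G):
        assert degeneracy(G) == pytest.approx(0.0)

    def test_path3_is_a_star(self):
        assert degeneracy(nx.path_graph(3)) == pytest.approx(1.0)

    def test_small_graphs_rejected(self):
        with pytest.raises(ValueError):
            degeneracy(nx.path_graph(2))

    def test_disconnected_rejected(self):
        G = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            degeneracy(G)

    def test_bounded_between_zero_and_one(self, rng):
        for _ in range(20):
            G = nx.gnp_random_graph(12, 0.4, seed=int(rng.integers(2**31)))
            if G.number_of_nodes() < 3 or not nx.is_connected(G):
                continue
            assert 0.0 <= degeneracy(G) <= 1.0 + 1e-12


class TestTailFit:
    def test_recovers_planted_exponent(self):
        x = sample_discrete_power_law(2.0, xmin=5, size=2000, seed=11)
        fit = tail_exponent(x)
        assert 1.85 <= fit.gamma <= 2.15
        assert fit.n_tail >= 10

    def test_all_equal_rejected(self):
        with pytest.raises(NoFitError):
            tail_exponent([3] * 100)

    def test_too_few_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            tail_exponent([1, 2, 3])

    def test_exponential_tail_truncates_hard(self):
        # a geometric sample is not scale-free: the KS-optimal cutoff
        # climbs deep into the tail, a diagnostic of a poor power law
        x = np.random.default_rng(4).geometric(0.05, size=2000)
        fit = tail_exponent(x)
        assert fit.n_tail < len(x) // 2


class TestShrinkage:
    def test_star_examples(self):
        star = nx.star_graph(5)  # N = 6
        assert shrinkage_factor(star, 0) == pytest.approx(1 - 1 / 6)
        assert shrinkage_factor(star, 3) == pytest.approx(1 - 5 / 6)

    def test_triangle(self):
        assert shrinkage_factor(nx.complete_graph(3), 0) == pytest.approx(1 / 3)

    def test_absent_node(self):
        with pytest.raises(KeyError):
            shrinkage_factor(nx.path_graph(3), "missing")

    def test_matches_component_oracle_on_random_graphs(self, rng):
        for _ in range(25):
            G = nx.gnp_random_graph(
                int(rng.integers(10, 60)), 0.08, seed=int(rng.integers(2**31))
            )
            gc = max(nx.connected_components(G), key=len)
            node = sorted(gc)[int(rng.integers(len(gc)))]
            comps = csgraph_gc_sizes(G.subgraph(gc), removed=node)
            rest = max((len(c) for c in comps.values()), default=0)
            assert shrinkage_factor(G, node) == pytest.approx(1 - rest / len(gc))


class TestArticulation:
    def test_star_hub_and_leaf(self):
        star = nx.star_graph(5)
        for n in star:
            star.nodes[n]["valence"] = "neutral"
        n_dep, frac, _ = articulation_share(star, 0)
        assert (n_dep, frac) == (5, 5 / 6)
        assert articulation_share(star, 1)[0] == 0

    def test_two_connected_graph_has_no_dependents(self):
        tri = nx.complete_graph(3)
        assert articulation_share(tri, 0) == (0, 0.0, 0.0)

    def test_negative_dependence_fraction(self):
        star = nx.star_graph(5)
        vals = {0: "neutral", 1: "negative", 2: "negative"}
        for n in star:
            star.nodes[n]["valence"] = vals.get(n, "positive")
        n_dep, _, frac_neg = articulation_share(star, 0)
        assert n_dep == 5 and frac_neg == 1.0

    def test_matches_component_oracle(self, rng):
        for _ in range(25):
            G = nx.gnp_random_graph(
                int(rng.integers(10, 80)), 0.05, seed=int(rng.integers(2**31))
            )
            for n in G:
                G.nodes[n]["valence"] = "neutral"
            gc = max(nx.connected_components(G), key=len)
            node = sorted(gc)[int(rng.integers(len(gc)))]
            comps = csgraph_gc_sizes(G.subgraph(gc), removed=node).values()
            expected = sum(len(c) for c in comps if len(c) < (len(gc) - 1) / 2)
            assert articulation_share(G, node)[0] == expected


class TestSoftConfigurationModel:
    def test_expected_strengths_preserved(self):
        G = nx.Graph()
        G.add_weighted_edges_from(
            [("a", "b", 3), ("b", "c", 2), ("c", "d", 5), ("d", "a", 1), ("a", "c", 2)]
        )
        target = dict(G.degree(weight="weight"))
        sums = {n: 0.0 for n in target}
        sq = {n: 0.0 for n in target}
        n_real = 600
        for r in range(n_real):
            H = sample_soft_configuration(target, seed=r)
            s = dict(H.degree(weight="weight"))
            for n in target:
                sums[n] += s.get(n, 0)
                sq[n] += s.get(n, 0) ** 2
        for n, t in target.items():
            mean = sums[n] / n_real
            sd = np.sqrt(sq[n] / n_real - mean**2)
            assert abs(mean - t) <= 3 * sd / np.sqrt(n_real)

    def test_null_median_gives_p_near_one(self):
        G = nx.cycle_graph(10)
        nx.set_edge_attributes(G, 1, "weight")
        out = soft_cm_shrinkage_null(G, [0], n_realizations=200, seed=2)
        # a typical node of a homogeneous graph is not an outlier
        assert out[0].p_value > 0.05
        assert out[0].outlier == "typical"

    def test_planted_star_hub_is_positive_outlier(self):
        G = nx.star_graph(12)
        nx.set_edge_attributes(G, 1, "weight")
        out = soft_cm_shrinkage_null(G, [0], n_realizations=300, seed=5)
        assert out[0].observed > out[0].centile_99
        assert out[0].outlier == "positive"

    def test_zero_strength_node_excluded(self):
        G = nx.path_graph(5)
        nx.set_edge_attributes(G, 1, "weight")
        G.add_node("isolated")
        with pytest.raises(InsufficientDataError):
            soft_cm_shrinkage_null(G, ["isolated"], n_realizations=100, seed=0)


class TestGnClusters:
    def test_bridge_between_triangles(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        assert gn_clusters(G, 2) == [{0, 1, 2}, {3, 4, 5}]

    def test_k1_returns_giant_component(self):
        G = nx.path_graph(6)
        assert gn_clusters(G, 1) == [set(range(6))]

    def test_star_cut_is_valid_partition(self):
        G = nx.star_graph(6)
        parts = gn_clusters(G, 2)
        assert sum(len(p) for p in parts) == 7
        assert set().union(*parts) == set(G.nodes)

    def test_partition_property_random_graph(self, rng):
        G = nx.gnp_random_graph(18, 0.2, seed=9)
        gc = max(nx.connected_components(G), key=len)
        for k in (2, 3, 5):
            parts = gn_clusters(G, k)
            assert len(parts) >= k
            assert set().union(*parts) == gc
            assert sum(len(p) for p in parts) == len(gc)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            gn_clusters(nx.path_graph(4), 10)

    def test_deterministic(self):
        G = nx.gnp_random_graph(15, 0.25, seed=2)
        assert gn_clusters(G, 3) == gn_clusters(G, 3)


class TestNeighborhoodValence:
    def test_closed_form_example(self):
        # 30/100 vs 10/100 negative, pooled p = 0.2 -> chi2 = 12.5
        chi2, p = two_proportion_chi2(30, 100, 10, 100)
        assert chi2 == pytest.approx(12.5)
        assert 0 < p < 0.001

    def test_identical_proportions(self):
        chi2, p = two_proportion_chi2(5, 50, 5, 50)
        assert chi2 == 0.0 and p == 1.0

    def test_star_negative_neighborhood(self):
        G = nx.star_graph(10)
        for n in G:
            G.nodes[n]["valence"] = "negative" if 1 <= n <= 8 else "positive"
        G.add_edges_from((i, 100 + i) for i in range(1, 6))
        for i in range(1, 6):
            G.nodes[100 + i]["valence"] = "positive"
        res = neighborhood_valence_test(G, 0)
        assert res.p_neg_in > res.p_neg_out
        assert res.chi2_neg > 0

    def test_few_neighbors_rejected(self):
        G = nx.path_graph(10)
        for n in G:
            G.nodes[n]["valence"] = "neutral"
        with pytest.raises(InsufficientDataError):
            neighborhood_valence_test(G, 0)

    def test_empty_comparison_group_rejected(self):
        G = nx.star_graph(6)
        for n in G:
            G.nodes[n]["valence"] = "neutral"
        with pytest.raises(InsufficientDataError):
            neighborhood_valence_test(G, 0)
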
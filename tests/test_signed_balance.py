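import itertools

import networkx as nx
import numpy as np
import pytest

from cognet.signed_balance import (
    NullDistribution,
    TriadCensus,
    UndefinedStatisticError,
    ValenceError,
    balance_report,
    configuration_null,
    degree_of_balance,
    edge_sign,
    label_shuffle_null,
    rewire_preserving_degrees,
    shuffle_valences,
    sign_edges,
    triad_census,
)
from conftest import random_valenced_graph, valenced_graph

VALS = ("positive", "negative", "neutral")


def brute_force_census(G):
    """Independent oracle: cubic triple loop with the node-valence rule."""
    nodes = list(G.nodes)
    ppp = pmm = mmm = excl = 0
    for a, b, c in itertools.combinations(nodes, 3):
        if not (G.has_edge(a, b) and G.has_edge(b, c) and G.has_edge(a, c)):
            continue
        vals = [G.nodes[x]["valence"] for x in (a, b, c)]
        if vals.count("neutral") >= 2:
            excl += 1
        elif vals.count("negative") >= 2:
            mmm += 1
        elif vals.count("negative") == 1:
            pmm += 1
        else:
            ppp += 1
    return ppp, pmm, mmm, excl


class TestEdgeSign:
    @pytest.mark.parametrize(
        "a, b, sign",
        [
            ("positive", "positive", 1),
            ("positive", "neutral", 1),
            ("neutral", "neutral", 0),
            ("negative", "positive", -1),
            ("negative", "neutral", -1),
            ("negative", "negative", -1),
        ],
    )
    def test_rule(self, a, b, sign):
        assert edge_sign(a, b) == sign == edge_sign(b, a)

    def test_unknown_valence_rejected(self):
        G = valenced_graph([("a", "b")], {"a": "positive", "b": "unknown"})
        with pytest.raises(ValenceError, match="b"):
            sign_edges(G)

    def test_sign_attribute_set_everywhere(self):
        G = valenced_graph(
            [("a", "b"), ("b", "c")],
            {"a": "positive", "b": "negative", "c": "neutral"},
        )
        S = sign_edges(G)
        assert all("sign" in d for _, _, d in S.edges(data=True))


class TestTriadTaxonomy:
    def test_plus_plus_minus_is_impossible(self):
        """No valence assignment induces the {+,+,-} signed triangle."""
        for vals in itertools.product(VALS, repeat=3):
            signs = sorted(
                (
                    edge_sign(vals[0], vals[1]),
                    edge_sign(vals[1], vals[2]),
                    edge_sign(vals[0], vals[2]),
                )
            )
            assert signs != [-1, 1, 1]

    def test_classification_matches_majority_rule(self):
        tri = nx.complete_graph(3)
        for vals in itertools.product(VALS, repeat=3):
            for n, v in zip(tri.nodes, vals):
                tri.nodes[n]["valence"] = v
            census = triad_census(tri)
            n_neu = vals.count("neutral")
            n_neg = vals.count("negative")
            if n_neu >= 2:
                assert census.n_excluded == 1
            elif n_neg >= 2:
                assert census.n_mmm == 1
            elif n_neg == 1:
                assert census.n_pmm == 1
            else:
                assert census.n_ppp == 1

    @pytest.mark.parametrize(
        "vals, attr",
        [
            (("positive", "positive", "negative"), "n_pmm"),
            (("negative", "negative", "neutral"), "n_mmm"),
            (("neutral", "neutral", "positive"), "n_excluded"),
        ],
    )
    def test_examples(self, vals, attr):
        tri = valenced_graph(
            [(0, 1), (1, 2), (0, 2)], dict(zip(range(3), vals))
        )
        assert getattr(triad_census(tri), attr) == 1

    def test_census_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(20):
            G = random_valenced_graph(rng, int(rng.integers(5, 25)))
            c = triad_census(G)
            assert (c.n_ppp, c.n_pmm, c.n_mmm, c.n_excluded) == brute_force_census(G)

    def test_no_triangles_flagged(self):
        G = valenced_graph([(0, 1), (1, 2)], {i: "positive" for i in range(3)})
        census = triad_census(G)
        assert census.dob is None
        with pytest.raises(UndefinedStatisticError):
            degree_of_balance(census)


class TestDegreeOfBalance:
    @pytest.mark.parametrize(
        "census, dob",
        [
            (TriadCensus(10, 0, 0, 5), 1.0),
            (TriadCensus(0, 0, 7, 0), 0.0),
            (TriadCensus(3, 1, 4, 0), 0.5),
        ],
    )
    def test_arithmetic(self, census, dob):
        assert degree_of_balance(census) == dob


class TestConfigurationNull:
    def test_degree_sequence_and_connectivity_preserved(self, rng):
        G = random_valenced_graph(rng, 15, p=0.35)
        G = G.subgraph(max(nx.connected_components(G), key=len)).copy()
        for s in range(5):
            H = rewire_preserving_degrees(G, seed=s)
            assert dict(H.degree()) == dict(G.degree())
            assert nx.is_connected(H)
            assert nx.get_node_attributes(H, "valence") == nx.get_node_attributes(
                G, "valence"
            )

    def test_all_positive_graph_degenerate_at_one(self, rng):
        G = nx.gnp_random_graph(12, 0.5, seed=3)
        for n in G:
            G.nodes[n]["valence"] = "positive"
        nulls = configuration_null(G, n_realizations=20, seed=0)
        assert nulls["dob"].mean == 1.0 and nulls["dob"].sd == 0.0

    def test_matches_independent_mcmc_oracle(self, rng):
        """Null triad fractions agree with a long, independently coded
        double-edge-swap chain on a small graph."""
        G = random_valenced_graph(rng, 8, p=0.5)
        G = G.subgraph(max(nx.connected_components(G), key=len)).copy()
        nulls = configuration_null(G, n_realizations=200, seed=1)

        # oracle: plain Metropolis-style swap chain, thinned samples
        chain = G.copy()
        edges = [tuple(e) for e in chain.edges()]
        oracle_samples = {"frac_ppp": [], "frac_pmm": [], "frac_mmm": [], "dob": []}
        orng = np.random.default_rng(99)
        for step in range(40000):
            (a, b), (c, d) = (
                edges[orng.integers(len(edges))],
                edges[orng.integers(len(edges))],
            )
            if orng.random() < 0.5:  # both swap pairings must be proposable
                a, b = b, a
            if (
                len({a, b, c, d}) == 4
                and not chain.has_edge(a, d)
                and not chain.has_edge(c, b)
            ):
                chain.remove_edges_from([(a, b), (c, d)])
                chain.add_edges_from([(a, d), (c, b)])
                if not nx.is_connected(chain):
                    chain.remove_edges_from([(a, d), (c, b)])
                    chain.add_edges_from([(a, b), (c, d)])
                edges = [tuple(e) for e in chain.edges()]
            if step % 200 == 0 and step > 2000:
                fr = {}
                ppp, pmm, mmm, _ = brute_force_census(chain)
                tot = ppp + pmm + mmm
                if tot == 0:
                    continue
                oracle_samples["frac_ppp"].append(ppp / tot)
                oracle_samples["frac_pmm"].append(pmm / tot)
                oracle_samples["frac_mmm"].append(mmm / tot)
                oracle_samples["dob"].append((ppp + pmm) / tot)

        for stat, dist in nulls.items():
            osamp = np.array(oracle_samples[stat])
            se = np.sqrt(
                dist.sd**2 / dist.n_realizations + osamp.var(ddof=1) / len(osamp)
            )
            assert abs(dist.mean - osamp.mean()) <= 3 * max(se, 1e-12) + 1e-9


class TestLabelShuffleNull:
    def test_adjacency_and_label_multiset_preserved(self, rng):
        G = random_valenced_graph(rng, 12, p=0.4)
        for s in range(5):
            H = shuffle_valences(G, seed=s)
            assert set(H.edges()) == set(G.edges())
            assert sorted(nx.get_node_attributes(H, "valence").values()) == sorted(
                nx.get_node_attributes(G, "valence").values()
            )

    def test_identical_labels_degenerate(self):
        G = nx.complete_graph(6)
        for n in G:
            G.nodes[n]["valence"] = "negative"
        observed = triad_census(G)
        nulls = label_shuffle_null(G, n_realizations=50, seed=0)
        assert nulls["dob"].sd == 0.0
        assert nulls["dob"].mean == observed.dob == 0.0


class TestBalanceReport:
    def test_z_arithmetic_and_degenerate_flag(self):
        observed = TriadCensus(9, 0, 1, 0)  # dob = 0.9
        good = NullDistribution("dob", np.array([0.5, 0.6, 0.7]))
        # samples 0.5/0.6/0.7: mean 0.6, sd 0.1 -> z = 3
        nulls = {
            "m": {
                "frac_ppp": NullDistribution("frac_ppp", np.array([0.9, 0.9])),
                "frac_pmm": NullDistribution("frac_pmm", np.array([0.0, 0.0])),
                "frac_mmm": NullDistribution("frac_mmm", np.array([0.1, 0.1])),
                "dob": good,
            }
        }
        rep = balance_report(observed, nulls).set_index("statistic")
        assert rep.loc["dob", "z"] == pytest.approx(3.0)
        assert np.isnan(rep.loc["frac_ppp", "z"])  # degenerate null sd = 0

    def test_observed_equal_null_mean_gives_zero(self):
        dist = NullDistribution("dob", np.array([0.4, 0.5, 0.6]))
        assert dist.z(0.5) == 0.0
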
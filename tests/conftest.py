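import networkx as nx
import numpy as np
import pytest

from cognet.corpus_io import Sentence, Token


def make_sentence(words, doc_id="d0", stopwords=()):
    return Sentence(
        tuple(
            Token(surface=w, lemma=w, is_stopword=w in stopwords) for w in words
        ),
        doc_id,
    )


def valenced_graph(edges, valences):
    """Graph from an edge list with per-node valence attributes."""
    G = nx.Graph()
    G.add_edges_from(edges, weight=1)
    for n, v in valences.items():
        G.nodes[n]["valence"] = v
    return G


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_valenced_graph(rng, n, p=0.3):
    G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    vals = rng.choice(["positive", "negative", "neutral"], size=n)
    for i, v in zip(G.nodes, vals):
        G.nodes[i]["valence"] = str(v)
    nx.set_edge_attributes(G, 1, "weight")
    return G
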
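"""Large-scale structure of SVO networks: hubs, heavy tails, star-degeneracy,
component shrinkage, clusters, and neighborhood valence contrasts.

The guiding question is whether a network is organized around a small
set of actor hubs (in narrative corpora, typically the self pronoun):

* ``tail_exponent`` — maximum-likelihood discrete power-law fit to the
  node-strength distribution, lower cutoff chosen by KS-distance
  minimization;
* ``degeneracy`` — a [0, 1] statistic of star-likeness: how
  concentrated the position of a one-step random walk from a uniformly
  random start is (1 only on perfect stars, 0 on regular graphs);
* ``shrinkage_factor`` — relative loss of giant-component nodes when a
  node is deleted, compared against a strength-preserving (soft
  configuration model) null;
* ``articulation_share`` — how much of the network hangs off a single
  node, overall and restricted to negative words;
* ``gn_clusters`` — Girvan-Newman divisive communities on the
  unweighted topology;
* ``neighborhood_valence_test`` — pooled two-proportion chi-square
  contrasting the valence mix of a node's neighborhood with the rest
  of the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse, stats
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .signed_balance import NullDistribution

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    pass


class NoFitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# heavy-tail fit

@dataclass
class TailFit:
    """Discrete power-law fit P(X = x) ∝ x^(-gamma), x >= xmin."""

    gamma: float
    xmin: int
    n_tail: int
    ks: float


def _fit_gamma(tail: np.ndarray, xmin: int) -> tuple[float, float]:
    """ML exponent and KS distance for a fixed lower cutoff."""
    n = len(tail)
    slog = np.log(tail).sum()

    def nll(g: float) -> float:
        return n * np.log(zeta(g, xmin)) + g * slog

    res = minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
    g = float(res.x)
    xs = np.arange(xmin, tail.max() + 1)
    # model CDF via the Hurwitz zeta survival function
    surv = zeta(g, xs + 1) / zeta(g, xmin)
    cdf_model = 1.0 - surv
    cdf_emp = np.searchsorted(np.sort(tail), xs, side="right") / n
    ks = float(np.abs(cdf_emp - cdf_model).max())
    return g, ks


def tail_exponent(
    strengths, min_tail: int = 10, max_candidates: int = 100
) -> TailFit:
    """Fit a discrete power law to the tail of a strength distribution.

    The lower cutoff ``xmin`` scans the unique observed values
    (subsampled to at most ``max_candidates``); for each, the exponent
    is the discrete MLE and the cutoff minimizing the Kolmogorov-
    Smirnov distance between the tail and its fit wins. Fits with
    fewer than ``min_tail`` tail points are not considered.
    """
    x = np.asarray(list(strengths), dtype=float)
    if len(x) < 50:
        raise InsufficientDataError("need >= 50 strength values")
    x = np.round(x).astype(np.int64)
    x = x[x >= 1]
    uniq = np.unique(x)
    if len(uniq) < 2:
        raise NoFitError("degenerate strengths (all equal)")
    candidates = [u for u in uniq if (x >= u).sum() >= min_tail]
    if not candidates:
        raise NoFitError(f"no cutoff leaves >= {min_tail} tail points")
    if len(candidates) > max_candidates:
        idx = np.linspace(0, len(candidates) - 1, max_candidates).astype(int)
        candidates = [candidates[i] for i in np.unique(idx)]
    best: TailFit | None = None
    for xmin in candidates:
        tail = x[x >= xmin]
        g, ks = _fit_gamma(tail, int(xmin))
        if best is None or ks < best.ks:
            best = TailFit(gamma=g, xmin=int(xmin), n_tail=len(tail), ks=ks)
    assert best is not None
    if best.gamma <= 1:
        raise NoFitError("fitted exponent not in the power-law regime")
    return best


# ---------------------------------------------------------------------------
# star-degeneracy

def degeneracy(G: nx.Graph) -> float:
    """Star-likeness of a connected graph, in [0, 1].

    Let pi(v) be the probability that one uniform random-walk step
    from a uniformly random node lands on v:
    pi(v) = (1/N) * sum over neighbors u of 1/deg(u). Then
    D = (N * max_v pi(v) - 1) / (N - 2): 1 exactly on perfect stars
    (every step lands on the hub), 0 on any regular graph (uniform
    landing distribution).
    """
    n = G.number_of_nodes()
    if n < 3:
        raise ValueError("degeneracy undefined for fewer than 3 nodes")
    if not nx.is_connected(G):
        raise ValueError("degeneracy requires a connected graph")
    deg = dict(G.degree())
    pi_max = max(sum(1.0 / deg[u] for u in G[v]) / n for v in G)
    return (n * pi_max - 1.0) / (n - 2.0)


# ---------------------------------------------------------------------------
# giant-component shrinkage

def _giant_component(G: nx.Graph) -> set:
    return max(nx.connected_components(G), key=len)


def shrinkage_factor(G: nx.Graph, node) -> float:
    """Relative node loss of the giant component when ``node`` is deleted.

    1 - |GC(G - node)| / |GC(G)|, both sizes in node counts.
    """
    if node not in G:
        raise KeyError(node)
    gc = _giant_component(G)
    if node not in gc:
        raise ValueError(f"{node!r} is not in the giant component")
    H = G.subgraph(gc - {node})
    rest = max((len(c) for c in nx.connected_components(H)), default=0)
    return 1.0 - rest / len(gc)


def articulation_share(G: nx.Graph, node) -> tuple[int, float, float]:
    """How much of the giant component depends on one node.

    Returns ``(n_dependent, fraction_of_gc, fraction_of_negative)``:
    the number of nodes whose every path to the bulk of the giant
    component runs through ``node``, that count as a fraction of the
    giant component, and the fraction of the giant component's
    negative-valence words (the node itself excluded) that are among
    the dependents. A node counts as dependent when its component
    after the removal holds strictly less than half of the remaining
    nodes — the minority fragments split off by the removal (on a
    star this is every leaf; on a 2-connected graph, nobody).
    """
    if node not in G:
        raise KeyError(node)
    gc = _giant_component(G)
    if node not in gc:
        raise ValueError(f"{node!r} is not in the giant component")
    comps = list(nx.connected_components(G.subgraph(gc - {node})))
    n_rest = len(gc) - 1
    dependents: set = set()
    for c in comps:
        if len(c) < n_rest / 2:
            dependents |= c
    negatives = {
        v for v in gc - {node} if G.nodes[v].get("valence") == "negative"
    }
    frac_neg = (len(dependents & negatives) / len(negatives)) if negatives else 0.0
    return len(dependents), len(dependents) / len(gc), frac_neg


# ---------------------------------------------------------------------------
# soft configuration model

def sample_soft_configuration(
    strengths: dict, seed: int | np.random.Generator | None = None
) -> nx.Graph:
    """Sample one weighted graph with the given expected strengths.

    Edge (i, j), i < j, receives an integer weight drawn from a
    Poisson law with mean s_i * s_j / (2W), W the half-sum of
    strengths; zero-weight pairs are absent. Self-loops are kept
    (mean s_i^2 / (4W), counting twice toward strength, the usual
    Chung-Lu convention), which makes E[strength_i] = s_i exact;
    they are irrelevant to connectivity.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(strengths)
    s = np.array([strengths[n] for n in nodes], dtype=float)
    two_w = s.sum()
    if two_w <= 0:
        raise ValueError("total strength must be positive")
    mean = np.outer(s, s) / two_w
    iu = np.triu_indices(len(s), k=1)
    w = rng.poisson(mean[iu])
    H = nx.Graph()
    H.add_nodes_from(nodes)
    nz = np.nonzero(w)[0]
    H.add_edges_from(
        (nodes[iu[0][k]], nodes[iu[1][k]], {"weight": int(w[k])}) for k in nz
    )
    loops = rng.poisson(s * s / (2 * two_w))
    for i in np.nonzero(loops)[0]:
        H.add_edge(nodes[i], nodes[i], weight=int(loops[i]))
    return H


@dataclass
class ShrinkageNull:
    """Per-node shrinkage under the soft configuration model."""

    node: object
    observed: float
    null: NullDistribution
    centile_1: float
    centile_99: float
    p_value: float

    @property
    def outlier(self) -> str:
        if self.observed > self.centile_99:
            return "positive"
        if self.observed < self.centile_1:
            return "negative"
        return "typical"


def _gc_shrinkages(adj: np.ndarray, targets: list[int]) -> list[float]:
    """Shrinkage of each target index in a dense 0/1 adjacency matrix."""
    graph = sparse.csr_matrix(adj)
    n_comp, labels = sparse.csgraph.connected_components(graph, directed=False)
    sizes = np.bincount(labels)
    gc_label = int(np.argmax(sizes))
    gc_size = int(sizes[gc_label])
    out = []
    for t in targets:
        if labels[t] != gc_label:
            out.append(0.0)
            continue
        keep = np.flatnonzero(labels == gc_label)
        keep = keep[keep != t]
        sub = adj[np.ix_(keep, keep)]
        _, lab2 = sparse.csgraph.connected_components(
            sparse.csr_matrix(sub), directed=False
        )
        rest = int(np.bincount(lab2).max()) if len(lab2) else 0
        out.append(1.0 - rest / gc_size)
    return out


def soft_cm_shrinkage_null(
    G: nx.Graph,
    nodes: list,
    n_realizations: int = 1000,
    seed: int | None = None,
) -> dict[object, ShrinkageNull]:
    """Shrinkage null for selected nodes under the soft configuration model.

    Each realization resamples the whole weighted network conditional
    on expected strengths, then recomputes every target node's
    shrinkage factor. Reported per node: 1st/99th centiles of the
    null and a two-sided empirical p-value (with the standard +1
    continuity correction). Zero-strength targets are excluded with a
    log message. Targets absent from a realization's giant component
    contribute shrinkage 0 for that realization.
    """
    if n_realizations < 100:
        raise ValueError("n_realizations must be >= 100")
    strengths = dict(G.degree(weight="weight"))
    targets = []
    for v in nodes:
        if strengths.get(v, 0) <= 0:
            logger.info("excluding zero-strength node %r from shrinkage null", v)
        else:
            targets.append(v)
    if not targets:
        raise InsufficientDataError("no positive-strength target nodes")
    observed = {v: shrinkage_factor(G, v) for v in targets}

    order = sorted(strengths)
    pos = {n: i for i, n in enumerate(order)}
    t_idx = [pos[v] for v in targets]
    rng = np.random.default_rng(seed)
    samples = np.empty((n_realizations, len(targets)))
    for r in range(n_realizations):
        H = sample_soft_configuration(strengths, rng)
        adj = nx.to_numpy_array(H, nodelist=order, weight=None)
        samples[r] = _gc_shrinkages(adj, t_idx)

    out = {}
    for j, v in enumerate(targets):
        col = samples[:, j]
        obs = observed[v]
        p_lo = (1 + (col <= obs).sum()) / (1 + n_realizations)
        p_hi = (1 + (col >= obs).sum()) / (1 + n_realizations)
        out[v] = ShrinkageNull(
            node=v,
            observed=obs,
            null=NullDistribution(f"shrinkage[{v}]", col, seed=seed),
            centile_1=float(np.percentile(col, 1)),
            centile_99=float(np.percentile(col, 99)),
            p_value=float(min(1.0, 2 * min(p_lo, p_hi))),
        )
    return out


# ---------------------------------------------------------------------------
# communities

def _most_valuable_edge(H: nx.Graph):
    """Deterministic GN step: max betweenness, lexicographic tie-break."""
    bet = nx.edge_betweenness_centrality(H, weight=None)
    best = max(bet.values())
    ties = [tuple(sorted(e, key=str)) for e, b in bet.items() if b >= best - 1e-12]
    return min(ties)


def gn_clusters(G: nx.Graph, k: int) -> list[set]:
    """Girvan-Newman communities of the giant component, cut at k blocks.

    Edge weights are ignored (pure topology). Ties in edge
    betweenness break lexicographically, making the divisive sequence
    deterministic. Returns the first partition with at least ``k``
    blocks, sorted by decreasing size.
    """
    gc = _giant_component(G)
    if k < 1 or k > len(gc):
        raise ValueError(f"k must be in [1, {len(gc)}]")
    sub = G.subgraph(gc).copy()
    if k == 1:
        return [set(gc)]
    for partition in nx.community.girvan_newman(
        sub, most_valuable_edge=_most_valuable_edge
    ):
        if len(partition) >= k:
            return sorted(
                (set(c) for c in partition), key=lambda c: (-len(c), min(map(str, c)))
            )
    raise RuntimeError("GN did not reach the requested number of clusters")


def cluster_report(G: nx.Graph, partition: list[set]) -> list[dict]:
    """Per-cluster valence mix and star-degeneracy (induced subgraphs)."""
    rows = []
    for i, block in enumerate(partition):
        vals = [G.nodes[v].get("valence") for v in block]
        n = len(block)
        sub = G.subgraph(block)
        try:
            d = degeneracy(sub)
        except ValueError:
            d = None
        rows.append(
            {
                "cluster": i,
                "n_nodes": n,
                "frac_positive": sum(v == "positive" for v in vals) / n,
                "frac_negative": sum(v == "negative" for v in vals) / n,
                "degeneracy": d,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# neighborhood valence contrast

@dataclass
class NeighborhoodValenceResult:
    p_neg_in: float
    p_neg_out: float
    p_pos_in: float
    p_pos_out: float
    chi2_neg: float
    p_value_neg: float
    chi2_pos: float
    p_value_pos: float


def two_proportion_chi2(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion chi-square (1 df, no continuity correction)."""
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError("empty comparison group")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    denom = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if denom == 0:
        return 0.0, 1.0
    chi2 = (p1 - p2) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def neighborhood_valence_test(G: nx.Graph, node) -> NeighborhoodValenceResult:
    """Is a node's neighborhood more negative (or positive) than the rest?

    Compares the fraction of negative (resp. positive) words among the
    node's neighbors with the fraction among all other nodes, via the
    pooled two-proportion chi-square without continuity correction.
    """
    if node not in G:
        raise KeyError(node)
    nbrs = set(G[node])
    if len(nbrs) < 5:
        raise InsufficientDataError(f"{node!r} has only {len(nbrs)} neighbors")
    rest = set(G.nodes) - nbrs - {node}
    if not rest:
        raise InsufficientDataError("comparison group is empty")

    def count(group, val):
        return sum(G.nodes[v].get("valence") == val for v in group)

    n_in, n_out = len(nbrs), len(rest)
    k_neg_in, k_neg_out = count(nbrs, "negative"), count(rest, "negative")
    k_pos_in, k_pos_out = count(nbrs, "positive"), count(rest, "positive")
    chi2_neg, p_neg = two_proportion_chi2(k_neg_in, n_in, k_neg_out, n_out)
    chi2_pos, p_pos = two_proportion_chi2(k_pos_in, n_in, k_pos_out, n_out)
    return NeighborhoodValenceResult(
        p_neg_in=k_neg_in / n_in,
        p_neg_out=k_neg_out / n_out,
        p_pos_in=k_pos_in / n_in,
        p_pos_out=k_pos_out / n_out,
        chi2_neg=chi2_neg,
        p_value_neg=p_neg,
        chi2_pos=chi2_pos,
        p_value_pos=p_pos,
    )
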
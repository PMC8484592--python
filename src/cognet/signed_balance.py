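"""Emotional balance of signed word networks.

Edge signs are induced from word valences: a link touching a negative
word is negative (associations bridging into negative content carry
tension), a link between positive words — or a positive and a neutral
word — is positive, and a link between two neutral words carries no
sign. Under this rule the classic unbalanced triangle with exactly
one negative edge ({+,+,-}) can never arise, so the triad taxonomy
reduces to three classes plus an excluded class:

* ``{+,+,+}`` — no negative word (balanced),
* ``{+,-,-}`` — exactly one negative word (balanced),
* ``{-,-,-}`` — two or more negative words (unbalanced),
* excluded — two or more neutral words (no affective majority).

The degree of balance (DoB) is the fraction of classified triads that
are balanced. Observed censuses are compared against two null
models: degree-preserving connected rewiring (configuration model)
and uniform shuffling of the valence labels on the fixed topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VAL_CODE = {"positive": 1, "neutral": 0, "negative": -1}


class ValenceError(ValueError):
    """A node lacks the valence annotation the signing rule needs."""


class UndefinedStatisticError(ValueError):
    """Raised when a statistic's denominator is empty."""


@dataclass
class TriadCensus:
    """Counts of classified triangles and the resulting degree of balance."""

    n_ppp: int
    n_pmm: int
    n_mmm: int
    n_excluded: int

    @property
    def n_classified(self) -> int:
        return self.n_ppp + self.n_pmm + self.n_mmm

    @property
    def dob(self) -> float | None:
        """Degree of balance; ``None`` when no triad is classified."""
        if self.n_classified == 0:
            return None
        return (self.n_ppp + self.n_pmm) / self.n_classified

    def fractions(self) -> dict[str, float | None]:
        """Triad-class fractions over classified triads (and DoB)."""
        d = self.n_classified
        if d == 0:
            return {"frac_ppp": None, "frac_pmm": None, "frac_mmm": None, "dob": None}
        return {
            "frac_ppp": self.n_ppp / d,
            "frac_pmm": self.n_pmm / d,
            "frac_mmm": self.n_mmm / d,
            "dob": self.dob,
        }

    def fractions_all(self) -> dict[str, float | None]:
        """Same fractions over *all* triangles, excluded ones included."""
        d = self.n_classified + self.n_excluded
        if d == 0:
            return {"frac_ppp": None, "frac_pmm": None, "frac_mmm": None}
        return {
            "frac_ppp": self.n_ppp / d,
            "frac_pmm": self.n_pmm / d,
            "frac_mmm": self.n_mmm / d,
        }


@dataclass
class NullDistribution:
    """Monte-Carlo null distribution of one scalar statistic."""

    statistic: str
    samples: np.ndarray
    seed: int | None = None
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(
            [s for s in np.atleast_1d(self.samples) if s is not None], dtype=float
        )
        self.mean = float(np.mean(self.samples)) if len(self.samples) else float("nan")
        self.sd = float(np.std(self.samples, ddof=1)) if len(self.samples) > 1 else 0.0

    @property
    def n_realizations(self) -> int:
        return len(self.samples)

    def z(self, observed: float) -> float | None:
        """z-score of an observed value; ``None`` for a degenerate null."""
        if self.sd == 0:
            return None
        return (observed - self.mean) / self.sd


# ---------------------------------------------------------------------------
# signing and census

def edge_sign(valence_a: str, valence_b: str) -> int:
    """Sign of a link between two valenced words (see module docstring)."""
    try:
        ca, cb = _VAL_CODE[valence_a], _VAL_CODE[valence_b]
    except KeyError as exc:
        raise ValenceError(f"unannotated valence {exc.args[0]!r}") from exc
    if ca == -1 or cb == -1:
        return -1
    if ca == 0 and cb == 0:
        return 0
    return 1


def sign_edges(G: nx.Graph) -> nx.Graph:
    """Return a copy of the network with a ``sign`` attribute on every edge."""
    for n, d in G.nodes(data=True):
        if d.get("valence") not in _VAL_CODE:
            raise ValenceError(f"node {n!r} has valence {d.get('valence')!r}")
    S = G.copy()
    for a, b in S.edges():
        S[a][b]["sign"] = edge_sign(S.nodes[a]["valence"], S.nodes[b]["valence"])
    return S


def _triangle_index(G: nx.Graph) -> tuple[list, np.ndarray]:
    """Enumerate each triangle once as a (T, 3) array of node indices."""
    nodes = sorted(G.nodes())
    idx = {n: i for i, n in enumerate(nodes)}
    adj = {idx[n]: np.array(sorted(idx[m] for m in G[n]), dtype=np.int64) for n in nodes}
    tris = []
    for i in range(len(nodes)):
        nbrs_i = adj[i][adj[i] > i]
        for j in nbrs_i:
            nbrs_j = adj[j][adj[j] > j]
            common = np.intersect1d(nbrs_i, nbrs_j, assume_unique=True)
            for k in common:
                tris.append((i, j, k))
    arr = np.array(tris, dtype=np.int64).reshape(-1, 3)
    return nodes, arr


def _census_from_codes(tri: np.ndarray, codes: np.ndarray) -> TriadCensus:
    if len(tri) == 0:
        return TriadCensus(0, 0, 0, 0)
    v = codes[tri]
    n_neu = (v == 0).sum(axis=1)
    n_neg = (v == -1).sum(axis=1)
    excluded = n_neu >= 2
    mmm = ~excluded & (n_neg >= 2)
    pmm = ~excluded & (n_neg == 1)
    ppp = ~excluded & (n_neg == 0)
    return TriadCensus(int(ppp.sum()), int(pmm.sum()), int(mmm.sum()), int(excluded.sum()))


def _valence_codes(G: nx.Graph, nodes: list) -> np.ndarray:
    try:
        return np.array([_VAL_CODE[G.nodes[n]["valence"]] for n in nodes], dtype=np.int8)
    except KeyError as exc:
        raise ValenceError(f"unannotated valence: {exc.args[0]!r}") from exc


def triad_census(G: nx.Graph) -> TriadCensus:
    """Classify every triangle of the network by its nodes' valences.

    Works on the plain valence-annotated network (signing the edges is
    equivalent, since signs are a function of endpoint valences). A
    graph with no triangles yields an all-zero census whose ``dob`` is
    ``None``.
    """
    if G.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes for a triad census")
    nodes, tri = _triangle_index(G)
    census = _census_from_codes(tri, _valence_codes(G, nodes))
    if census.n_classified == 0:
        logger.warning("no classified triads; degree of balance undefined")
    return census


def degree_of_balance(census: TriadCensus) -> float:
    """Fraction of classified triads that are balanced."""
    if census.n_classified == 0:
        raise UndefinedStatisticError("no classified triads")
    return census.dob


# ---------------------------------------------------------------------------
# null models

_STATS = ("frac_ppp", "frac_pmm", "frac_mmm", "dob")


def rewire_preserving_degrees(
    G: nx.Graph, seed: int | np.random.Generator, nswap_factor: int = 10
) -> nx.Graph:
    """One configuration-model realization: connected double-edge swaps.

    Attempts ``nswap_factor * |E|`` swaps, each preserving every
    node's degree and rejected if it would disconnect the graph. Node
    attributes (valences) stay attached to their words.
    """
    rng = np.random.default_rng(seed)
    H = G.copy()
    nswap = nswap_factor * H.number_of_edges()
    try:
        nx.connected_double_edge_swap(
            H, nswap=nswap, seed=int(rng.integers(2**31))
        )
    except nx.NetworkXError as exc:
        logger.warning("rewiring stopped early: %s", exc)
    return H


def configuration_null(
    G: nx.Graph,
    n_realizations: int = 1000,
    seed: int | None = None,
    nswap_factor: int = 10,
) -> dict[str, NullDistribution]:
    """Triad-census null under degree-preserving connected rewiring.

    Disconnected inputs are reduced to their giant component (logged).
    Returns one :class:`NullDistribution` per triad-class fraction and
    for the degree of balance.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if not nx.is_connected(G):
        gc = max(nx.connected_components(G), key=len)
        logger.info("using giant component (%d/%d nodes)", len(gc), len(G))
        G = G.subgraph(gc).copy()
    rng = np.random.default_rng(seed)
    samples: dict[str, list] = {s: [] for s in _STATS}
    for _ in range(n_realizations):
        H = rewire_preserving_degrees(G, rng, nswap_factor)
        fr = triad_census(H).fractions()
        for s in _STATS:
            samples[s].append(fr[s])
    return {s: NullDistribution(s, samples[s], seed=seed) for s in _STATS}


def label_shuffle_null(
    G: nx.Graph, n_realizations: int = 1000, seed: int | None = None
) -> dict[str, NullDistribution]:
    """Triad-census null under uniform permutation of valence labels.

    The topology is fixed; only the assignment of the (multiset of)
    valences to words changes, so any excess balance in the data
    attributable to *where* valences sit — rather than to how many
    there are — vanishes.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    nodes, tri = _triangle_index(G)
    codes = _valence_codes(G, nodes)
    rng = np.random.default_rng(seed)
    samples: dict[str, list] = {s: [] for s in _STATS}
    for _ in range(n_realizations):
        fr = _census_from_codes(tri, rng.permutation(codes)).fractions()
        for s in _STATS:
            samples[s].append(fr[s])
    return {s: NullDistribution(s, samples[s], seed=seed) for s in _STATS}


def shuffle_valences(G: nx.Graph, seed: int | np.random.Generator) -> nx.Graph:
    """One label-shuffle realization as a graph (adjacency untouched)."""
    rng = np.random.default_rng(seed)
    nodes = sorted(G.nodes())
    vals = [G.nodes[n]["valence"] for n in nodes]
    H = G.copy()
    for n, v in zip(nodes, [vals[i] for i in rng.permutation(len(vals))]):
        H.nodes[n]["valence"] = v
    return H


def balance_report(
    observed: TriadCensus, nulls: dict[str, dict[str, NullDistribution]]
) -> pd.DataFrame:
    """Tabulate observed triad statistics against one or more null models.

    ``nulls`` maps a null-model name (e.g. ``"configuration"``,
    ``"label_shuffle"``) to the distributions returned by the null
    functions. z-scores are omitted (NaN) for degenerate nulls.
    """
    fr = observed.fractions()
    rows = []
    for model, dists in nulls.items():
        for stat in _STATS:
            dist = dists[stat]
            obs = fr[stat]
            z = dist.z(obs) if obs is not None else None
            rows.append(
                {
                    "statistic": stat,
                    "null_model": model,
                    "observed": np.nan if obs is None else obs,
                    "null_mean": dist.mean,
                    "null_sd": dist.sd,
                    "z": np.nan if z is None else z,
                    "n_realizations": dist.n_realizations,
                }
            )
    return pd.DataFrame(rows)
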
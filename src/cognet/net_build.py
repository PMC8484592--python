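"""Construction of co-occurrence (CO) and subject-verb-object (SVO) word networks.

Both representations live in undirected weighted :class:`networkx.Graph`
objects whose nodes are word types ("concepts") carrying ``valence``,
``is_stopword`` and ``frequency`` attributes, and whose graph-level
``kind`` attribute is one of ``CO``, ``SVO`` or ``FA``.

CO networks link concepts occurring near each other inside a sentence
(default: strictly adjacent after stopword removal), so they capture
the successive flow of ideas. SVO networks link the three participants
of each subject-verb-object triple as a 3-clique, so a word's strength
(sum of incident edge weights) equals exactly twice the number of
triples it occurs in — the property that makes strength a natural
centrality for actor analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .corpus_io import Corpus, CorpusError, PRONOUN_MERGE, Sentence
from .lemmatize import lemmatize

logger = logging.getLogger(__name__)

NETWORK_KINDS = ("CO", "SVO", "FA")


@dataclass(frozen=True)
class SvoTriple:
    """A subject-verb-object triple extracted from one sentence."""

    subject: str
    verb: str
    object: str
    doc_id: str = ""

    def __post_init__(self) -> None:
        if not (self.subject and self.verb and self.object):
            raise ValueError("triple fields must be non-empty")
        if self.subject == self.verb or self.verb == self.object:
            raise ValueError("verb must differ from subject and object")


def build_cooccurrence(
    corpus: Corpus, window: int = 1, drop_stopwords: bool = True
) -> nx.Graph:
    """Build the co-occurrence network of a corpus.

    Every pair of distinct concepts at distance <= ``window`` within a
    sentence adds 1 to the pair's edge weight; edges never cross
    sentence boundaries. With ``drop_stopwords`` (default), stopwords
    are removed *before* measuring distance, so content words
    separated only by function words count as adjacent. Repeated
    words at qualifying distance would be self-loops and are skipped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sentences = list(corpus.sentences())
    if not sentences:
        raise CorpusError("corpus has no sentences")

    G = nx.Graph(kind="CO")
    for sent in sentences:
        toks = [t for t in sent.tokens if not (drop_stopwords and t.is_stopword)]
        concepts = [corpus.concept(t) for t in toks]
        for t, c in zip(toks, concepts):
            if c not in G:
                G.add_node(c, valence=t.valence, is_stopword=t.is_stopword, frequency=0)
            G.nodes[c]["frequency"] += 1
        for i in range(len(concepts)):
            for j in range(i + 1, min(i + window, len(concepts) - 1) + 1):
                a, b = concepts[i], concepts[j]
                if a == b:
                    continue
                if G.has_edge(a, b):
                    G[a][b]["weight"] += 1
                else:
                    G.add_edge(a, b, weight=1)
    G.remove_nodes_from([n for n in G if G.degree(n) == 0])
    return G


# ---------------------------------------------------------------------------
# SVO extraction

#: dependency relations accepted as subject / object links (UD v2 names
#: plus the older Stanford-style aliases)
_SUBJ_RELS = {"nsubj", "nsubjpass", "nsubj:pass"}
_OBJ_RELS = {"obj", "dobj"}


def _normalize(word: str) -> str:
    w = word.strip().lower()
    return PRONOUN_MERGE.get(w, w)


def extract_svo_triples(
    parsed: str | Path | Iterable[Sentence],
    *,
    lemmatize_verbs: bool = True,
) -> list[SvoTriple]:
    """Extract subject-verb-object triples.

    Two input routes:

    * a CoNLL-U file path — triples come from ``nsubj``/``obj``
      dependents sharing a verbal head;
    * an iterable of tokenized :class:`Sentence` objects — the
      bundled heuristic extractor emits one triple per simple
      three-token declarative sentence (subject verb object), the
      pattern the synthetic generator plants.

    Gendered pronouns merge to "s/he"; verbs are lemmatized.
    Sentences that fit no pattern are skipped (counted in a log
    message), never fatal.
    """
    if isinstance(parsed, (str, Path)):
        return _extract_from_conllu(Path(parsed), lemmatize_verbs=lemmatize_verbs)

    triples: list[SvoTriple] = []
    n_skipped = 0
    for sent in parsed:
        toks = list(sent.tokens)
        if len(toks) == 3:
            s, v, o = toks
            verb = lemmatize(v.surface) if lemmatize_verbs else v.surface
            try:
                triples.append(
                    SvoTriple(
                        _normalize(s.surface), verb, _normalize(o.surface), sent.doc_id
                    )
                )
                continue
            except ValueError:
                pass
        n_skipped += 1
    if n_skipped:
        logger.info("SVO heuristic skipped %d sentence(s) with no pattern", n_skipped)
    return triples


def _extract_from_conllu(path: Path, *, lemmatize_verbs: bool) -> list[SvoTriple]:
    """Minimal CoNLL-U reader: FORM/LEMMA/HEAD/DEPREL columns only."""
    triples: list[SvoTriple] = []
    n_skipped = 0
    sent_rows: list[list[str]] = []
    doc_id = ""

    def flush() -> None:
        nonlocal n_skipped
        if not sent_rows:
            return
        by_id = {r[0]: r for r in sent_rows}
        subj: dict[str, str] = {}
        obj: dict[str, str] = {}
        for r in sent_rows:
            head, rel = r[6], r[7]
            lemma = _normalize(r[2] if r[2] != "_" else r[1])
            if rel in _SUBJ_RELS:
                subj.setdefault(head, lemma)
            elif rel in _OBJ_RELS:
                obj.setdefault(head, lemma)
        emitted = False
        for head in subj:
            if head in obj and head in by_id:
                r = by_id[head]
                verb = r[2] if r[2] != "_" else r[1]
                verb = lemmatize(verb.lower()) if lemmatize_verbs else verb.lower()
                try:
                    triples.append(SvoTriple(subj[head], verb, obj[head], doc_id))
                    emitted = True
                except ValueError:
                    pass
        if not emitted:
            n_skipped += 1

    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                if line.startswith("# newdoc id ="):
                    doc_id = line.split("=", 1)[1].strip()
                continue
            if not line:
                flush()
                sent_rows = []
                continue
            cols = line.split("\t")
            if len(cols) >= 8 and cols[0].isdigit():
                sent_rows.append(cols)
    flush()
    if n_skipped:
        logger.info("CoNLL-U: %d sentence(s) yielded no triple", n_skipped)
    return triples


def build_svo_network(
    triples: Sequence[SvoTriple],
    valence: dict[str, str] | None = None,
) -> nx.Graph:
    """Build the SVO network: one 3-clique (s-v, v-o, s-o) per triple.

    Each participating word gains strength 2 per triple, so node
    strength equals twice the word's triple count. Reflexive triples
    (subject == object) contribute only the s-v and v-o increments,
    which merge onto a single edge; their count is logged.
    ``valence`` optionally sets the node valence attribute.
    """
    if not triples:
        raise ValueError("no triples to build from")
    G = nx.Graph(kind="SVO")
    n_reflexive = 0
    for t in triples:
        pairs = [(t.subject, t.verb), (t.verb, t.object)]
        if t.subject != t.object:
            pairs.append((t.subject, t.object))
        else:
            n_reflexive += 1
        for a, b in pairs:
            if G.has_edge(a, b):
                G[a][b]["weight"] += 1
            else:
                G.add_edge(a, b, weight=1)
    if n_reflexive:
        logger.info("%d reflexive triple(s) (subject == object)", n_reflexive)
    for n in G.nodes:
        G.nodes[n]["valence"] = (valence or {}).get(n, "unknown")
        G.nodes[n]["is_stopword"] = False
    return G


def node_strengths(G: nx.Graph) -> dict[str, float]:
    """Strength = sum of incident edge weights, per node."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    return dict(G.degree(weight="weight"))
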
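"""Synthetic corpora, lexicons and baseline association networks.

Real narrative corpora of the kind this package analyzes (personal
notes and letters) are typically not distributable, so every analysis
stage must be exercisable on generated data with the same statistical
structure:

* a vocabulary with a positive/negative/neutral valence mix and
  per-word Plutchik emotion flags;
* documents of token sequences (default: 139 documents averaging
  ~120 tokens) whose adjacent words share valence with tunable
  probability ``c`` — the *compartmentalization* knob producing
  valence-assortative co-occurrence structure;
* planted subject-verb-object triples, embedded as parseable
  three-token sentences, including a *self* token acting as a star
  hub that preferentially attaches negative words;
* a connected free-association-style baseline network whose edges
  are independent of valence (no compartmentalization).

Sentences are token sequences sufficient for the network machinery,
not plausible prose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import zeta

from .corpus_io import (
    Corpus,
    EmotionLexicon,
    PLUTCHIK_EMOTIONS,
    Sentence,
    Token,
    ValenceLexicon,
)
from .net_build import SvoTriple

_VALS = ("positive", "negative", "neutral")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study condition.

    Defaults mirror a small corpus of personal notes: 139 documents of
    roughly 120 content tokens each, a lexicon with a realistic
    positive/negative/neutral mix, moderate affective
    compartmentalization, and a self token whose attached words are
    negative with probability 0.6.
    """

    vocab_size: int = 300
    valence_mix: tuple[float, float, float] = (0.35, 0.25, 0.40)  # pos, neg, neu
    emotion_prevalence: dict = field(
        default_factory=lambda: {e: 0.10 for e in PLUTCHIK_EMOTIONS}
    )
    n_docs: int = 139
    sentences_per_doc: tuple[int, int] = (6, 10)
    tokens_per_sentence: tuple[int, int] = (12, 18)
    compartmentalization: float = 0.4
    self_token: str = "i"
    p_self_negative_attach: float = 0.6
    n_planted_triples: int = 50
    n_self_triples: int = 60
    verb_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 20:
            raise ValueError("vocab_size must be >= 20")
        if abs(sum(self.valence_mix) - 1.0) > 1e-9:
            raise ValueError("valence_mix must sum to 1")
        for p in (*self.valence_mix, self.compartmentalization,
                  self.p_self_negative_attach, *self.emotion_prevalence.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for lo, hi in (self.sentences_per_doc, self.tokens_per_sentence):
            if lo > hi or lo < 1:
                raise ValueError("invalid integer range (min > max or < 1)")
        if set(self.emotion_prevalence) - set(PLUTCHIK_EMOTIONS):
            raise ValueError("unknown emotion in prevalence map")


def _vocab(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    """Noun and verb word lists; the self token is extra (in neither)."""
    n_verbs = max(2, int(spec.vocab_size * spec.verb_fraction))
    nouns = [f"n{i:04d}" for i in range(spec.vocab_size - n_verbs)]
    verbs = [f"v{i:04d}" for i in range(n_verbs)]
    return nouns, verbs


def generate_lexicons(spec: SyntheticSpec) -> tuple[ValenceLexicon, EmotionLexicon]:
    """Draw valence classes and emotion flags i.i.d. for the vocabulary.

    Valences follow ``valence_mix``; each emotion flag is an
    independent Bernoulli at its prevalence. The self token is always
    neutral (a pronoun carries no valence of its own). Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    nouns, verbs = _vocab(spec)
    words = nouns + verbs
    draws = rng.choice(3, size=len(words), p=list(spec.valence_mix))
    entries = {w: _VALS[d] for w, d in zip(words, draws)}
    entries[spec.self_token] = "neutral"

    emo_entries = {}
    for w in [*words, spec.self_token]:
        emo_entries[w] = frozenset(
            e for e in PLUTCHIK_EMOTIONS
            if rng.random() < spec.emotion_prevalence.get(e, 0.0)
        )
    return (
        ValenceLexicon(entries),
        EmotionLexicon(entries=emo_entries, universe=set(emo_entries)),
    )


def _sentence(words: list[str], doc_id: str) -> Sentence:
    return Sentence(
        tuple(Token(surface=w, lemma=w, is_stopword=False) for w in words), doc_id
    )


def _markov_sentence(
    length: int,
    c: float,
    by_valence: dict[str, list[str]],
    all_words: list[str],
    val_of: dict[str, str],
    rng: np.random.Generator,
) -> list[str]:
    """Token chain: each word copies its predecessor's valence w.p. ``c``."""
    words: list[str] = []
    prev_val: str | None = None
    for _ in range(length):
        pool = (
            by_valence[prev_val]
            if prev_val is not None and rng.random() < c
            else all_words
        )
        w = pool[rng.integers(len(pool))]
        words.append(w)
        prev_val = val_of[w]
    return words


def _draw_self_triples(
    spec: SyntheticSpec,
    verbs: list[str],
    periphery: list[str],
    val_of: dict[str, str],
    rng: np.random.Generator,
) -> list[SvoTriple]:
    """Self-as-subject triples whose objects skew negative.

    Objects come from a peripheral noun pool the background prose and
    planted triples do not use, so the self token accumulates
    neighbors connected to the rest of the network only through it —
    the star-hub pattern the structural analyses are meant to detect.
    """
    triples = []
    for _ in range(spec.n_self_triples):
        obj = periphery[rng.integers(len(periphery))]
        verb = verbs[rng.integers(len(verbs))]
        triples.append(SvoTriple(spec.self_token, verb, obj, ""))
    return triples


def generate_corpus(
    spec: SyntheticSpec, valence: ValenceLexicon | None = None
) -> tuple[Corpus, list[SvoTriple]]:
    """Generate a corpus and the ground-truth SVO triples embedded in it.

    Each document holds Markov prose sentences (the
    compartmentalization mechanism) plus, distributed uniformly over
    documents, the planted background triples and the self-hub
    triples, each embedded as a parseable three-token
    "subject verb object" sentence. Returns the corpus (tokens
    unannotated; apply :func:`cognet.corpus_io.annotate_valence`) and
    the full ground-truth triple list with document ids filled in.
    Deterministic given ``spec.seed``.
    """
    if valence is None:
        valence, _ = generate_lexicons(spec)
    rng = np.random.default_rng(spec.seed + 1)
    nouns, verbs = _vocab(spec)
    val_of = dict(valence.entries)

    # Reserve ~30% of nouns as the self hub's peripheral pool, composed so
    # that a fraction p_self_negative_attach of it is negative: a word the
    # self token attaches is negative with exactly that probability, and
    # negative words concentrate around the self rather than in the prose.
    n_periph = max(5, int(0.3 * len(nouns))) if spec.n_self_triples else 0
    if n_periph:
        neg_nouns = [w for w in nouns if val_of[w] == "negative"]
        other_nouns = [w for w in nouns if val_of[w] != "negative"]
        n_neg = min(len(neg_nouns), round(spec.p_self_negative_attach * n_periph))
        periph_neg = [neg_nouns[i] for i in rng.choice(len(neg_nouns), n_neg, replace=False)]
        n_other = min(len(other_nouns), n_periph - n_neg)
        periph_other = [
            other_nouns[i] for i in rng.choice(len(other_nouns), n_other, replace=False)
        ]
        periphery = sorted(periph_neg + periph_other)
    else:
        periphery = []
    periph_set = set(periphery)
    core_nouns = [w for w in nouns if w not in periph_set]
    core_words = core_nouns + verbs
    by_valence = {v: [w for w in core_words if val_of[w] == v] for v in _VALS}
    by_valence = {v: (ws if ws else core_words) for v, ws in by_valence.items()}

    # ground-truth triples
    triples: list[SvoTriple] = []
    for _ in range(spec.n_planted_triples):
        s = core_nouns[rng.integers(len(core_nouns))]
        o = core_nouns[rng.integers(len(core_nouns))]
        v = verbs[rng.integers(len(verbs))]
        triples.append(SvoTriple(s, v, o, ""))
    triples.extend(_draw_self_triples(spec, verbs, periphery, val_of, rng))

    # assign each triple to a document
    doc_of_triple = rng.integers(spec.n_docs, size=len(triples))

    documents: list[tuple[str, list[Sentence]]] = []
    placed: list[SvoTriple] = []
    lo_s, hi_s = spec.sentences_per_doc
    lo_t, hi_t = spec.tokens_per_sentence
    for d in range(spec.n_docs):
        doc_id = f"doc{d:04d}"
        sents = [
            _sentence(
                _markov_sentence(
                    int(rng.integers(lo_t, hi_t + 1)),
                    spec.compartmentalization,
                    by_valence,
                    core_words,
                    val_of,
                    rng,
                ),
                doc_id,
            )
            for _ in range(int(rng.integers(lo_s, hi_s + 1)))
        ]
        for t_idx in np.flatnonzero(doc_of_triple == d):
            t = triples[t_idx]
            t = SvoTriple(t.subject, t.verb, t.object, doc_id)
            placed.append(t)
            pos = int(rng.integers(len(sents) + 1))
            sents.insert(pos, _sentence([t.subject, t.verb, t.object], doc_id))
        documents.append((doc_id, sents))
    return Corpus(documents=documents), placed


def generate_fa_baseline(
    spec: SyntheticSpec, vocab: set[str] | None = None
) -> nx.Graph:
    """Connected association-style baseline network over the vocabulary.

    Preferential attachment (each new word attaches to 2 existing
    ones, chosen proportionally to degree) over a valence-independent
    random word order: degree heterogeneity without any coupling
    between valence and structure. ``kind`` is ``FA``; edge weights
    are 1. Deterministic given ``spec.seed``.
    """
    if vocab is None:
        nouns, verbs = _vocab(spec)
        vocab = set(nouns) | set(verbs) | {spec.self_token}
    if not vocab:
        raise ValueError("empty vocabulary")
    rng = np.random.default_rng(spec.seed + 2)
    words = sorted(vocab)
    order = [words[i] for i in rng.permutation(len(words))]
    m = min(2, len(words) - 1)
    B = nx.barabasi_albert_graph(len(words), m, seed=int(rng.integers(2**31)))
    G = nx.relabel_nodes(B, {i: order[i] for i in range(len(words))})
    nx.set_edge_attributes(G, 1, "weight")
    G.graph["kind"] = "FA"
    return G


# ---------------------------------------------------------------------------
# auxiliary samplers

def sample_discrete_power_law(
    gamma: float, xmin: int, size: int, seed: int | None = None, cap: int = 10**6
) -> np.ndarray:
    """Draw integers from P(X = k) ∝ k^(-gamma), k >= xmin.

    Exact inverse-CDF sampling on a table truncated at ``cap``
    (the truncated mass is ~zeta(gamma, cap)/zeta(gamma, xmin),
    negligible for the sizes used here); overflowing draws clamp to
    the cap.
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    rng = np.random.default_rng(seed)
    ks = np.arange(xmin, cap + 1, dtype=np.float64)
    pmf = ks ** (-gamma)
    tail_rest = zeta(gamma, cap + 1)  # mass beyond the table
    cdf = np.cumsum(pmf)
    total = cdf[-1] + tail_rest
    u = rng.random(size) * total
    idx = np.searchsorted(cdf, u, side="left")
    return np.minimum(idx + xmin, cap).astype(np.int64)
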
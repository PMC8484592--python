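"""Corpus, lexicon and association-network input/output.

This module turns raw inputs — plain-text documents, valence and
emotion lexicons, free-association edge lists — into the domain types
the rest of the pipeline consumes.  Tokenization is deliberately
simple and fully specified: lowercase, strip punctuation, split
sentences on terminal punctuation, merge gendered third-person
pronouns into "s/he", optionally lemmatize.  Stopwords are flagged
but never removed here; downstream stages decide what to do with
them.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .lemmatize import lemmatize
from .stopwords import DEFAULT_STOPWORDS

logger = logging.getLogger(__name__)

VALENCES = ("positive", "negative", "neutral", "unknown")
PLUTCHIK_EMOTIONS = (
    "anger", "anticipation", "disgust", "fear",
    "joy", "sadness", "surprise", "trust",
)

_SENT_SPLIT = re.compile(r"[.!?]+")
_WORD = re.compile(r"[a-z']+")

#: gendered third-person pronouns are merged into a single concept,
#: so that the self/other actor structure does not split by gender.
PRONOUN_MERGE = {"he": "s/he", "she": "s/he"}


class CorpusError(ValueError):
    """Raised for unreadable, empty or fully-filtered corpora."""


class LexiconFormatError(ValueError):
    """Raised for malformed lexicon files."""


@dataclass(frozen=True)
class Token:
    """One word occurrence: surface form, lemma, stopword flag, valence."""

    surface: str
    lemma: str
    is_stopword: bool
    valence: str = "unknown"

    def __post_init__(self) -> None:
        if not self.surface or any(ch.isspace() for ch in self.surface):
            raise ValueError(f"invalid token surface {self.surface!r}")
        if self.valence not in VALENCES:
            raise ValueError(f"invalid valence {self.valence!r}")


@dataclass(frozen=True)
class Sentence:
    tokens: tuple[Token, ...]
    doc_id: str

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Corpus:
    """An ordered collection of documents, each a list of sentences.

    ``concept_key`` selects whether the pipeline's word types
    ("concepts") are lemmas (default) or surface forms.
    """

    documents: list[tuple[str, list[Sentence]]]
    concept_key: str = "lemma"  # "lemma" | "surface"

    def __post_init__(self) -> None:
        if self.concept_key not in ("lemma", "surface"):
            raise ValueError("concept_key must be 'lemma' or 'surface'")

    def concept(self, token: Token) -> str:
        return token.lemma if self.concept_key == "lemma" else token.surface

    def sentences(self) -> Iterable[Sentence]:
        for _, sents in self.documents:
            yield from sents

    @property
    def vocabulary(self) -> set[str]:
        return {self.concept(t) for s in self.sentences() for t in s.tokens}

    @property
    def stats(self) -> dict:
        words_per_doc = [
            sum(len(s) for s in sents) for _, sents in self.documents
        ]
        n = len(words_per_doc)
        mean = sum(words_per_doc) / n if n else 0.0
        var = (
            sum((w - mean) ** 2 for w in words_per_doc) / (n - 1)
            if n > 1 else 0.0
        )
        return {
            "n_docs": n,
            "mean_words_per_doc": mean,
            "sd_words_per_doc": var ** 0.5,
            "n_distinct_concepts": len(self.vocabulary),
        }


@dataclass
class ValenceLexicon:
    """word -> {positive, negative, neutral} map.

    When built from a numeric norms table, scores <= ``thresholds[0]``
    are negative, >= ``thresholds[1]`` positive, and the band between
    is neutral.
    """

    entries: dict[str, str]
    thresholds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        bad = {v for v in self.entries.values()} - {"positive", "negative", "neutral"}
        if bad:
            raise LexiconFormatError(f"invalid valence classes: {sorted(bad)}")
        if self.thresholds is not None and not self.thresholds[0] < self.thresholds[1]:
            raise LexiconFormatError("thresholds must satisfy low < high")

    def classify_score(self, score: float) -> str:
        if self.thresholds is None:
            raise LexiconFormatError("no numeric thresholds configured")
        low, high = self.thresholds
        if score <= low:
            return "negative"
        if score >= high:
            return "positive"
        return "neutral"

    def get(self, word: str, default: str = "unknown") -> str:
        return self.entries.get(word, default)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class EmotionLexicon:
    """word -> subset of the 8 Plutchik basic emotions.

    ``universe`` is the full set of lexicon words, including words
    carrying no emotion at all; random-sampling null models for
    emotional profiling draw from it.
    """

    entries: dict[str, frozenset[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for word, emos in self.entries.items():
            bad = set(emos) - set(PLUTCHIK_EMOTIONS)
            if bad:
                raise LexiconFormatError(
                    f"unknown emotion(s) {sorted(bad)} for word {word!r}"
                )
        self.universe |= set(self.entries)

    def emotions(self, word: str) -> frozenset[str]:
        return self.entries.get(word, frozenset())

    def __len__(self) -> int:
        return len(self.universe)


# ---------------------------------------------------------------------------
# tokenization

def tokenize_text(
    text: str,
    *,
    lemmatize_tokens: bool = True,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    merge_pronouns: bool = True,
) -> list[list[Token]]:
    """Split raw text into sentences of Tokens.

    Sentences split on ``.!?``; tokens are maximal runs of letters or
    apostrophes, lowercased. Gendered pronouns merge to "s/he" before
    lemmatization so the merged form is the concept.
    """
    sentences: list[list[Token]] = []
    for raw_sent in _SENT_SPLIT.split(text.lower()):
        words = [w for w in _WORD.findall(raw_sent) if w.strip("'")]
        if not words:
            continue
        toks = []
        for w in words:
            w = w.strip("'")
            if merge_pronouns:
                w = PRONOUN_MERGE.get(w, w)
            lemma = lemmatize(w) if lemmatize_tokens and w != "s/he" else w
            toks.append(Token(surface=w, lemma=lemma, is_stopword=w in stopwords))
        sentences.append(toks)
    return sentences


def read_corpus(
    path: str | Path,
    min_sentences: int = 2,
    *,
    lemmatize_tokens: bool = True,
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    concept_key: str = "lemma",
) -> Corpus:
    """Read a corpus from a directory of ``.txt`` files or a JSONL file.

    Each ``.txt`` file is one document (its stem is the doc id); a
    JSONL file holds one ``{"id": ..., "text": ...}`` record per line.
    Documents with fewer than ``min_sentences`` sentences are dropped,
    mirroring the usual practice of discarding notes too short to
    carry sentence-level structure.
    """
    path = Path(path)
    raw_docs: list[tuple[str, str]] = []
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            raw_docs.append((f.stem, f.read_text(encoding="utf-8")))
    elif path.is_file():
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                raw_docs.append((str(rec.get("id", i)), rec["text"]))
    else:
        raise CorpusError(f"unreadable corpus path: {path}")
    if not raw_docs:
        raise CorpusError(f"no documents found at {path}")

    documents = []
    for doc_id, text in raw_docs:
        sents = [
            Sentence(tuple(toks), doc_id)
            for toks in tokenize_text(
                text, lemmatize_tokens=lemmatize_tokens, stopwords=stopwords
            )
        ]
        if len(sents) >= min_sentences:
            documents.append((doc_id, sents))
    if not documents:
        raise CorpusError(
            f"all {len(raw_docs)} documents filtered out (min_sentences={min_sentences})"
        )
    return Corpus(documents=documents, concept_key=concept_key)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in the one-JSON-record-per-line format.

    Token surfaces are joined with spaces and sentences terminated
    with ``.`` so that re-reading yields the same token sequences
    (modulo re-lemmatization, which is deterministic).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc_id, sents in corpus.documents:
            text = " . ".join(" ".join(t.surface for t in s.tokens) for s in sents)
            fh.write(json.dumps({"id": doc_id, "text": text + " ."}) + "\n")


# ---------------------------------------------------------------------------
# valence / emotion annotation

def annotate_valence(
    corpus: Corpus, lexicon: ValenceLexicon, oov_policy: str = "neutral"
) -> Corpus:
    """Return a copy of the corpus with token valences set from the lexicon.

    Out-of-vocabulary tokens get ``oov_policy`` ("neutral" by default:
    words the lexicon does not know neither create nor break signed
    triads). Idempotent for a fixed lexicon.
    """
    if len(lexicon) == 0:
        raise LexiconFormatError("empty valence lexicon")
    if oov_policy not in ("neutral", "unknown"):
        raise ValueError("oov_policy must be 'neutral' or 'unknown'")
    new_docs = []
    for doc_id, sents in corpus.documents:
        new_sents = []
        for s in sents:
            toks = tuple(
                replace(t, valence=lexicon.get(corpus.concept(t), oov_policy))
                for t in s.tokens
            )
            new_sents.append(Sentence(toks, doc_id))
        new_docs.append((doc_id, new_sents))
    return Corpus(documents=new_docs, concept_key=corpus.concept_key)


# ---------------------------------------------------------------------------
# lexicon readers / writers

def read_valence_lexicon(
    path: str | Path, thresholds: tuple[float, float] | None = None
) -> ValenceLexicon:
    """Read a two-column TSV ``word<TAB>class`` or ``word<TAB>score``.

    Class and score rows may not be mixed. Numeric scores are
    classified by ``thresholds`` (low, high).
    """
    path = Path(path)
    entries: dict[str, str] = {}
    saw_class = saw_score = False
    lex = ValenceLexicon({}, thresholds) if thresholds else None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LexiconFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(parts)}"
                )
            word, value = parts[0].strip().lower(), parts[1].strip()
            if value in ("positive", "negative", "neutral"):
                saw_class = True
                entries[word] = value
            else:
                try:
                    score = float(value)
                except ValueError as exc:
                    raise LexiconFormatError(
                        f"{path}:{lineno}: {value!r} is neither a class nor a number"
                    ) from exc
                saw_score = True
                if lex is None:
                    raise LexiconFormatError(
                        f"{path}:{lineno}: numeric score but no thresholds given"
                    )
                entries[word] = lex.classify_score(score)
            if saw_class and saw_score:
                raise LexiconFormatError(
                    f"{path}:{lineno}: mixed class and score rows"
                )
    return ValenceLexicon(entries, thresholds)


def read_emotion_lexicon(path: str | Path) -> EmotionLexicon:
    """Read an emotion lexicon in long (word, emotion, flag) or wide TSV.

    Long format follows the NRC association-lexicon convention; wide
    format has a ``word`` column plus one 0/1 column per emotion.
    Words with all flags 0 stay in the universe with an empty set.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] == 3:
        df.columns = ["word", "emotion", "flag"]
        # tolerate a header row
        if df.iloc[0]["flag"] not in ("0", "1"):
            df = df.iloc[1:]
        bad = set(df["emotion"].str.lower()) - set(PLUTCHIK_EMOTIONS)
        if bad:
            raise LexiconFormatError(f"unknown emotion name(s): {sorted(bad)}")
        entries: dict[str, set[str]] = {}
        for word, emo, flag in df.itertuples(index=False):
            w = word.strip().lower()
            entries.setdefault(w, set())
            if flag.strip() == "1":
                entries[w].add(emo.strip().lower())
    elif df.shape[1] == 9:
        header = [c.strip().lower() for c in df.iloc[0]]
        if header[0] != "word":
            raise LexiconFormatError("wide format needs a 'word' first column")
        emos = header[1:]
        bad = set(emos) - set(PLUTCHIK_EMOTIONS)
        if bad:
            raise LexiconFormatError(f"unknown emotion name(s): {sorted(bad)}")
        entries = {}
        for row in df.iloc[1:].itertuples(index=False):
            w = row[0].strip().lower()
            entries[w] = {e for e, f in zip(emos, row[1:]) if f.strip() == "1"}
    else:
        raise LexiconFormatError(
            f"emotion lexicon must have 3 (long) or 9 (wide) columns, got {df.shape[1]}"
        )
    frozen = {w: frozenset(e) for w, e in entries.items()}
    return EmotionLexicon(entries=frozen, universe=set(frozen))


def write_valence_lexicon(lexicon: ValenceLexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for word in sorted(lexicon.entries):
            fh.write(f"{word}\t{lexicon.entries[word]}\n")


def write_emotion_lexicon(lexicon: EmotionLexicon, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for word in sorted(lexicon.universe):
            emos = lexicon.emotions(word)
            for e in PLUTCHIK_EMOTIONS:
                fh.write(f"{word}\t{e}\t{1 if e in emos else 0}\n")


# ---------------------------------------------------------------------------
# association networks

def read_association_network(
    path: str | Path, vocab_filter: set[str] | None = None
) -> nx.Graph:
    """Read a cue,response[,weight] CSV into an undirected FA network.

    Reciprocal pairs aggregate their weights onto one undirected edge;
    self-loops are dropped (with a logged count). With
    ``vocab_filter``, only edges between listed words survive — the
    standard way of restricting a free-association baseline to a
    co-occurrence network's vocabulary.
    """
    df = pd.read_csv(path, header=None, comment="#", dtype=str)
    if df.shape[1] == 2:
        df.columns = ["cue", "response"]
        df["weight"] = 1.0
    elif df.shape[1] >= 3:
        df = df.iloc[:, :3]
        df.columns = ["cue", "response", "weight"]
        if not df.iloc[0]["weight"].replace(".", "", 1).lstrip("-").isdigit():
            df = df.iloc[1:]
        df["weight"] = df["weight"].astype(float)
    else:
        raise CorpusError("association CSV needs at least cue,response columns")
    df["cue"] = df["cue"].str.strip().str.lower()
    df["response"] = df["response"].str.strip().str.lower()

    n_loops = int((df["cue"] == df["response"]).sum())
    if n_loops:
        logger.info("dropping %d self-loop association(s)", n_loops)
        df = df[df["cue"] != df["response"]]

    G = nx.Graph(kind="FA")
    for cue, resp, w in df.itertuples(index=False):
        if vocab_filter is not None and (cue not in vocab_filter or resp not in vocab_filter):
            continue
        if G.has_edge(cue, resp):
            G[cue][resp]["weight"] += float(w)
        else:
            G.add_edge(cue, resp, weight=float(w))
    if G.number_of_edges() == 0:
        raise CorpusError("association network empty after filtering")
    return G


def write_network_csv(G: nx.Graph, path: str | Path, *, signed: bool = False) -> None:
    """Serialize a word network as a weighted (optionally signed) edge list."""
    with Path(path).open("w", encoding="utf-8") as fh:
        cols = "word_a,word_b,weight" + (",sign" if signed else "")
        fh.write(cols + "\n")
        for a, b in sorted((min(u, v), max(u, v)) for u, v in G.edges()):
            d = G[a][b]
            row = f"{a},{b},{d.get('weight', 1)}"
            if signed:
                row += f",{d['sign']}"
            fh.write(row + "\n")
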